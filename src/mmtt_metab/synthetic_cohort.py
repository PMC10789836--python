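"""Synthetic trial cohort generator.

Produces every input the analysis pipeline consumes — meal-test (MMTT)
time series forward-simulated from known beta cell parameters through the
same two-compartment C-peptide kinetics the deconvolution inverts, flash
glucose monitoring traces with arm-specific meal-timing structure, 3-day
food diaries, and a two-arm longitudinal trial table with prescribed diet,
group and interaction effects — so that ground truth is always available
for recovery tests.

Default conditions emulate a 12-week two-arm trial in type 2 diabetes:
14 + 13 randomised participants with 2 dropouts per arm, visits at weeks
0/4/8/12, MMTT sampling at 0, 15, 30, 45, 60, 90, 120, 150 and 180 min,
14-day sensor wear at 15-min intervals, and meals at 08:00/13:00/20:00.
The early time-restricted-carbohydrate (eTRC) arm eats carbohydrate only
at breakfast and lunch, so its simulated sensor trace has no dinner
glucose excursion, while the Mediterranean-diet (Med) arm shows three
daily postprandial peaks. Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .beta_cell_model import BetaCellParams, model_isr
from .isr_deconvolution import CpeptideKinetics, IsrTrace, forward_cpeptide, population_kinetics

__all__ = [
    "SimulationConfig",
    "TrueSubject",
    "MmttProfile",
    "simulate_subjects",
    "simulate_mmtt",
    "simulate_cgm",
    "simulate_trial",
    "simulate_cohort",
    "mmtt_glucose_curve",
]

MEAL_TIMES_H = {"breakfast": 8.0, "lunch": 13.0, "dinner": 20.0}

#: Trial-table variables the generator knows how to draw, with
#: (baseline mean, between-subject SD) in the units of the trial report.
VARIABLE_BASELINES: dict[str, tuple[float, float]] = {
    "hba1c_mmol_mol": (49.0, 5.0),
    "weight_kg": (80.0, 12.0),
    "fasting_glucose_mmol_l": (7.6, 0.8),
    "triglycerides_mmol_l": (1.25, 0.40),
    "alt_iu_l": (21.0, 7.0),
}

#: Study-condition effect sizes (diet, group, diet x group) per variable:
#: the diet effect is the week-12 change shared by both arms, the group
#: effect a constant eTRC offset, and the interaction an extra week-12
#: change in the eTRC arm. HbA1c reproduces the reported arm medians
#: (-4 Med, -3 eTRC mmol/mol); weight the ~5% prescribed loss.
DEFAULT_EFFECTS: dict[str, tuple[float, float, float]] = {
    "hba1c_mmol_mol": (-4.0, 0.0, 1.0),
    "weight_kg": (-4.0, 0.0, 0.0),
    "fasting_glucose_mmol_l": (-0.5, 0.0, 0.0),
    "triglycerides_mmol_l": (-0.26, 0.0, 0.05),
    "alt_iu_l": (-6.0, 0.0, 3.0),
}

DEFAULT_NOISE_SD: dict[str, float] = {
    "hba1c_mmol_mol": 3.0,  # the trial's own power assumption
    "weight_kg": 1.0,
    "fasting_glucose_mmol_l": 0.6,
    "triglycerides_mmol_l": 0.25,
    "alt_iu_l": 4.0,
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; the defaults are the study design."""

    seed: int = 0
    n_per_arm: tuple[int, int] = (14, 13)  # randomised (eTRC, Med)
    dropouts_per_arm: tuple[int, int] = (2, 2)
    visit_weeks: tuple[int, ...] = (0, 4, 8, 12)
    mmtt_weeks: tuple[int, ...] = (0, 12)
    mmtt_sampling_times: tuple[float, ...] = (0, 15, 30, 45, 60, 90, 120, 150, 180)
    effect_sizes: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    subject_sd: float = 1.0  # scale on between-subject baseline SDs
    cgm_days: int = 14
    cgm_interval_min: int = 15
    cgm_baseline_mmol_l: float = 7.0
    cgm_circadian_amp: float = 0.4
    cgm_bump_amp: dict[str, float] = field(
        default_factory=lambda: {"breakfast": 2.5, "lunch": 2.2, "dinner": 2.5}
    )
    cgm_bump_width_min: float = 55.0
    cgm_noise_sd: float = 0.35
    cgm_ar1: float = 0.8
    cgm_start: str = "2023-01-02T00:00:00"
    meal_times_h: dict[str, float] = field(default_factory=lambda: dict(MEAL_TIMES_H))
    after_lunch_carb_share: dict[str, float] = field(
        default_factory=lambda: {"eTRC": 0.10, "Med": 0.30}
    )
    diary_days: int = 3
    daily_carb_g: float = 180.0
    mmtt_noise: dict[str, float] = field(
        default_factory=lambda: {"glucose": 0.10, "insulin": 6.0, "cpeptide": 25.0}
    )
    insulin_lag_min: float = 25.0

    def __post_init__(self) -> None:
        if min(self.n_per_arm) < 2:
            raise ValueError("n_per_arm must be >= 2 in each arm")
        t = np.asarray(self.mmtt_sampling_times, float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("MMTT sampling times must start at 0 and be strictly increasing")
        if self.cgm_days < 1:
            raise ValueError("cgm_days must be >= 1")
        unknown = set(self.effect_sizes) - set(VARIABLE_BASELINES)
        if unknown:
            raise ValueError(f"unknown variables in effect_sizes: {sorted(unknown)}")


@dataclass
class TrueSubject:
    """Ground-truth physiology of one simulated participant."""

    id: str
    arm: str
    sex: str
    age: float
    weight_kg: float
    height_cm: float
    fasting_glucose: float
    true_betacell: dict  # glucose_sensitivity, isr_at_5_5, rate_sensitivity, pot_slope
    true_kinetics: CpeptideKinetics
    insulin_clearance_true: float  # l/min
    completer: bool = True

    def __post_init__(self) -> None:
        if min(self.age, self.weight_kg, self.height_cm, self.fasting_glucose,
               self.insulin_clearance_true) <= 0:
            raise ValueError("physiological quantities must be strictly positive")


@dataclass
class MmttProfile:
    """One participant-visit's sampled meal-test series, with ground truth."""

    subject_id: str
    visit_week: int
    time_min: np.ndarray
    glucose_mmol_l: np.ndarray
    insulin_pmol_l: np.ndarray
    cpeptide_pmol_l: np.ndarray
    true_isr: IsrTrace | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "visit_week": self.visit_week,
                "time_min": self.time_min,
                "glucose_mmol_l": self.glucose_mmol_l,
                "insulin_pmol_l": self.insulin_pmol_l,
                "cpeptide_pmol_l": self.cpeptide_pmol_l,
            }
        )


def _betacell_from_truth(truth: dict, grid: np.ndarray) -> BetaCellParams:
    """Materialize a ground-truth parameter set on a grid; potentiation is
    exp(slope * (t - mid)/180), renormalized to mean 1 over the window."""
    lp = truth.get("pot_slope", 0.0) * (grid - grid.mean()) / 180.0
    p = np.exp(lp)
    p = p / (np.trapezoid(p, grid) / (grid[-1] - grid[0]))
    return BetaCellParams(
        glucose_sensitivity=truth["glucose_sensitivity"],
        isr_at_5_5=truth["isr_at_5_5"],
        rate_sensitivity=truth["rate_sensitivity"],
        potentiation_time=grid,
        potentiation=p,
    )


def mmtt_glucose_curve(
    g0: float,
    rise: float,
    t_peak: float = 45.0,
    t_end: float = 180.0,
    dt: float = 1.0,
    shape: float = 1.6,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth meal-test glucose excursion: baseline g0 plus a gamma-shaped
    bump of height ``rise`` peaking at ``t_peak`` min.

    ``shape`` sharpens the bump (exponent on the normalized gamma kernel);
    the default returns glucose most of the way to baseline by 180 min, the
    characteristic profile of a 3 h mixed meal. The return limb matters
    beyond realism: revisiting matched glucose levels at different times is
    what identifies the potentiation factor against the dose-response in
    downstream model fits.
    """
    t = np.arange(0.0, t_end + dt / 2, dt)
    bump = ((t / t_peak) * np.exp(1.0 - t / t_peak)) ** shape
    return t, g0 + rise * bump


def simulate_mmtt(
    subject: TrueSubject,
    glucose_time: np.ndarray,
    glucose_curve: np.ndarray,
    config: SimulationConfig,
    visit_week: int = 0,
    rng: np.random.Generator | None = None,
) -> MmttProfile:
    """Forward-simulate a sampled MMTT from ground-truth physiology.

    ISR comes from the beta cell model (dose-response x potentiation + rate
    component) on the fine glucose grid; C-peptide from exact forward
    two-compartment kinetics started at the fasting steady state; insulin as
    ISR / clearance through a first-order plasma lag. Samples are read off
    at the configured times with additive Gaussian noise (zero noise if
    ``rng`` is None).
    """
    t = np.asarray(glucose_time, float)
    g = np.asarray(glucose_curve, float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("glucose grid must be strictly increasing")
    if t[1] - t[0] > 1.0 + 1e-9:
        raise ValueError("glucose curve must be on a fine (<= 1 min) grid")
    if np.any(g <= 0):
        raise ValueError("glucose must be positive throughout")

    params = _betacell_from_truth(subject.true_betacell, t)
    dgdt = np.gradient(g, t)
    isr = model_isr(params, t, g, dgdt)
    kin = subject.true_kinetics
    c0 = isr.isr[0] / (kin.k01 * kin.v)
    cpep = forward_cpeptide(isr, kin, c0=c0)
    if np.any(cpep < 0):
        raise ValueError("impossible parameters: negative noise-free C-peptide")

    # insulin: first-order lag towards ISR/CL, exact exponential update
    target = isr.isr / subject.insulin_clearance_true
    tau = config.insulin_lag_min
    ins = np.empty_like(target)
    ins[0] = target[0]
    dt = np.diff(t)
    decay = np.exp(-dt / tau)
    for i in range(len(t) - 1):
        ins[i + 1] = target[i + 1] + (ins[i] - target[i + 1]) * decay[i]

    samp = np.asarray(config.mmtt_sampling_times, float)
    gs = np.interp(samp, t, g)
    cs = np.interp(samp, t, cpep)
    xs = np.interp(samp, t, ins)
    if rng is not None:
        gs = gs + rng.normal(0.0, config.mmtt_noise["glucose"], gs.shape)
        cs = cs + rng.normal(0.0, config.mmtt_noise["cpeptide"], cs.shape)
        xs = xs + rng.normal(0.0, config.mmtt_noise["insulin"], xs.shape)
    return MmttProfile(
        subject_id=subject.id,
        visit_week=visit_week,
        time_min=samp,
        glucose_mmol_l=np.clip(gs, 0.1, None),
        insulin_pmol_l=np.clip(xs, 0.1, None),
        cpeptide_pmol_l=np.clip(cs, 0.1, None),
        true_isr=isr,
    )


def simulate_cgm(
    arm: str,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    bump_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a sensor trace: circadian baseline + postprandial Gaussian
    bumps (no dinner bump in the eTRC arm) + AR(1) sensor noise.

    Returns (timestamps, glucose). Trace length is exactly
    cgm_days * 24 * 60 / cgm_interval_min samples.
    """
    if arm not in ("eTRC", "Med"):
        raise ValueError(f"arm must be 'eTRC' or 'Med', got {arm!r}")
    n = config.cgm_days * 24 * 60 // config.cgm_interval_min
    t0 = np.datetime64(config.cgm_start)
    times = t0 + np.arange(n) * np.timedelta64(config.cgm_interval_min * 60, "s")
    minutes = (np.arange(n) * config.cgm_interval_min) % (24 * 60)
    hours = minutes / 60.0
    g = config.cgm_baseline_mmol_l + config.cgm_circadian_amp * np.sin(
        2 * np.pi * (hours - 10.0) / 24.0
    )
    meals = ["breakfast", "lunch"] + (["dinner"] if arm == "Med" else [])
    for meal in meals:
        center = config.meal_times_h[meal] * 60.0 + 40.0  # peak ~40 min post meal
        amp = bump_scale * config.cgm_bump_amp[meal]
        d = np.minimum(np.abs(minutes - center), 24 * 60 - np.abs(minutes - center))
        g = g + amp * np.exp(-0.5 * (d / config.cgm_bump_width_min) ** 2)
    if rng is not None and config.cgm_noise_sd > 0:
        eps = rng.normal(0.0, config.cgm_noise_sd * np.sqrt(1 - config.cgm_ar1**2), n)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, config.cgm_noise_sd)
        for i in range(1, n):
            noise[i] = config.cgm_ar1 * noise[i - 1] + eps[i]
        g = g + noise
    return times, np.clip(g, 2.5, None)


def simulate_subjects(config: SimulationConfig, rng: np.random.Generator) -> list[TrueSubject]:
    """Draw ground-truth participants for both arms.

    Physiology brackets the trial cohort: age ~67 +/- 8 y, BMI ~29 +/- 3.7,
    fasting glucose 6.6-8.9 mmol/l, and beta cell parameters in the range
    typical of well-controlled type 2 diabetes.
    """
    subjects = []
    for arm, n_arm, dropouts in zip(
        ("eTRC", "Med"), config.n_per_arm, config.dropouts_per_arm
    ):
        drop_idx = set(rng.choice(n_arm, size=min(dropouts, n_arm), replace=False).tolist())
        for i in range(n_arm):
            sex = "F" if rng.random() < 0.478 else "M"
            age = float(np.clip(rng.normal(67.0, 8.0), 40.0, 75.0))
            height = float(rng.normal(161.0 if sex == "F" else 172.0, 6.0))
            bmi = float(np.clip(rng.normal(29.4, 3.7), 25.0, 40.0))
            weight = bmi * (height / 100.0) ** 2
            g0 = float(rng.uniform(6.6, 8.9))
            truth = {
                "glucose_sensitivity": float(rng.lognormal(np.log(60.0), 0.35)),
                "isr_at_5_5": float(rng.lognormal(np.log(110.0), 0.25)),
                "rate_sensitivity": float(rng.lognormal(np.log(500.0), 0.40)),
                "pot_slope": float(rng.uniform(0.3, 1.2)),
            }
            kin = population_kinetics(age, sex, height, weight, diabetes=True)
            subjects.append(
                TrueSubject(
                    id=f"{arm}-{i+1:02d}",
                    arm=arm,
                    sex=sex,
                    age=age,
                    weight_kg=weight,
                    height_cm=height,
                    fasting_glucose=g0,
                    true_betacell=truth,
                    true_kinetics=kin,
                    insulin_clearance_true=float(rng.lognormal(np.log(1.1), 0.20)),
                    completer=i not in drop_idx,
                )
            )
    return subjects


def simulate_trial(
    config: SimulationConfig, subjects: list[TrueSubject], rng: np.random.Generator
) -> pd.DataFrame:
    """Long trial table (subject x visit x variable) with prescribed effects.

    value = subject baseline + diet_effect * f + group_offset * [eTRC]
            + interaction * f * [eTRC] + noise,  f = week / final week,
    so the week-12 minus week-0 change equals the diet effect (plus the
    interaction in the eTRC arm) exactly when noise is zero.
    """
    wmax = max(config.visit_weeks)
    rows = []
    for s in subjects:
        is_etrc = 1.0 if s.arm == "eTRC" else 0.0
        for var, (diet_eff, group_eff, inter_eff) in config.effect_sizes.items():
            mu, sd_b = VARIABLE_BASELINES[var]
            base = mu + config.subject_sd * sd_b * rng.standard_normal()
            noise_sd = config.noise_sd.get(var, 0.0)
            for week in config.visit_weeks:
                f = week / wmax if wmax > 0 else 0.0
                val = (
                    base
                    + diet_eff * f
                    + group_eff * is_etrc
                    + inter_eff * f * is_etrc
                    + noise_sd * rng.standard_normal()
                )
                rows.append(
                    {
                        "subject_id": s.id,
                        "arm": s.arm,
                        "visit_week": week,
                        "variable": var,
                        "value": val,
                    }
                )
    return pd.DataFrame(rows)


def simulate_diaries(
    config: SimulationConfig, subjects: list[TrueSubject], rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-meal food diaries whose after-lunch carbohydrate share matches the
    arm's configured fraction (eTRC well below Med by construction)."""
    rows = []
    for s in subjects:
        share = config.after_lunch_carb_share[s.arm]
        for day in range(1, config.diary_days + 1):
            total = config.daily_carb_g * (
                1.0 + (0.08 * rng.standard_normal() if rng is not None else 0.0)
            )
            jitter = 0.15 * rng.standard_normal() if rng is not None else 0.0
            sh = float(np.clip(share * (1.0 + jitter), 0.01, 0.6))
            after = total * sh
            pre = total - after
            split = {"breakfast": 0.45 * pre, "lunch": 0.55 * pre, "dinner": 0.8 * after,
                     "other": 0.2 * after}
            for meal, carb in split.items():
                protein = 0.35 * carb + 10.0
                fat = 0.30 * carb + 8.0
                energy = (carb * 4 + protein * 4 + fat * 9) * 4.184
                rows.append(
                    {
                        "subject_id": s.id,
                        "day": day,
                        "meal": meal,
                        "carb_g": carb,
                        "fat_g": fat,
                        "protein_g": protein,
                        "energy_kj": energy,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class Cohort:
    """Bundle of everything the generator produces for one seeded run."""

    config: SimulationConfig
    subjects: list[TrueSubject]
    mmtt: pd.DataFrame
    cgm: pd.DataFrame
    diaries: pd.DataFrame
    trial_table: pd.DataFrame
    true_isr: dict[tuple[str, int], IsrTrace]


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Run the full generator under the config's seed.

    MMTTs are simulated at the configured MMTT weeks (the week-12 curves use
    a lower fasting glucose and smaller excursion, emulating the diet
    response); CGM is simulated per completer at each visit after week 0.
    """
    rng = np.random.default_rng(config.seed)
    subjects = simulate_subjects(config, rng)
    mmtt_frames, true_isr = [], {}
    cgm_frames = []
    for s in subjects:
        if not s.completer:
            continue
        for week in config.mmtt_weeks:
            f = week / max(config.visit_weeks)
            g0 = s.fasting_glucose - 0.5 * f
            rise = 3.0 * (1.0 - 0.15 * f)
            t, curve = mmtt_glucose_curve(g0, rise)
            prof = simulate_mmtt(s, t, curve, config, visit_week=week, rng=rng)
            mmtt_frames.append(prof.to_frame())
            true_isr[(s.id, week)] = prof.true_isr
        times, glucose = simulate_cgm(s.arm, config, rng=rng)
        cgm_frames.append(
            pd.DataFrame({"subject_id": s.id, "timestamp": times, "glucose_mmol_l": glucose})
        )
    diaries = simulate_diaries(config, subjects, rng=rng)
    trial_table = simulate_trial(config, subjects, rng)
    return Cohort(
        config=config,
        subjects=subjects,
        mmtt=pd.concat(mmtt_frames, ignore_index=True),
        cgm=pd.concat(cgm_frames, ignore_index=True),
        diaries=diaries,
        trial_table=trial_table,
        true_isr=true_isr,
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, str]:
    """Write the cohort to CSV files plus a ground-truth JSON sidecar."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, df in (
        ("mmtt", cohort.mmtt),
        ("cgm", cohort.cgm),
        ("diaries", cohort.diaries),
        ("trial_table", cohort.trial_table),
    ):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        files[name] = str(path)
    subj = pd.DataFrame(
        [
            {
                "subject_id": s.id, "arm": s.arm, "sex": s.sex, "age": s.age,
                "weight_kg": s.weight_kg, "height_cm": s.height_cm,
                "completer": s.completer,
            }
            for s in cohort.subjects
        ]
    )
    subj_path = out / "subjects.csv"
    subj.to_csv(subj_path, index=False)
    files["subjects"] = str(subj_path)
    truth = {
        s.id: {
            "arm": s.arm,
            "betacell": s.true_betacell,
            "kinetics": dataclasses.asdict(s.true_kinetics),
            "insulin_clearance": s.insulin_clearance_true,
            "fasting_glucose": s.fasting_glucose,
            "completer": s.completer,
        }
        for s in cohort.subjects
    }
    truth_path = out / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))
    files["ground_truth"] = str(truth_path)
    return files
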