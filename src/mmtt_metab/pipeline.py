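"""End-to-end pipeline: simulate -> deconvolve -> fit -> indices -> CGM -> trial stats.

Each stage reads its inputs from and writes its outputs to the run
directory, so a run can be resumed: a stage is skipped when its outputs
already exist and no upstream stage was re-executed. A JSON run manifest
records the resolved configuration (and its hash), seed, package versions,
the file inventory and CONSORT-style participant accounting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .beta_cell_model import fit_beta_cell
from .cgm_metrics import CgmTrace, summarize
from .isr_deconvolution import IsrTrace, deconvolve_isr, population_kinetics
from .metabolic_indices import homa_ir, insulin_clearance, matsuda
from .synthetic_cohort import SimulationConfig, simulate_cohort, write_cohort
from .trial_stats import compare_groups, rm_anova, tertile_stratify

__all__ = ["run_pipeline", "load_config"]

STAGES = ("simulate", "deconvolve", "betacell", "indices", "cgm", "trial")

STAGE_OUTPUTS = {
    "simulate": ["mmtt.csv", "cgm.csv", "diaries.csv", "trial_table.csv",
                 "subjects.csv", "ground_truth.json"],
    "deconvolve": ["isr.csv"],
    "betacell": ["betacell.csv"],
    "indices": ["indices.csv"],
    "cgm": ["cgm_summary.csv"],
    "trial": ["anova.csv", "tertiles.csv", "report.txt"],
}


def load_config(path: str | Path | None = None, seed: int | None = None,
                overrides: dict | None = None) -> SimulationConfig:
    """Build a SimulationConfig from an optional YAML file plus overrides.

    Schema violations are collected and reported all at once.
    """
    import yaml

    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        raw.update(overrides)
    if seed is not None:
        raw["seed"] = seed
    valid = {f.name for f in dataclasses.fields(SimulationConfig)}
    errors = [f"unknown config key: {k}" for k in raw if k not in valid]
    for key in ("n_per_arm", "dropouts_per_arm", "visit_weeks", "mmtt_weeks",
                "mmtt_sampling_times"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return SimulationConfig(**{k: v for k, v in raw.items() if k in valid})


def _config_hash(config: SimulationConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _pct(k: int, n: int) -> float:
    return float(np.round(100.0 * k / n, 1))


def _stage_deconvolve(outdir: Path, lam: float | None = None) -> None:
    mmtt = pd.read_csv(outdir / "mmtt.csv")
    subjects = pd.read_csv(outdir / "subjects.csv").set_index("subject_id")
    frames = []
    for (sid, week), grp in mmtt.groupby(["subject_id", "visit_week"]):
        row = subjects.loc[sid]
        kin = population_kinetics(row["age"], row["sex"], row["height_cm"],
                                  row["weight_kg"], diabetes=True)
        trace = deconvolve_isr(grp["time_min"].to_numpy(),
                               grp["cpeptide_pmol_l"].to_numpy(), kin, lam=lam)
        frames.append(pd.DataFrame({
            "subject_id": sid, "visit_week": week,
            "time_min": trace.time, "isr_pmol_min": trace.isr,
        }))
    pd.concat(frames, ignore_index=True).to_csv(outdir / "isr.csv", index=False)


def _stage_betacell(outdir: Path, seed: int, n_starts: int = 5) -> None:
    mmtt = pd.read_csv(outdir / "mmtt.csv")
    isr = pd.read_csv(outdir / "isr.csv")
    rows = []
    for (sid, week), grp in isr.groupby(["subject_id", "visit_week"]):
        m = mmtt[(mmtt["subject_id"] == sid) & (mmtt["visit_week"] == week)]
        trace = IsrTrace(grp["time_min"].to_numpy(), grp["isr_pmol_min"].to_numpy())
        fit = fit_beta_cell(m["time_min"].to_numpy(), m["glucose_mmol_l"].to_numpy(),
                            trace, n_starts=n_starts, seed=seed)
        p = fit.params
        rows.append({
            "subject_id": sid, "visit_week": week,
            "beta_gs": p.glucose_sensitivity, "isr_5_5": p.isr_at_5_5,
            "beta_rs": p.rate_sensitivity, "pot_ratio": p.potentiation_ratio,
            "resid_sd": p.resid_sd, "converged": p.converged,
        })
    pd.DataFrame(rows).to_csv(outdir / "betacell.csv", index=False)


def _stage_indices(outdir: Path) -> None:
    mmtt = pd.read_csv(outdir / "mmtt.csv")
    isr = pd.read_csv(outdir / "isr.csv")
    rows = []
    for (sid, week), m in mmtt.groupby(["subject_id", "visit_week"]):
        s = isr[(isr["subject_id"] == sid) & (isr["visit_week"] == week)]
        t = m["time_min"].to_numpy()
        g = m["glucose_mmol_l"].to_numpy()
        ins = m["insulin_pmol_l"].to_numpy()
        st, sv = s["time_min"].to_numpy(), s["isr_pmol_min"].to_numpy()
        rows.append({
            "subject_id": sid, "visit_week": week,
            "homa_ir": homa_ir(g[t == 0][0], ins[t == 0][0]),
            "matsuda": matsuda(t, g, ins),
            "clear_fast": insulin_clearance(st, sv, t, ins, mode="fasting"),
            "clear_total": insulin_clearance(st, sv, t, ins, mode="total"),
        })
    pd.DataFrame(rows).to_csv(outdir / "indices.csv", index=False)


def _stage_cgm(outdir: Path, interval_min: float) -> None:
    cgm = pd.read_csv(outdir / "cgm.csv")
    rows = []
    for sid, grp in cgm.groupby("subject_id"):
        trace = CgmTrace.from_frame(grp)
        s = summarize(trace, nominal_interval_min=interval_min)
        rows.append({"subject_id": sid, **dataclasses.asdict(s)})
    pd.DataFrame(rows).to_csv(outdir / "cgm_summary.csv", index=False)


def _stage_trial(outdir: Path) -> dict:
    table = pd.read_csv(outdir / "trial_table.csv")
    diaries = pd.read_csv(outdir / "diaries.csv")
    subjects = pd.read_csv(outdir / "subjects.csv")
    completers = set(subjects.loc[subjects["completer"], "subject_id"])
    table = table[table["subject_id"].isin(completers)]
    diaries = diaries[diaries["subject_id"].isin(completers)]

    anova_frames = []
    for var in sorted(table["variable"].unique()):
        eff = rm_anova(table, var)
        eff.insert(0, "variable", var)
        anova_frames.append(eff)
    anova = pd.concat(anova_frames, ignore_index=True)
    anova.to_csv(outdir / "anova.csv", index=False)

    weeks = sorted(table["visit_week"].unique())
    wide = table.pivot_table(index=["subject_id", "variable"], columns="visit_week",
                             values="value")
    change = (wide[weeks[-1]] - wide[weeks[0]]).rename("change").reset_index()
    changes = change.pivot(index="subject_id", columns="variable", values="change")
    tert = tertile_stratify(diaries, changes.reset_index())
    tert["tests"].to_csv(outdir / "tertiles.csv", index=False)

    report = _report(outdir, table, anova, tert)
    (outdir / "report.txt").write_text(report)
    return {"n_analysed": len(completers)}


def _report(outdir: Path, table: pd.DataFrame, anova: pd.DataFrame, tert: dict) -> str:
    lines = ["Synthetic trial analysis report", "=" * 34, ""]
    base = table[table["visit_week"] == table["visit_week"].min()]
    lines.append("Baseline comparison (median [Q1, Q3]; Mann-Whitney p):")
    for var, grp in base.groupby("variable"):
        parts = []
        for arm in ("eTRC", "Med"):
            v = grp.loc[grp["arm"] == arm, "value"]
            parts.append(f"{arm} {v.median():.1f} [{v.quantile(.25):.1f}, {v.quantile(.75):.1f}]")
        _, p = compare_groups(grp.loc[grp["arm"] == "eTRC", "value"],
                              grp.loc[grp["arm"] == "Med", "value"])
        lines.append(f"  {var}: " + " vs ".join(parts) + f", p={p:.3f}")
    lines.append("")
    lines.append("Repeated-measures ANOVA (diet / group / diet x group):")
    for var, grp in anova.groupby("variable"):
        terms = ", ".join(f"{r.effect} p={r.p:.3f}" for r in grp.itertuples())
        lines.append(f"  {var}: {terms}")
    lines.append("")
    if (outdir / "betacell.csv").exists():
        bc = pd.read_csv(outdir / "betacell.csv")
        lines.append("Beta cell parameters (mean by visit week):")
        for week, grp in bc.groupby("visit_week"):
            lines.append(
                f"  week {week}: beta-GS {grp['beta_gs'].mean():.1f}, "
                f"ISR@5.5 {grp['isr_5_5'].mean():.1f}, beta-RS {grp['beta_rs'].mean():.0f}, "
                f"pot. ratio {grp['pot_ratio'].mean():.2f}"
            )
        lines.append("")
    if (outdir / "cgm_summary.csv").exists():
        cs = pd.read_csv(outdir / "cgm_summary.csv")
        lines.append(
            f"CGM (cohort means): glucose {cs['mean'].mean():.2f} mmol/l, "
            f"CV {cs['cv'].mean():.1f}%, TIR {cs['tir_3_9_10'].mean():.1f}%, "
            f"TAR {cs['tar_10'].mean():.1f}%, TBR {cs['tbr_3_9'].mean():.2f}%"
        )
        lines.append("")
    lines.append("Extreme-tertile comparison of after-lunch carbohydrate share:")
    for r in tert["tests"].itertuples():
        lines.append(f"  {r.outcome}: U={r.U:.1f}, p={r.p:.3f} (n={r.n_t1} vs {r.n_t3})")
    return "\n".join(lines) + "\n"


def run_pipeline(
    config: SimulationConfig,
    outdir: str | Path,
    resume: bool = False,
    lam: float | None = None,
    n_starts: int = 5,
) -> dict:
    """Execute all stages in dependency order; returns the run manifest.

    With ``resume=True`` a stage whose outputs all exist is skipped, but any
    stage downstream of a re-executed stage is re-executed too. A stage
    failure propagates with the stage name attached.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dirty = False
    executed = []
    for stage in STAGES:
        outputs = [out / f for f in STAGE_OUTPUTS[stage]]
        if resume and not dirty and all(p.exists() for p in outputs):
            continue
        dirty = True
        try:
            if stage == "simulate":
                write_cohort(simulate_cohort(config), out)
            elif stage == "deconvolve":
                _stage_deconvolve(out, lam=lam)
            elif stage == "betacell":
                _stage_betacell(out, seed=config.seed, n_starts=n_starts)
            elif stage == "indices":
                _stage_indices(out)
            elif stage == "cgm":
                _stage_cgm(out, interval_min=config.cgm_interval_min)
            elif stage == "trial":
                _stage_trial(out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        executed.append(stage)

    subjects = pd.read_csv(out / "subjects.csv")
    counts = {}
    for arm, grp in subjects.groupby("arm"):
        counts[arm] = {
            "randomised": int(len(grp)),
            "completed": int(grp["completer"].sum()),
            "completion_pct": _pct(int(grp["completer"].sum()), len(grp)),
        }
    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": _versions(),
        "stages_executed": executed,
        "files": sorted(str(p.name) for p in out.iterdir() if p.is_file()),
        "consort": counts,
        "analysed": int(subjects["completer"].sum()),
    }
    for arm in counts:
        assert counts[arm]["completed"] <= counts[arm]["randomised"]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _versions() -> dict:
    import scipy

    return {
        "mmtt_metab": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }
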