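"""Closed-form metabolic indices and dietary prescriptions.

Surrogate insulin-resistance indices (HOMA-IR, Matsuda), insulin clearance
from secretion/insulin ratios, the fatty liver index, HbA1c unit
conversion between IFCC (mmol/mol) and NGSP (%) scales, Harris-Benedict
resting energy expenditure with an energy-deficit prescription, and
macronutrient energy fractions of a meal.

Unit conventions follow routine European clinical reporting: glucose in
mmol/l, insulin and C-peptide in pmol/l, triglycerides in mmol/l (converted
internally to mg/dl where an index was defined on conventional units).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FastingPanel",
    "MealComposition",
    "EnergyPrescription",
    "body_surface_area",
    "homa_ir",
    "matsuda",
    "insulin_clearance",
    "fatty_liver_index",
    "hba1c_ifcc_to_ngsp",
    "hba1c_ngsp_to_ifcc",
    "energy_fractions",
    "energy_requirement",
]

#: pmol/l of insulin per microU/ml (WHO 1st IRP 66/304 conversion).
PMOL_PER_MICROU = 6.0
#: mg/dl per mmol/l of glucose.
GLUCOSE_MGDL_PER_MMOL = 18.016
#: mg/dl per mmol/l of triglycerides.
TG_MGDL_PER_MMOL = 88.57
#: kJ per kcal.
KJ_PER_KCAL = 4.184
#: Atwater general factors, kcal per gram.
ATWATER_KCAL_PER_G = {"carb": 4.0, "protein": 4.0, "fat": 9.0}
#: Energy density of lost body mass, kJ per kg (7700 kcal/kg), used to size
#: the daily deficit of a weight-loss prescription.
BODY_ENERGY_KJ_PER_KG = 32_220.0

# IFCC <-> NGSP master equation: NGSP% = 0.09148 * IFCC + 2.152
_NGSP_SLOPE = 0.09148
_NGSP_INTERCEPT = 2.152


@dataclass(frozen=True)
class FastingPanel:
    """Fasting biochemistry and anthropometry for index computation.

    All concentrations in SI units (glucose mmol/l, insulin pmol/l,
    triglycerides mmol/l, GGT IU/l); ``hba1c_ifcc`` in mmol/mol.
    """

    glucose: float
    insulin: float
    triglycerides: float | None = None
    ggt: float | None = None
    bmi: float | None = None
    waist: float | None = None
    hba1c_ifcc: float | None = None

    def __post_init__(self) -> None:
        for name in ("glucose", "insulin", "triglycerides", "ggt", "bmi", "waist", "hba1c_ifcc"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")


@dataclass(frozen=True)
class MealComposition:
    """Macronutrient content of a meal; grams plus labelled total energy (kJ)."""

    carb_g: float
    fat_g: float
    protein_g: float
    energy_kj: float

    def __post_init__(self) -> None:
        if min(self.carb_g, self.fat_g, self.protein_g) < 0:
            raise ValueError("macronutrient grams must be >= 0")
        if self.energy_kj <= 0:
            raise ValueError("energy_kj must be > 0")


@dataclass(frozen=True)
class EnergyPrescription:
    """Daily energy prescription with its Harris-Benedict components (kJ/day)."""

    prescribed_kj: float
    ree_kj: float
    activity_kj: float
    daily_deficit_kj: float
    below_08_ree: bool  # prescription < 0.8 * REE: flagged, not rejected


def body_surface_area(height_cm: float, weight_kg: float) -> float:
    """Du Bois body surface area in m**2: 0.007184 * W^0.425 * H^0.725."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


def homa_ir(glucose_mmol_l: float, insulin_pmol_l: float) -> float:
    """HOMA-IR = fasting glucose (mmol/l) x fasting insulin (microU/ml) / 22.5.

    Insulin is converted from pmol/l at 6.0 pmol/l per microU/ml.
    """
    if glucose_mmol_l <= 0 or insulin_pmol_l <= 0:
        raise ValueError("glucose and insulin must be > 0")
    return glucose_mmol_l * (insulin_pmol_l / PMOL_PER_MICROU) / 22.5


def _trapz_mean(time: np.ndarray, y: np.ndarray) -> float:
    """Time-weighted (trapezoidal) mean of a sampled series."""
    span = time[-1] - time[0]
    if span <= 0:
        return float(y[0])
    return float(np.trapezoid(y, time) / span)


def matsuda(
    time_min: np.ndarray,
    glucose_mmol_l: np.ndarray,
    insulin_pmol_l: np.ndarray,
    variant: str = "full",
) -> float:
    """Matsuda whole-test insulin sensitivity index.

    10000 / sqrt(G0 * I0 * Gmean * Imean) with glucose in mg/dl and insulin
    in microU/ml. ``variant="full"`` (default) takes trapezoidal time-weighted
    means over the whole sampled test, appropriate for a 180 min test on a
    non-uniform grid; ``variant="0-120"`` takes the unweighted mean of samples
    at 0-120 min (the classic OGTT form).
    """
    time = np.asarray(time_min, dtype=float)
    g = np.asarray(glucose_mmol_l, dtype=float) * GLUCOSE_MGDL_PER_MMOL
    ins = np.asarray(insulin_pmol_l, dtype=float) / PMOL_PER_MICROU
    if time.shape != g.shape or time.shape != ins.shape:
        raise ValueError("time, glucose and insulin must have equal length")
    if not np.any(time == 0):
        raise ValueError("series must include a t=0 sample")
    if np.any(g <= 0) or np.any(ins <= 0):
        raise ValueError("concentrations must be > 0")
    i0 = int(np.flatnonzero(time == 0)[0])
    g0, ins0 = g[i0], ins[i0]
    if variant == "full":
        gbar, ibar = _trapz_mean(time, g), _trapz_mean(time, ins)
    elif variant == "0-120":
        m = (time >= 0) & (time <= 120)
        gbar, ibar = float(g[m].mean()), float(ins[m].mean())
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return 10_000.0 / float(np.sqrt(g0 * ins0 * gbar * ibar))


def insulin_clearance(
    isr_time_min: np.ndarray,
    isr_pmol_min: np.ndarray,
    insulin_time_min: np.ndarray,
    insulin_pmol_l: np.ndarray,
    mode: str = "total",
) -> float:
    """Insulin clearance as an ISR/insulin ratio (l/min).

    ``mode="fasting"`` uses the t=0 values, ``mode="total"`` the ratio of
    trapezoidal AUCs over the common sampling window. ISR in pmol/min and
    insulin in pmol/l give the ratio the dimension of a volume flow.
    """
    it = np.asarray(isr_time_min, float)
    isr = np.asarray(isr_pmol_min, float)
    jt = np.asarray(insulin_time_min, float)
    ins = np.asarray(insulin_pmol_l, float)
    if mode == "fasting":
        s0 = isr[int(np.flatnonzero(it == it.min())[0])]
        i0 = ins[int(np.flatnonzero(jt == jt.min())[0])]
        if i0 == 0:
            raise ZeroDivisionError("fasting insulin is zero")
        return float(s0 / i0)
    if mode == "total":
        auc_s = np.trapezoid(isr, it)
        auc_i = np.trapezoid(ins, jt)
        if auc_i == 0:
            raise ZeroDivisionError("insulin AUC is zero")
        return float(auc_s / auc_i)
    raise ValueError(f"unknown mode {mode!r}")


def fatty_liver_index(
    triglycerides_mmol_l: float,
    bmi: float,
    ggt_iu_l: float,
    waist_cm: float,
) -> float:
    """Fatty liver index (0-100), the logistic steatosis score of Bedogni et al.

    y = 0.953 ln(TG mg/dl) + 0.139 BMI + 0.718 ln(GGT) + 0.053 waist - 15.745;
    FLI = e^y / (1 + e^y) * 100. Triglycerides are taken in mmol/l and
    converted to mg/dl (x88.57) internally, matching the index's original
    definition on conventional units.
    """
    if min(triglycerides_mmol_l, bmi, ggt_iu_l, waist_cm) <= 0:
        raise ValueError("all fatty liver index inputs must be > 0")
    tg_mgdl = triglycerides_mmol_l * TG_MGDL_PER_MMOL
    y = 0.953 * np.log(tg_mgdl) + 0.139 * bmi + 0.718 * np.log(ggt_iu_l) + 0.053 * waist_cm - 15.745
    return float(100.0 / (1.0 + np.exp(-y)))


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def hba1c_ifcc_to_ngsp(ifcc_mmol_mol: float, rounded: bool = True) -> float:
    """Convert HbA1c from IFCC mmol/mol to NGSP percent.

    NGSP% = 0.09148 x IFCC + 2.152 (the IFCC/NGSP master equation); display
    rounding is half-up to one decimal, the convention of clinical reports.
    """
    if not 20 <= ifcc_mmol_mol <= 200:
        raise ValueError("IFCC HbA1c outside the plausible 20-200 mmol/mol range")
    pct = _NGSP_SLOPE * ifcc_mmol_mol + _NGSP_INTERCEPT
    return _round_half_up(pct) if rounded else pct


def hba1c_ngsp_to_ifcc(ngsp_percent: float) -> float:
    """Inverse of the IFCC->NGSP master equation (unrounded)."""
    return (ngsp_percent - _NGSP_INTERCEPT) / _NGSP_SLOPE


def energy_fractions(meal: MealComposition, rounded: bool = True) -> dict[str, float]:
    """Percent of a meal's labelled energy from each macronutrient.

    Uses Atwater general factors (carbohydrate 4, protein 4, fat 9 kcal/g at
    4.184 kJ/kcal) against the *stated* total energy; fractions are not
    renormalized to sum to 100 because label totals may be internally
    inconsistent.
    """
    out = {}
    for key, grams in (("carb", meal.carb_g), ("fat", meal.fat_g), ("protein", meal.protein_g)):
        kj = grams * ATWATER_KCAL_PER_G[key] * KJ_PER_KCAL
        pct = 100.0 * kj / meal.energy_kj
        out[key] = _round_half_up(pct) if rounded else pct
    return out


def harris_benedict_ree(sex: str, age_years: float, weight_kg: float, height_cm: float) -> float:
    """Harris-Benedict resting energy expenditure, kJ/day (original equations)."""
    if min(age_years, weight_kg, height_cm) <= 0:
        raise ValueError("anthropometrics must be positive")
    s = sex.upper()[0]
    if s == "M":
        kcal = 66.4730 + 13.7516 * weight_kg + 5.0033 * height_cm - 6.7550 * age_years
    elif s in ("F", "W"):
        kcal = 655.0955 + 9.5634 * weight_kg + 1.8496 * height_cm - 4.6756 * age_years
    else:
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    return kcal * KJ_PER_KCAL


def energy_requirement(
    sex: str,
    age_years: float,
    weight_kg: float,
    height_cm: float,
    activity_kj: float = 0.0,
    target_loss_fraction: float = 0.0,
    weeks: int = 12,
) -> EnergyPrescription:
    """Daily energy prescription for a fractional weight-loss target.

    Total expenditure is Harris-Benedict REE plus the stated activity energy.
    The daily deficit is sized so that the cumulative deficit over ``weeks``
    equals ``target_loss_fraction x weight x 32220 kJ/kg`` (7700 kcal per kg
    of body mass lost). A prescription below 0.8 x REE is flagged, not
    rejected.
    """
    if not 0 <= target_loss_fraction < 0.2:
        raise ValueError("target_loss_fraction must be in [0, 0.2)")
    if activity_kj < 0:
        raise ValueError("activity_kj must be >= 0")
    if weeks < 1:
        raise ValueError("weeks must be >= 1")
    ree = harris_benedict_ree(sex, age_years, weight_kg, height_cm)
    deficit = target_loss_fraction * weight_kg * BODY_ENERGY_KJ_PER_KG / (weeks * 7)
    prescribed = ree + activity_kj - deficit
    return EnergyPrescription(
        prescribed_kj=prescribed,
        ree_kj=ree,
        activity_kj=activity_kj,
        daily_deficit_kj=deficit,
        below_08_ree=prescribed < 0.8 * ree,
    )
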