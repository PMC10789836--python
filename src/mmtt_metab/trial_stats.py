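"""Statistical machinery of a two-arm randomized dietary trial.

Covers the trial's analysis plan: Monte-Carlo power of the two-sided
Mann-Whitney U test (the sample-size justification), two-way repeated
measures ANOVA with diet (visit), group and diet x group effects, the
within-meal-test variant adding a time factor, nonparametric two-group
comparisons (Mann-Whitney, Fisher exact), Spearman rank correlation,
stratification into extreme tertiles of after-lunch carbohydrate share,
and dual-assessor food-diary reconciliation with a 20% dispute rule.

All tests are two-sided at alpha = 0.05 with no multiplicity adjustment,
and longitudinal models use complete cases only (subjects missing any
visit are dropped and counted), matching common practice in small
dietary RCTs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "power_mannwhitney",
    "rm_anova",
    "mmtt_anova",
    "compare_groups",
    "spearman",
    "tertile_stratify",
    "reconcile_diaries",
]

ARMS = ("eTRC", "Med")
AFTER_LUNCH_MEALS = ("dinner", "other")


# ---------------------------------------------------------------------------
# Mann-Whitney exact machinery and power simulation


def mannwhitney_exact_pvalues(n: int, m: int) -> np.ndarray:
    """Two-sided exact p-value lookup table for the Mann-Whitney U statistic.

    Entry u holds 2*min(P(U<=u), P(U>=u)) (capped at 1) under the null for
    continuous data, from the exact null distribution: the number of rank
    configurations with U = u is the number of integer partitions of u
    fitting in an n x m box (Gaussian binomial coefficient), built here by
    exact polynomial multiplication/division. Exact in double precision for
    n, m <= 25.
    """
    nm = n * m
    counts = np.zeros(nm + 1)
    counts[0] = 1.0
    # prod_{i=1..n} (1 - q^{m+i}) / (1 - q^i), all divisions exact
    for i in range(1, n + 1):
        if m + i <= nm:
            counts[m + i :] -= counts[: nm + 1 - (m + i)].copy()
        for j in range(i, nm + 1):  # divide by (1 - q^i): running sum, stride i
            counts[j] += counts[j - i]
    total = counts.sum()
    cdf = np.cumsum(counts) / total
    sf = np.cumsum(counts[::-1])[::-1] / total
    return np.minimum(1.0, 2.0 * np.minimum(cdf, sf))


def power_mannwhitney(
    n_per_group: int,
    delta: float,
    sd: float,
    alpha: float = 0.05,
    reps: int = 10_000,
    seed: int = 0,
    n_other: int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo power of the two-sided Mann-Whitney U test for a location
    shift between two normal populations.

    Each replicate draws N(0, sd) vs N(delta, sd) samples and rejects when
    the two-sided p-value is <= alpha; p-values are exact (enumerated null
    distribution) for groups up to 25, otherwise the continuity-corrected
    normal approximation. Returns (power, binomial SE).
    """
    n, m = n_per_group, n_other if n_other is not None else n_per_group
    if min(n, m) < 3:
        raise ValueError("need at least 3 per group")
    if reps < 1000:
        raise ValueError("reps must be >= 1000 for a stable estimate")
    if delta <= 0 or sd <= 0:
        raise ValueError("delta and sd must be > 0 (power is for a real shift)")
    rng = np.random.default_rng(seed)
    exact = max(n, m) <= 25
    ptable = mannwhitney_exact_pvalues(n, m) if exact else None
    rejections = 0
    chunk = 2000
    done = 0
    while done < reps:
        r = min(chunk, reps - done)
        x = rng.normal(0.0, sd, size=(r, n))
        y = rng.normal(delta, sd, size=(r, m))
        u1 = _u_statistic(x, y)
        if exact:
            p = ptable[u1.astype(int)]
        else:
            mu, sig = n * m / 2.0, np.sqrt(n * m * (n + m + 1) / 12.0)
            z = (np.abs(u1 - mu) - 0.5) / sig
            p = 2.0 * scipy.stats.norm.sf(z)
        rejections += int(np.sum(p <= alpha))
        done += r
    power = rejections / reps
    return power, float(np.sqrt(power * (1.0 - power) / reps))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """U of the first sample, per row, via midranks (ties get average rank)."""
    n = x.shape[1]
    data = np.concatenate([x, y], axis=1)
    ranks = scipy.stats.rankdata(data, axis=1)
    r1 = ranks[:, :n].sum(axis=1)
    return r1 - n * (n + 1) / 2.0


def null_power_mannwhitney(
    n_per_group: int, sd: float, alpha: float = 0.05, reps: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Rejection rate under the null (delta = 0); calibration companion to
    :func:`power_mannwhitney`."""
    rng = np.random.default_rng(seed)
    n = n_per_group
    ptable = mannwhitney_exact_pvalues(n, n)
    x = rng.normal(0.0, sd, size=(reps, n))
    y = rng.normal(0.0, sd, size=(reps, n))
    p = ptable[_u_statistic(x, y).astype(int)]
    rate = float(np.mean(p <= alpha))
    return rate, float(np.sqrt(rate * (1 - rate) / reps))


# ---------------------------------------------------------------------------
# Two-group comparisons and correlation


def compare_groups(x, y=None, kind: str = "mannwhitney") -> tuple[float, float]:
    """Two-sided two-group test: Mann-Whitney U on two samples, or Fisher's
    exact test on a 2x2 count table (pass the table as ``x``).

    Mann-Whitney is exact (full enumeration) when both groups have n <= 10
    and there are no ties, otherwise the tie-corrected normal approximation.
    Returns (statistic, p).
    """
    if kind == "fisher":
        table = np.asarray(x)
        if table.shape != (2, 2):
            raise ValueError("Fisher's exact test needs a 2x2 count table")
        res = scipy.stats.fisher_exact(table, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if kind == "mannwhitney":
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if len(x) == 0 or len(y) == 0:
            raise ValueError("empty group")
        ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (max(len(x), len(y)) <= 10 and not ties) else "asymptotic"
        res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test kind {kind!r}")


def spearman(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value is an exhaustive permutation p (all n! relabelings of y)
    for n <= ``exact_max_n``, otherwise the usual t approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d arrays")
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 pairs")
    rho, p_t = scipy.stats.spearmanr(x, y)
    if n > exact_max_n:
        return float(rho), float(p_t)
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rxc = rx - rx.mean()
    perms = np.array(list(itertools.permutations(ry)))
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc @ rxc) * np.einsum("ij,ij->i", pc, pc))
    rhos = (pc @ rxc) / denom
    p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return float(rho), p


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA


def _complete_case_pivot(
    table: pd.DataFrame, variable: str, index_cols: list[str]
) -> tuple[pd.DataFrame, int]:
    sub = table[table["variable"] == variable] if "variable" in table.columns else table
    if sub.empty:
        raise ValueError(f"no rows for variable {variable!r}")
    wide = sub.pivot_table(index=["subject_id", "arm"], columns=index_cols, values="value")
    complete = wide.dropna()
    return complete, len(wide) - len(complete)


def rm_anova(
    table: pd.DataFrame, variable: str, correction: bool = False
) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA: within factor visit (diet effect),
    between factor group, and their interaction, on complete cases.

    ``table`` is long-format with columns subject_id, arm, visit_week,
    variable, value. Classical mixed ANOVA F tests (via pingouin);
    ``correction=True`` applies Greenhouse-Geisser to the within terms.
    Returns a tidy effect table with rows diet, group, diet x group; the
    number of dropped (incomplete) subjects is in ``.attrs["dropped"]``.
    """
    import pingouin as pg

    complete, dropped = _complete_case_pivot(table, variable, ["visit_week"])
    arms = complete.index.get_level_values("arm")
    counts = pd.Series(arms).value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("each group needs at least 2 complete subjects")
    long = complete.stack().rename("value").reset_index()
    aov = pg.mixed_anova(
        data=long, dv="value", within="visit_week", subject="subject_id",
        between="arm", correction=correction,
    )
    gg = next((c for c in aov.columns if "GG" in c), None)
    pcol = gg if correction and gg else "p_unc"
    rows = {"arm": "group", "visit_week": "diet", "Interaction": "diet x group"}
    out = pd.DataFrame(
        {
            "effect": [rows[s] for s in aov["Source"]],
            "F": aov["F"].to_numpy(float),
            "df1": aov["DF1"].to_numpy(float),
            "df2": aov["DF2"].to_numpy(float),
            "p": aov[pcol].fillna(aov["p_unc"]).to_numpy(float),
        }
    ).set_index("effect").loc[["diet", "group", "diet x group"]].reset_index()
    out.attrs["dropped"] = dropped
    out.attrs["n_complete"] = counts.to_dict()
    return out


def _stratum(z: np.ndarray, groups: np.ndarray, levels: np.ndarray) -> tuple[float, float, float, int, int]:
    """Within-subject stratum SS for one centered factor array z (N x L).

    Returns (SS_factor, SS_factor_x_group, SS_error, df_factor, df_error);
    the error term is the factor x subject(group) interaction.
    """
    n, nl = z.shape
    a = len(levels)
    ss_f = n * float(np.sum(z.mean(axis=0) ** 2))
    ss_cells = 0.0
    ss_err = 0.0
    for gl in levels:
        zg = z[groups == gl]
        ss_cells += len(zg) * float(np.sum(zg.mean(axis=0) ** 2))
        ss_err += float(np.sum((zg - zg.mean(axis=0)) ** 2))
    return ss_f, ss_cells - ss_f, ss_err, nl - 1, (nl - 1) * (n - a)


def _f_row(effect: str, ss: float, df1: int, ss_err: float, df_err: int) -> dict:
    ms, ms_err = ss / df1, ss_err / df_err
    f = ms / ms_err if ms_err > 0 else np.nan
    return {
        "effect": effect, "F": f, "df1": float(df1), "df2": float(df_err),
        "p": float(scipy.stats.f.sf(f, df1, df_err)) if np.isfinite(f) else np.nan,
    }


def mmtt_anova(table: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Repeated-measures ANOVA for series measured *within* each meal test:
    within factors visit (diet) and MMTT time, between factor group.

    Classical split-plot stratum partition on complete cases: the group
    effect is tested against subject(group); each within factor and its
    group interaction against its own factor x subject(group) error stratum.
    ``table`` is long-format with columns subject_id, arm, visit_week,
    time_min, value (and optionally variable). Returns the full effect table
    (group, diet, time, and interactions).
    """
    complete, dropped = _complete_case_pivot(table, variable, ["visit_week", "time_min"])
    arms = np.asarray(complete.index.get_level_values("arm"))
    levels = np.unique(arms)
    if len(levels) < 2 or min((arms == g).sum() for g in levels) < 2:
        raise ValueError("each group needs at least 2 complete subjects")
    visits = complete.columns.get_level_values(0).unique().sort_values()
    times = complete.columns.get_level_values(1).unique().sort_values()
    nv, nt = len(visits), len(times)
    y = complete.to_numpy().reshape(len(complete), nv, nt)
    n = len(y)

    y_s = y.mean(axis=(1, 2))
    y_sv = y.mean(axis=2)
    y_st = y.mean(axis=1)

    # between stratum: one-way ANOVA on subject means (scaled SS cancels in F)
    grand = y_s.mean()
    ss_g = sum((arms == gl).sum() * (y_s[arms == gl].mean() - grand) ** 2 for gl in levels)
    ss_s = sum(np.sum((y_s[arms == gl] - y_s[arms == gl].mean()) ** 2) for gl in levels)
    rows = [_f_row("group", ss_g * nv * nt, len(levels) - 1, ss_s * nv * nt, n - len(levels))]

    if nv > 1:
        z = y_sv - y_s[:, None]
        ss_f, ss_fg, ss_e, df1, dfe = _stratum(z, arms, levels)
        rows.append(_f_row("diet", ss_f * nt, df1, ss_e * nt, dfe))
        rows.append(_f_row("diet x group", ss_fg * nt, df1 * (len(levels) - 1), ss_e * nt, dfe))
    if nt > 1:
        z = y_st - y_s[:, None]
        ss_f, ss_fg, ss_e, df1, dfe = _stratum(z, arms, levels)
        rows.append(_f_row("time", ss_f * nv, df1, ss_e * nv, dfe))
        rows.append(_f_row("time x group", ss_fg * nv, df1 * (len(levels) - 1), ss_e * nv, dfe))
    if nv > 1 and nt > 1:
        w = y - y_sv[:, :, None] - y_st[:, None, :] + y_s[:, None, None]
        wf = w.reshape(n, nv * nt)
        ss_f, ss_fg, ss_e, _, _ = _stratum(wf, arms, levels)
        df1 = (nv - 1) * (nt - 1)
        dfe = df1 * (n - len(levels))
        rows.append(_f_row("time x diet", ss_f, df1, ss_e, dfe))
        rows.append(_f_row("time x diet x group", ss_fg, df1 * (len(levels) - 1), ss_e, dfe))

    out = pd.DataFrame(rows)
    out.attrs["dropped"] = dropped
    return out


# ---------------------------------------------------------------------------
# Exploratory tertile stratification


def after_lunch_carb_share(diaries: pd.DataFrame) -> pd.Series:
    """Per-subject median (across diary days) percentage of daily
    carbohydrate grams consumed after lunch (dinner + later snacks)."""
    need = {"subject_id", "day", "meal", "carb_g"}
    if not need <= set(diaries.columns):
        raise ValueError(f"diaries must have columns {sorted(need)}")
    per_day = diaries.groupby(["subject_id", "day"]).apply(
        lambda d: 100.0 * d.loc[d["meal"].isin(AFTER_LUNCH_MEALS), "carb_g"].sum()
        / d["carb_g"].sum(),
        include_groups=False,
    )
    return per_day.groupby("subject_id").median().rename("after_lunch_carb_pct")


def tertile_stratify(diaries: pd.DataFrame, outcomes: pd.DataFrame) -> dict:
    """Compare outcome changes between extreme tertiles of after-lunch
    carbohydrate share.

    Cuts the per-subject shares at the empirical 33.3/66.7 percentiles and
    runs a Mann-Whitney test (first vs third tertile) for every outcome
    column of ``outcomes`` (indexed or keyed by subject_id). Returns the
    per-subject metric, tertile assignment and a test table.
    """
    metric = after_lunch_carb_share(diaries)
    if len(metric) < 6:
        raise ValueError("tertile stratification needs at least 6 subjects")
    q1, q2 = np.percentile(metric, [100.0 / 3.0, 200.0 / 3.0])
    if q1 == q2:
        raise ValueError("degenerate tertiles: after-lunch carbohydrate shares are tied")
    tertile = pd.Series(
        np.where(metric <= q1, 1, np.where(metric > q2, 3, 2)), index=metric.index,
        name="tertile",
    )
    out = outcomes.set_index("subject_id") if "subject_id" in outcomes.columns else outcomes
    t1_ids = tertile[tertile == 1].index
    t3_ids = tertile[tertile == 3].index
    tests = []
    for col in out.columns:
        x = out.loc[out.index.intersection(t1_ids), col].dropna().to_numpy(float)
        y = out.loc[out.index.intersection(t3_ids), col].dropna().to_numpy(float)
        stat, p = compare_groups(x, y, kind="mannwhitney")
        tests.append({"outcome": col, "U": stat, "p": p, "n_t1": len(x), "n_t3": len(y)})
    return {"metric": metric, "tertile": tertile, "tests": pd.DataFrame(tests)}


# ---------------------------------------------------------------------------
# Food-diary reconciliation


@dataclass(frozen=True)
class DiaryConsensus:
    """Consensus of independent diary assessments for one subject-diary."""

    subject_id: str
    energy_kj: float
    carb_g: float
    flagged: bool
    n_assessors: int
    rel_diff_energy: float | None
    rel_diff_carb: float | None


def _rel_diff(a: float, b: float) -> float:
    m = 0.5 * (a + b)
    return abs(a - b) / m if m > 0 else 0.0


def reconcile_diaries(assessments: pd.DataFrame, threshold: float = 0.20) -> pd.DataFrame:
    """Reconcile dual-assessor diary estimates with a dispute rule.

    ``assessments`` has one row per subject x assessor with columns
    subject_id, assessor_id, energy_kj, carb_g. If the two primary
    assessments differ by >= ``threshold`` (relative to their mean) on
    energy *or* carbohydrate, the diary is flagged; a third assessment, when
    present, resolves the dispute by the median of the three, otherwise the
    consensus stays the pairwise mean but keeps the flag. Single assessments
    pass through flagged.
    """
    rows = []
    for sid, grp in assessments.groupby("subject_id", sort=False):
        e = grp["energy_kj"].to_numpy(float)
        c = grp["carb_g"].to_numpy(float)
        if np.any(e < 0) or np.any(c < 0):
            raise ValueError("assessment values must be >= 0")
        if len(grp) == 1:
            rows.append(DiaryConsensus(sid, e[0], c[0], True, 1, None, None))
            continue
        rde, rdc = _rel_diff(e[0], e[1]), _rel_diff(c[0], c[1])
        disputed = rde >= threshold or rdc >= threshold
        if disputed and len(grp) >= 3:
            rows.append(DiaryConsensus(sid, float(np.median(e[:3])), float(np.median(c[:3])),
                                       True, 3, rde, rdc))
        else:
            rows.append(DiaryConsensus(sid, float(e[:2].mean()), float(c[:2].mean()),
                                       disputed, 2, rde, rdc))
    return pd.DataFrame([r.__dict__ for r in rows])
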