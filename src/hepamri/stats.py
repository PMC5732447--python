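"""Cohort statistics: group comparisons, correlations, agreement, summaries.

Implements the statistical battery applied to animal-level data: pooled
two-sample t tests (from raw data or printed summaries), Mann-Whitney U
with a normal approximation (tie and continuity corrected) or exact
enumeration, Pearson/Spearman correlations, two-way random-effects
absolute-agreement single-measure intraclass correlation ICC(2,1), and
per-animal percent-change summaries against the control-group mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatsResult",
    "ICCResult",
    "independent_t",
    "t_from_summaries",
    "mann_whitney",
    "icc_two_way",
    "correlate",
    "percent_change",
    "build_report",
    "MR_VARIABLES",
    "REFERENCE_VARIABLES",
    "DEFAULT_TEST_ROUTING",
]

MR_VARIABLES = ["Dslow", "Dfast", "PF", "MD", "FA", "R2star"]
REFERENCE_VARIABLES = [
    "ALT", "AST", "LDH", "MDA", "MPO", "SOD", "I_score", "F_score",
]

#: Which two-group test each cohort variable gets by default: variables
#: summarized as mean +/- SD go to the t test, those summarized as
#: median(IQR) (skewed enzymes) and the ordinal histology scores go to
#: Mann-Whitney.
DEFAULT_TEST_ROUTING: dict[str, str] = {
    **{v: "t" for v in MR_VARIABLES},
    "MDA": "t", "MPO": "t", "SOD": "t",
    "ALT": "mann_whitney", "AST": "mann_whitney", "LDH": "mann_whitney",
    "I_score": "mann_whitney", "F_score": "mann_whitney",
}


@dataclass(frozen=True)
class StatsResult:
    test: str
    statistic: float
    p_value: float
    n1: int
    n2: int = 0
    estimate: float | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str = "ICC(2,1)"
    degenerate: bool = False


def independent_t(a, b) -> StatsResult:
    """Pooled-variance two-sample t test, two-sided.

    Sign convention: the statistic carries the sign of mean(a) - mean(b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least two values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) != np.mean(b):
            raise ValueError("zero pooled variance with unequal means")
        return StatsResult("t", 0.0, 1.0, a.size, b.size)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return StatsResult("t", float(t), float(p), a.size, b.size)


def t_from_summaries(m1, s1, n1, m2, s2, n2) -> StatsResult:
    """Pooled-variance t from group means, SDs and sizes.

    Identical to :func:`independent_t` applied to any raw data with
    exactly these summaries.
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    t, p = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return StatsResult("t", float(t), float(p), int(n1), int(n2))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: number of (a_i, b_j) pairs with a_i > b_j plus half-ties."""
    ranks = sps.rankdata(np.concatenate([a, b]))
    r1 = ranks[: a.size].sum()
    return float(r1 - a.size * (a.size + 1) / 2.0)


def mann_whitney(a, b, method: str = "asymptotic") -> StatsResult:
    """Mann-Whitney U test.

    ``method`` "asymptotic" uses the normal approximation with tie and
    continuity corrections; "exact" enumerates the permutation null (no
    ties assumed for the exact path).  The reported statistic is the
    Z value of the approximation; the U statistic is in ``estimate``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups need at least one value")
    n1, n2 = a.size, b.size
    u = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return StatsResult("mann_whitney", 0.0, 1.0, n1, n2, estimate=u)
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    z = (u - mu - 0.5 * np.sign(u - mu)) / sigma if u != mu else 0.0
    if method == "exact":
        p = float(
            sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        )
    elif method == "asymptotic":
        p = float(2.0 * sps.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return StatsResult("mann_whitney", float(z), p, n1, n2, estimate=u)


def mann_whitney_z_uncorrected(a, b) -> float:
    """Normal-approximation Z without the continuity correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    u = _u_statistic(a, b)
    n = n1 + n2
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    return float((u - n1 * n2 / 2.0) / sigma)


def icc_two_way(obs1, obs2) -> ICCResult:
    """Interobserver ICC(2,1): two-way random effects, absolute agreement,
    single measure, with the F-based 95% confidence interval.

    Computed from the two-way ANOVA mean squares of the subjects x raters
    table (Shrout & Fleiss conventions; McGraw & Wong interval).
    """
    obs1 = np.asarray(obs1, dtype=float)
    obs2 = np.asarray(obs2, dtype=float)
    if obs1.size != obs2.size or obs1.size < 3:
        raise ValueError("need two equal-length series of at least 3 subjects")
    if np.allclose(obs1, obs1[0]) and np.allclose(obs2, obs2[0]):
        return ICCResult(np.nan, np.nan, np.nan, degenerate=True)
    if np.array_equal(obs1, obs2):
        return ICCResult(1.0, 1.0, 1.0)

    x = np.stack([obs1, obs2], axis=1)  # subjects x raters
    n, k = x.shape
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    msr = k * np.sum((row_m - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_m - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_m[:, None] - col_m[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = float((msr - mse) / denom)

    alpha = 0.05
    r = icc
    a = k * r / (n * (1.0 - r)) if r < 1 else np.inf
    b = 1.0 + k * r * (n - 1) / (n * (1.0 - r)) if r < 1 else np.inf
    if mse <= 0 or not np.isfinite(a):
        return ICCResult(icc, icc, icc)
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = sps.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_u = sps.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lo = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return ICCResult(icc, float(min(lo, icc)), float(max(hi, icc)))


def correlate(x, y, method: str = "spearman") -> StatsResult:
    """Pearson or Spearman correlation with two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length series of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return StatsResult(method, np.nan, np.nan, x.size, estimate=np.nan)
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return StatsResult(method, float(r), float(p), x.size, estimate=float(r))


def percent_change(control, model, direction: str = "decrease") -> tuple[float, float]:
    """Per-animal percent change of the model group vs the control mean.

    For each model animal x the change is 100*(mean(control) - x)/mean(control)
    when ``direction`` is "decrease", with the sign flipped for
    "increase".  Returns (mean, SD) over model animals (SD with n-1
    normalization; 0 for a single animal).
    """
    control = np.asarray(control, dtype=float)
    model = np.asarray(model, dtype=float)
    if control.size == 0 or model.size == 0:
        raise ValueError("both groups must be nonempty")
    ref = control.mean()
    if ref == 0:
        raise ValueError("control mean is zero")
    pc = 100.0 * (ref - model) / ref
    if direction == "increase":
        pc = -pc
    elif direction != "decrease":
        raise ValueError(f"unknown direction {direction!r}")
    sd = float(pc.std(ddof=1)) if pc.size > 1 else 0.0
    return float(pc.mean()), sd


def build_report(
    cohort: pd.DataFrame,
    routing: dict[str, str] | None = None,
    correlation_method: str = "spearman",
    observer_cols: tuple[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble the cohort statistics report.

    Parameters
    ----------
    cohort : one row per animal with a ``group`` column ("control" /
        "model") and the MR / biochemical / histology variables.
    routing : per-variable test choice ("t" | "mann_whitney");
        defaults to :data:`DEFAULT_TEST_ROUTING`.
    observer_cols : optional suffix pair, e.g. ("_obs1", "_obs2").  When
        given, interobserver ICC is computed for each MR variable from
        ``<var><suffix>`` column pairs.

    Returns a dict of DataFrames: "group_comparison", "correlations"
    (r and p for each MR x reference pair), "percent_change", and
    "icc" when observer columns are present.
    """
    routing = dict(DEFAULT_TEST_ROUTING, **(routing or {}))
    groups = set(cohort["group"].unique())
    ctrl = cohort[cohort["group"] == "control"]
    modl = cohort[cohort["group"] == "model"]
    two_groups = len(ctrl) > 0 and len(modl) > 0

    out: dict[str, pd.DataFrame] = {}

    rows = []
    variables = [
        v for v in MR_VARIABLES + REFERENCE_VARIABLES if v in cohort.columns
    ]
    if two_groups:
        for var in variables:
            a = ctrl[var].to_numpy()
            b = modl[var].to_numpy()
            kind = routing.get(var, "t")
            res = (
                independent_t(a, b) if kind == "t" else mann_whitney(a, b)
            )
            rows.append(
                {
                    "variable": var,
                    "control_mean": a.mean(),
                    "control_sd": a.std(ddof=1),
                    "model_mean": b.mean(),
                    "model_sd": b.std(ddof=1),
                    "test": res.test,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                }
            )
    out["group_comparison"] = pd.DataFrame(rows)

    corr_rows = []
    for mr in MR_VARIABLES:
        if mr not in cohort.columns:
            continue
        for ref in REFERENCE_VARIABLES:
            if ref not in cohort.columns:
                continue
            res = correlate(
                cohort[mr].to_numpy(), cohort[ref].to_numpy(),
                method=correlation_method,
            )
            corr_rows.append(
                {"mr": mr, "reference": ref, "r": res.estimate,
                 "p_value": res.p_value, "n": res.n1}
            )
    out["correlations"] = pd.DataFrame(corr_rows)

    pc_rows = []
    if two_groups:
        for var, direction in (
            ("Dfast", "decrease"), ("PF", "decrease"), ("R2star", "increase"),
        ):
            if var not in cohort.columns:
                continue
            m, s = percent_change(
                ctrl[var].to_numpy(), modl[var].to_numpy(), direction
            )
            pc_rows.append(
                {"variable": var, "direction": direction,
                 "mean_pct": m, "sd_pct": s}
            )
    out["percent_change"] = pd.DataFrame(pc_rows)

    if observer_cols is not None:
        s1, s2 = observer_cols
        icc_rows = []
        for var in MR_VARIABLES:
            c1, c2 = f"{var}{s1}", f"{var}{s2}"
            if c1 not in cohort.columns or c2 not in cohort.columns:
                continue
            r = icc_two_way(cohort[c1].to_numpy(), cohort[c2].to_numpy())
            icc_rows.append(
                {"variable": var, "icc": r.icc, "ci_low": r.ci_low,
                 "ci_high": r.ci_high, "model": r.model}
            )
        out["icc"] = pd.DataFrame(icc_rows)

    return out
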