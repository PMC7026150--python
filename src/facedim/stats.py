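"""Two-group and multi-group statistics for facial-distance comparisons.

Implements Welch's t test (from raw samples or from published group
summaries), Welch–Satterthwaite degrees of freedom, pooled-SD Cohen's d
with a normal-approximation 95% CI, the Mann–Whitney rank-sum test with
exact small-sample p-values, parametric/nonparametric test selection via
Shapiro–Wilk, one-way ANOVA (raw or summary-based) with Tukey HSD, and a
minimum-sample-size search under the noncentral F distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "d_confidence_interval",
    "GroupSummary",
    "ComparisonResult",
    "AnovaResult",
    "PowerSpec",
    "summarize",
    "iqr_to_sd",
    "as_mean_sd",
    "welch_from_summaries",
    "welch_t",
    "cohens_d",
    "rank_sum_test",
    "choose_test",
    "anova_from_summaries",
    "anova_raw",
    "tukey_hsd",
    "min_n_for_power",
    "holm_adjust",
]

# IQR of a standard normal = 2 * Phi^{-1}(0.75); used to convert median/IQR
# rows to mean/SD under a normality assumption.
_NORMAL_IQR = 2.0 * sps.norm.ppf(0.75)  # ~1.349


class DegenerateVarianceError(ValueError):
    """Raised when a comparison has no usable variance."""


class InsufficientDataError(ValueError):
    """Raised when a procedure's minimum group size is not met."""


@dataclass(frozen=True)
class GroupSummary:
    """(n, location, spread) for one group of subjects.

    ``kind`` records whether location/spread are mean/SD or median/IQR,
    mirroring the footnote convention of the source tables.
    """

    n: int
    location: float
    spread: float
    kind: Literal["mean_sd", "median_iqr"] = "mean_sd"
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InsufficientDataError(f"group {self.label!r}: n must be >= 2, got {self.n}")
        if not self.spread > 0:
            raise DegenerateVarianceError(f"group {self.label!r}: spread must be > 0")
        if self.kind not in ("mean_sd", "median_iqr"):
            raise ValueError(f"unknown summary kind {self.kind!r}")


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a two-group comparison (Welch's t or rank-sum W)."""

    statistic_name: Literal["t", "W"]
    statistic: float
    p: float
    d: float
    d_ci: tuple[float, float]
    df: float | None = None
    direction: str = "group1 minus group2; positive favours group1"
    approximated_from_median_iqr: bool = False

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    tukey_pairs: tuple[tuple[tuple[str, str], float, float], ...] | None = None


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a fixed-effect one-way ANOVA power calculation."""

    effect_f: float
    alpha: float = 0.05
    power: float = 0.90
    k: int = 2

    def __post_init__(self) -> None:
        if not self.effect_f > 0:
            raise ValueError("effect_f must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")


def summarize(x: Sequence[float], label: str = "") -> GroupSummary:
    """Mean/SD summary (ddof=1) of a raw sample."""
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("need n >= 2 to summarize")
    sd = float(np.std(arr, ddof=1))
    if sd == 0.0:
        raise DegenerateVarianceError("sample is constant")
    return GroupSummary(n=int(arr.size), location=float(np.mean(arr)), spread=sd, label=label)


def iqr_to_sd(iqr: float) -> float:
    """SD implied by an IQR under normality (IQR / 1.349)."""
    return float(iqr) / _NORMAL_IQR


def as_mean_sd(s: GroupSummary) -> GroupSummary:
    """Coerce a summary to mean/SD, converting median/IQR under normality."""
    if s.kind == "mean_sd":
        return s
    return GroupSummary(n=s.n, location=s.location, spread=iqr_to_sd(s.spread),
                        kind="mean_sd", label=s.label)


def _welch_satterthwaite(v1: float, n1: int, v2: float, n2: int) -> float:
    se2 = v1 / n1 + v2 / n2
    return se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))


def welch_from_summaries(
    s1: GroupSummary,
    s2: GroupSummary,
    *,
    median_approx: bool = False,
) -> ComparisonResult:
    """Welch's unequal-variance t test from (mean, SD, n) pairs.

    median/IQR summaries are rejected unless ``median_approx=True``, in
    which case they are converted to mean/SD assuming normality and the
    result is flagged.
    """
    approx = s1.kind == "median_iqr" or s2.kind == "median_iqr"
    if approx and not median_approx:
        raise ValueError(
            "median/IQR summaries require median_approx=True (normality approximation)"
        )
    a, b = as_mean_sd(s1), as_mean_sd(s2)
    v1, v2 = a.spread**2, b.spread**2
    se = math.sqrt(v1 / a.n + v2 / b.n)
    if se == 0.0:
        raise DegenerateVarianceError("both groups have zero variance")
    t = (a.location - b.location) / se
    df = _welch_satterthwaite(v1, a.n, v2, b.n)
    p = 2.0 * sps.t.sf(abs(t), df)
    d, ci = cohens_d(a, b)
    return ComparisonResult(
        statistic_name="t", statistic=t, df=df, p=min(p, 1.0), d=d, d_ci=ci,
        approximated_from_median_iqr=approx,
    )


def welch_t(x: Sequence[float], y: Sequence[float]) -> ComparisonResult:
    """Welch's t test on raw samples; definitionally equal to
    :func:`welch_from_summaries` applied to the samples' own summaries."""
    return welch_from_summaries(summarize(x, "x"), summarize(y, "y"))


def d_confidence_interval(d: float, n1: int, n2: int) -> tuple[float, float]:
    """95% CI around a standardized mean difference, Hedges–Olkin
    large-sample variance (n1+n2)/(n1*n2) + d^2/(2*(n1+n2))."""
    se = math.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2)))
    return d - 1.96 * se, d + 1.96 * se


def cohens_d(s1: GroupSummary, s2: GroupSummary) -> tuple[float, tuple[float, float]]:
    """Pooled-SD Cohen's d with a 95% normal-approximation CI."""
    a, b = as_mean_sd(s1), as_mean_sd(s2)
    n1, n2 = a.n, b.n
    pooled_var = ((n1 - 1) * a.spread**2 + (n2 - 1) * b.spread**2) / (n1 + n2 - 2)
    if pooled_var == 0.0:
        raise DegenerateVarianceError("pooled variance is zero")
    d = (a.location - b.location) / math.sqrt(pooled_var)
    return d, d_confidence_interval(d, n1, n2)


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> ComparisonResult:
    """Mann–Whitney rank-sum test (two-sided).

    Statistic convention: U = #{(i,j): x_i > y_j} + 1/2 #ties, i.e. the U
    of the first argument. The p-value is exact (full null distribution)
    when n1*n2 <= 400 and there are no ties, otherwise the normal
    approximation with continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    try:
        d, ci = cohens_d(summarize(x, "x"), summarize(y, "y"))
    except DegenerateVarianceError:
        d, ci = 0.0, (0.0, 0.0)
    return ComparisonResult(
        statistic_name="W", statistic=float(res.statistic), df=None,
        p=float(min(res.pvalue, 1.0)), d=d, d_ci=ci,
        direction="U of first sample; large when first-group values are larger",
    )


def choose_test(
    x: Sequence[float],
    y: Sequence[float],
    alpha_norm: float = 0.05,
) -> dict:
    """Pick parametric vs nonparametric via Shapiro–Wilk on each group.

    Returns a dict with the decision and the per-group normality p-values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise InsufficientDataError("normality testing needs n >= 3 per group")
    p1 = float(sps.shapiro(x).pvalue)
    p2 = float(sps.shapiro(y).pvalue)
    nonparam = p1 < alpha_norm or p2 < alpha_norm
    return {
        "choice": "nonparametric" if nonparam else "parametric",
        "shapiro_p": (p1, p2),
        "alpha_norm": alpha_norm,
    }


def anova_from_summaries(groups: Sequence[GroupSummary], *,
                         allow_two_groups: bool = False) -> AnovaResult:
    """One-way fixed-effects ANOVA from per-group (n, mean, SD).

    With two groups the pooled-variance t test is the standard tool, so
    k=2 raises unless ``allow_two_groups`` (where F equals that t squared).
    """
    if len(groups) < 2 or (len(groups) == 2 and not allow_two_groups):
        raise ValueError("anova needs >= 3 groups; use welch_from_summaries for 2")
    gs = [as_mean_sd(g) for g in groups]
    ns = np.array([g.n for g in gs], dtype=float)
    means = np.array([g.location for g in gs])
    sds = np.array([g.spread for g in gs])
    N = ns.sum()
    k = len(gs)
    grand = float((ns * means).sum() / N)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_b, df_w = k - 1, int(N) - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        raise DegenerateVarianceError("zero within-group variance")
    F = ms_b / ms_w
    return AnovaResult(F=F, df_between=df_b, df_within=df_w, p=float(sps.f.sf(F, df_b, df_w)))


def anova_raw(samples: Sequence[Sequence[float]], *,
              allow_two_groups: bool = False) -> AnovaResult:
    """One-way ANOVA on raw samples (delegates to the summary formula)."""
    return anova_from_summaries([summarize(s, str(i)) for i, s in enumerate(samples)],
                                allow_two_groups=allow_two_groups)


def tukey_hsd(
    samples: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> AnovaResult:
    """One-way ANOVA plus Tukey HSD studentized-range pairwise comparisons."""
    if len(samples) < 3:
        raise ValueError("tukey_hsd needs >= 3 groups")
    arrs = [np.asarray(s, dtype=float) for s in samples]
    if any(a.size < 2 for a in arrs):
        raise InsufficientDataError("every group needs n >= 2")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrs))]
    base = anova_raw(arrs)
    res = sps.tukey_hsd(*arrs)
    pairs = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            diff = float(np.mean(arrs[i]) - np.mean(arrs[j]))
            pairs.append(((labels[i], labels[j]), diff, float(min(res.pvalue[i, j], 1.0))))
    return AnovaResult(F=base.F, df_between=base.df_between, df_within=base.df_within,
                       p=base.p, tukey_pairs=tuple(pairs))


def _anova_power(total_n: int, spec: PowerSpec) -> float:
    df1 = spec.k - 1
    df2 = total_n - spec.k
    if df2 < 1:
        return 0.0
    lam = spec.effect_f**2 * total_n
    crit = sps.f.isf(spec.alpha, df1, df2)
    return float(sps.ncf.sf(crit, df1, df2, lam))


def min_n_for_power(spec: PowerSpec, max_n: int = 10**6) -> int:
    """Smallest balanced total N (a multiple of k) reaching the target power.

    Power is evaluated with the noncentral F distribution using
    noncentrality lambda = f^2 * N, the G*Power convention for fixed-effect
    one-way ANOVA.
    """
    n = 2 * spec.k
    while n <= max_n:
        if _anova_power(n, spec) >= spec.power:
            return n
        n += spec.k
    raise ValueError(f"target power {spec.power} unreachable with N <= {max_n}")


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (for report transparency only)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj
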