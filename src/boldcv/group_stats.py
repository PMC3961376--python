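"""Cohort-level inference on aggregated CV values.

The primary comparison is a two-sided Wilcoxon rank-sum (Mann-Whitney)
test for equal medians of two independent cohorts.  The p-value is exact
for small samples: with no ties the null rank-sum distribution is built by
dynamic programming over ranks; with ties all C(N, n1) assignments of the
pooled midranks are enumerated (feasible up to N = 20, i.e. 184,756
subsets); larger samples fall back to the normal approximation with
tie-corrected variance and continuity correction.  The two-sided p is
``2 * min(P(S <= s), P(S >= s))`` capped at 1.

Also provided: an ordinary least-squares line for the GM-vs-WM relation,
and a cohort report combining per-stratum descriptives, Wilcoxon p-values,
the head-displacement comparison and the GM~WM fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "FitResult",
    "CohortTable",
    "CohortReport",
    "wilcoxon_ranksum",
    "linear_fit",
    "compare_cohorts",
]

SIGNIFICANCE_LEVEL = 0.05

#: Largest per-group size for which the tie-free exact null is computed.
EXACT_LIMIT = 12
#: Largest pooled size for which ties are handled by full enumeration.
TIE_ENUM_LIMIT = 20


@dataclass
class TestResult:
    """Outcome of a two-sample rank-sum test."""

    statistic: float  # rank-sum of the first sample (midranks)
    p_two_sided: float
    n1: int
    n2: int
    method: str  # exact | exact_perm | normal_approx

    def __post_init__(self) -> None:
        if not 0 < self.p_two_sided <= 1:
            raise ValueError(f"p-value out of (0, 1]: {self.p_two_sided}")
        lo = self.n1 * (self.n1 + 1) / 2
        hi = self.n1 * (self.n1 + 2 * self.n2 + 1) / 2
        if not lo - 1e-9 <= self.statistic <= hi + 1e-9:
            raise ValueError(f"rank-sum {self.statistic} outside [{lo}, {hi}]")

    @property
    def significant(self) -> bool:
        return self.p_two_sided < SIGNIFICANCE_LEVEL


def _exact_ranksum_pmf(n1: int, n: int) -> np.ndarray:
    """Null pmf of the rank-sum of a size-n1 sample from ranks 1..n (no ties).

    Classic subset-sum DP: ``count[k, s]`` = number of k-subsets of
    {1..j} summing to s, updated rank by rank.  Index 0 of the returned
    array corresponds to sum 0.
    """
    max_sum = n1 * (2 * n - n1 + 1) // 2
    count = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    count[0, 0] = 1.0
    for rank in range(1, n + 1):
        upper = min(n1, rank)
        for k in range(upper, 0, -1):
            count[k, rank:] += count[k - 1, :-rank or None]
    total = count[n1].sum()
    return count[n1] / total


def _enumerate_tied_null(ranks2x: np.ndarray, n1: int, s2x: int) -> float:
    """Two-sided p by enumerating all n1-subsets of doubled midranks."""
    n = ranks2x.size
    sums = np.fromiter(
        (sum(c) for c in combinations(ranks2x.tolist(), n1)),
        dtype=np.int64,
    )
    p_le = np.mean(sums <= s2x)
    p_ge = np.mean(sums >= s2x)
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_ranksum(
    x: np.ndarray, y: np.ndarray, exact_limit: int = EXACT_LIMIT
) -> TestResult:
    """Two-sided Wilcoxon rank-sum test of equal medians.

    Parameters
    ----------
    x, y
        The two independent samples (each of size >= 2).
    exact_limit
        Both sample sizes must be at or below this for the tie-free exact
        null; beyond it (or beyond the enumeration limit when ties exist)
        the tie-corrected normal approximation with continuity correction
        is used.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled = np.concatenate([x, y])
    n = n1 + n2
    ranks = sps.rankdata(pooled)  # midranks for ties
    s = float(ranks[:n1].sum())

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = (tie_counts > 1).any()

    if (tie_counts == n).any():
        warnings.warn("all pooled values identical; rank-sum test degenerate, p = 1")
        return TestResult(statistic=s, p_two_sided=1.0, n1=n1, n2=n2,
                          method="degenerate")

    if not has_ties and n1 <= exact_limit and n2 <= exact_limit:
        pmf = _exact_ranksum_pmf(n1, n)
        si = int(round(s))
        p_le = pmf[: si + 1].sum()
        p_ge = pmf[si:].sum()
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(statistic=s, p_two_sided=p, n1=n1, n2=n2, method="exact")

    if has_ties and n <= TIE_ENUM_LIMIT:
        ranks2x = np.round(2 * ranks).astype(np.int64)
        p = _enumerate_tied_null(ranks2x, n1, int(round(2 * s)))
        return TestResult(statistic=s, p_two_sided=p, n1=n1, n2=n2,
                          method="exact_perm")

    # normal approximation, tie-corrected variance, continuity correction
    mean_s = n1 * (n + 1) / 2.0
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / ((n) * (n - 1))
    var_s = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_s <= 0:
        warnings.warn("zero rank-sum variance; p = 1")
        return TestResult(statistic=s, p_two_sided=1.0, n1=n1, n2=n2,
                          method="degenerate")
    delta = s - mean_s
    cc = min(0.5, abs(delta))  # continuity correction toward the mean
    z = (abs(delta) - cc) / np.sqrt(var_s)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return TestResult(statistic=s, p_two_sided=p, n1=n1, n2=n2,
                      method="normal_approx")


@dataclass
class FitResult:
    """Ordinary least-squares line y = slope*x + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n: int


def linear_fit(x: np.ndarray, y: np.ndarray) -> FitResult:
    """OLS line through (x, y); the caller decides which axis is which.

    R-squared is ``1 - SS_res / SS_tot``; a constant y gives slope 0 and
    R-squared 0; a constant x is an error.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("linear fit needs at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid ** 2).sum() / ss_tot if ss_tot > 0 else 0.0
    return FitResult(slope=float(slope), intercept=float(intercept),
                     r_squared=float(r2), n=x.size)


# ---------------------------------------------------------------------------
# Cohort table and report
# ---------------------------------------------------------------------------

GROUPS = ("control", "ckd")


@dataclass
class CohortTable:
    """Long-format per-subject results joined with group labels.

    ``data`` columns: subject, group, tissue, method, band, cv, n; plus an
    optional per-subject ``displacement`` frame (subject, group,
    displacement_mm).
    """

    data: pd.DataFrame
    displacement: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = {"subject", "group", "tissue", "method", "band", "cv", "n"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")
        groups_per_subject = self.data.groupby("subject")["group"].nunique()
        if (groups_per_subject > 1).any():
            bad = groups_per_subject[groups_per_subject > 1].index.tolist()
            raise ValueError(f"subjects in more than one group: {bad}")

    def group_sizes(self) -> dict[str, int]:
        return self.data.groupby("group")["subject"].nunique().to_dict()


@dataclass
class CohortReport:
    """Per-stratum descriptives and tests, plus ancillary comparisons."""

    strata: pd.DataFrame
    gm_wm_fit: FitResult | None = None
    displacement_test: TestResult | None = None
    displacement_means: dict[str, float] = field(default_factory=dict)
    incomplete: list[str] = field(default_factory=list)

    def summary(self) -> str:
        """Human-readable report text."""
        lines = ["Cohort comparison of BOLD fluctuation CV", "=" * 44]
        for _, row in self.strata.iterrows():
            star = " *" if row["p"] < SIGNIFICANCE_LEVEL else ""
            lines.append(
                f"{row['tissue']:>4} {row['method']:>8} {row['band']:>14}: "
                f"control {1e3 * row['mean_control']:.2f}±{1e3 * row['sd_control']:.2f}"
                f" vs ckd {1e3 * row['mean_ckd']:.2f}±{1e3 * row['sd_ckd']:.2f}"
                f" (CV x1e-3), p={row['p']:.4g}{star}"
            )
        if self.gm_wm_fit is not None:
            f = self.gm_wm_fit
            lines.append(
                f"WM vs GM fit: y = {f.slope:.3g} x + {f.intercept:.2g}, "
                f"R^2 = {f.r_squared:.3g} (n={f.n})"
            )
        if self.displacement_test is not None:
            m = self.displacement_means
            lines.append(
                "mean displacement (mm): "
                + ", ".join(f"{g} {v:.3g}" for g, v in m.items())
                + f"; p = {self.displacement_test.p_two_sided:.3g}"
            )
        if self.incomplete:
            lines.append("incomplete strata skipped: " + ", ".join(self.incomplete))
        return "\n".join(lines)


def compare_cohorts(table: CohortTable) -> CohortReport:
    """Group descriptives and Wilcoxon tests per tissue x method x band.

    Strata with fewer than two subjects in either group are listed as
    incomplete and skipped; the analysis proceeds on the complete strata.
    Adds the head-displacement comparison (when available) and an OLS fit
    of WM on GM using the strict-threshold full-band values pooled over
    subjects.
    """
    df = table.data
    rows, incomplete = [], []
    for (tissue, method, band), sub in df.groupby(["tissue", "method", "band"]):
        by_group = {g: sub.loc[sub["group"] == g, "cv"].to_numpy() for g in GROUPS}
        if any(v.size < 2 for v in by_group.values()):
            incomplete.append(f"{tissue}/{method}/{band}")
            continue
        test = wilcoxon_ranksum(by_group["control"], by_group["ckd"])
        rows.append({
            "tissue": tissue, "method": method, "band": band,
            "mean_control": by_group["control"].mean(),
            "sd_control": by_group["control"].std(ddof=1),
            "mean_ckd": by_group["ckd"].mean(),
            "sd_ckd": by_group["ckd"].std(ddof=1),
            "n_control": by_group["control"].size,
            "n_ckd": by_group["ckd"].size,
            "statistic": test.statistic,
            "p": test.p_two_sided,
            "test_method": test.method,
        })
    strata = pd.DataFrame(rows)
    if not strata.empty:
        strata = strata.sort_values(["tissue", "method", "band"]).reset_index(drop=True)

    # GM ~ WM relation: strict-threshold full-band values, one point per subject
    fit = None
    sel = df[(df["method"] == "strict") & (df["band"] == "full")]
    gm = sel[sel["tissue"] == "GM"].set_index("subject")["cv"]
    wm = sel[sel["tissue"] == "WM"].set_index("subject")["cv"]
    common = gm.index.intersection(wm.index)
    if common.size >= 3 and np.ptp(gm[common].to_numpy()) > 0:
        fit = linear_fit(gm[common].to_numpy(), wm[common].to_numpy())

    disp_test, disp_means = None, {}
    if table.displacement is not None and not table.displacement.empty:
        d = table.displacement
        samples = {g: d.loc[d["group"] == g, "displacement_mm"].to_numpy()
                   for g in GROUPS}
        disp_means = {g: float(v.mean()) for g, v in samples.items() if v.size}
        if all(v.size >= 2 for v in samples.values()):
            disp_test = wilcoxon_ranksum(samples["control"], samples["ckd"])

    return CohortReport(strata=strata, gm_wm_fit=fit,
                        displacement_test=disp_test,
                        displacement_means=disp_means,
                        incomplete=incomplete)
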