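"""Group comparison statistics.

Two-tailed t-tests (paired and unpaired, Welch by default with a
classic-Student switch), empirical CDFs of per-particle ratios, length-ratio
correlation, and pre/post drug-effect normalization.  Significance stars use
0.05 / 0.01 / 0.001 thresholds; no multiple-testing correction is applied
(per-comparison convention, noted in reports).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats as sps

from .errors import DataError, PairingError


@dataclass
class GroupSummary:
    """Summary statistics of one group (genotype × treatment)."""

    mean: float
    sd: float
    n: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DataError("a group needs n >= 2 for any test")
        if self.sd < 0:
            raise DataError("sd must be non-negative")


@dataclass
class ComparisonResult:
    """Outcome of a two-group comparison."""

    t: float
    p: float
    kind: str  # "paired" | "unpaired"
    stars: str
    df: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise DataError("p value must lie in [0, 1]")


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _as_summary(x) -> GroupSummary | None:
    return x if isinstance(x, GroupSummary) else None


def compare_groups(
    a, b, paired: bool = False, welch: bool = True
) -> ComparisonResult:
    """Two-tailed t-test between two groups.

    ``a`` and ``b`` are sample arrays, or :class:`GroupSummary` objects for
    the unpaired case.  ``welch=True`` (default) uses the unequal-variance
    form; ``welch=False`` pools variances.  Paired tests require raw samples
    of equal length in matched order.
    """
    sa, sb = _as_summary(a), _as_summary(b)
    if paired:
        if sa is not None or sb is not None:
            raise DataError("paired tests require raw samples, not summaries")
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size != b.size:
            raise DataError(f"paired test needs equal n, got {a.size} and {b.size}")
        if a.size < 2:
            raise DataError("paired test needs n >= 2")
        if np.array_equal(a, b):
            t, p, df = 0.0, 1.0, float(a.size - 1)
        else:
            res = sps.ttest_rel(a, b)
            t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        return ComparisonResult(t=t, p=p, kind="paired", stars=significance_stars(p), df=df)

    if sa is not None or sb is not None:
        if sa is None or sb is None:
            raise DataError("mixing raw samples and summaries is not supported")
        res = sps.ttest_ind_from_stats(
            sa.mean, sa.sd, sa.n, sb.mean, sb.sd, sb.n, equal_var=not welch
        )
    else:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise DataError("unpaired test needs n >= 2 per group")
        res = sps.ttest_ind(a, b, equal_var=not welch)
    t, p = float(res.statistic), float(res.pvalue)
    df = float(getattr(res, "df", np.nan))
    if np.isnan(t):  # identical zero-variance groups
        t, p = 0.0, 1.0
    return ComparisonResult(t=t, p=p, kind="unpaired", stars=significance_stars(p), df=df)


@dataclass
class EmpiricalCDF:
    """Nondecreasing step function from 0 to 1 over the sorted sample."""

    x: np.ndarray
    y: np.ndarray

    def __call__(self, value: float | np.ndarray) -> float | np.ndarray:
        idx = np.searchsorted(self.x, np.asarray(value), side="right")
        out = idx / self.x.size
        return float(out) if np.isscalar(value) else out


def cdf_of_ratios(ratios: np.ndarray) -> EmpiricalCDF:
    """Empirical cumulative distribution of per-particle ratios."""
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        raise DataError("cannot build a CDF from an empty sample")
    x = np.sort(ratios)
    y = np.arange(1, x.size + 1) / x.size
    return EmpiricalCDF(x=x, y=y)


def size_ratio_correlation(lengths: np.ndarray, ratios: np.ndarray) -> float:
    """Pearson product-moment correlation between particle length and ratio."""
    lengths = np.asarray(lengths, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    if lengths.size != ratios.size:
        raise DataError("lengths and ratios must have equal length")
    if lengths.size < 3:
        raise DataError("correlation needs n >= 3")
    if np.ptp(lengths) == 0 or np.ptp(ratios) == 0:
        raise DataError("correlation undefined for constant input")
    return float(sps.pearsonr(lengths, ratios).statistic)


def normalize_drug_effect(
    pre: Mapping[str, float], post: Mapping[str, float]
) -> dict[str, float | None]:
    """Post/pre quotient per quantity for one cell recorded before and after.

    Depolarization shows as normalized ratio < 1.  Quantities with a zero
    pretreatment value map to None (undefined, flagged rather than infinite).
    Missing post-treatment keys raise a pairing error.
    """
    out: dict[str, float | None] = {}
    for key, pre_value in pre.items():
        if key not in post:
            raise PairingError(f"post-treatment record is missing quantity {key!r}")
        out[key] = None if pre_value == 0 else post[key] / pre_value
    return out
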