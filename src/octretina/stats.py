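"""Group-comparison and validation statistics for thickness tables.

Thickness distributions across developmental time points are compared with
the Kruskal-Wallis rank test (tie-corrected H, chi-square reference
distribution, optional exact permutation p for small samples).  Outliers
are flagged with the 1.5-IQR fence rule but retained in comparisons.
Bland-Altman agreement statistics support method-comparison validation
(semi-automatic vs manual segmentation).

Quantile convention: linear interpolation between order statistics
(numpy's default), used consistently for quartiles, fences and boxplot
summaries.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "KWResult",
    "GroupSummary",
    "kruskal_wallis",
    "iqr_outliers",
    "summarize_groups",
    "bland_altman",
]


@dataclass
class KWResult:
    """Kruskal-Wallis outcome: tie-corrected H, df = k - 1, p-value."""

    H: float
    df: int
    p_value: float
    p_method: str = "asymptotic"


def _h_statistic(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H from rank sums."""
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    idx = 0
    h = 0.0
    for g in groups:
        r = ranks[idx: idx + g.size]
        idx += g.size
        h += r.sum() ** 2 / g.size
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    ties = np.sum(counts**3 - counts)
    denom = 1.0 - ties / (N**3 - N)
    if denom == 0.0:
        return 0.0  # every value identical
    return h / denom


def kruskal_wallis(
    groups: list,
    p_method: str = "asymptotic",
    n_resamples: int = 10000,
    seed: int | None = None,
) -> KWResult:
    """Kruskal-Wallis test across two or more independent samples.

    ``p_method="asymptotic"`` uses the chi-square reference with k - 1
    degrees of freedom.  ``p_method="permutation"`` computes
    ``P(H* >= H)`` over group-label permutations — exhaustively when the
    number of distinct assignments is small (< 2e5), otherwise by ``n_resamples``
    random permutations.  Identical data in every group yield H = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group needs at least one observation")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need at least three observations in total")
    H = _h_statistic(arrays)
    df = len(arrays) - 1
    if p_method == "asymptotic":
        p = 1.0 if H == 0.0 else float(sps.chi2.sf(H, df))
        return KWResult(H=float(H), df=df, p_value=min(p, 1.0), p_method=p_method)
    if p_method != "permutation":
        raise ValueError(f"unknown p_method {p_method!r}")
    pooled = np.concatenate(arrays)
    sizes = [a.size for a in arrays]
    N = pooled.size
    n_assign = math.factorial(N)
    for s in sizes:
        n_assign //= math.factorial(s)
    eps = 1e-12
    if n_assign <= 200_000:
        count = 0
        total = 0
        for assignment in _assignments(N, sizes):
            h = _h_statistic([pooled[list(ix)] for ix in assignment])
            count += h >= H - eps
            total += 1
        p = count / total
    else:
        rng = np.random.default_rng(seed)
        count = 1  # the observed assignment
        for _ in range(n_resamples):
            perm = rng.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            count += _h_statistic(list(parts)) >= H - eps
        p = count / (n_resamples + 1)
    return KWResult(H=float(H), df=df, p_value=float(p), p_method="permutation")


def _assignments(n: int, sizes: list[int]):
    """All ways to split indices 0..n-1 into ordered groups of given sizes."""
    indices = tuple(range(n))

    def recurse(remaining: tuple, sizes_left: list[int]):
        if not sizes_left:
            yield ()
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in combo)
            for tail in recurse(rest, sizes_left[1:]):
                yield (combo,) + tail

    yield from recurse(indices, list(sizes))


def iqr_outliers(values) -> np.ndarray:
    """Flag values outside (q1 - 1.5*IQR, q3 + 1.5*IQR).

    Quartiles use linear interpolation.  A zero IQR collapses the fences to
    the quartile value; equality is not "outside", so constant samples have
    no outliers.  Flagged values remain part of downstream comparisons.
    Samples smaller than 4 produce no flags (with a warning).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 4:
        warnings.warn("fewer than 4 values: IQR outlier rule not applied",
                      stacklevel=2)
        return np.zeros(v.size, dtype=bool)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return (v < lo) | (v > hi)


@dataclass
class GroupSummary:
    """Boxplot-style summary of one (age, layer) group."""

    group: tuple
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    outliers: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("quartiles must satisfy q1 <= median <= q3")


def summarize_groups(
    table: pd.DataFrame,
    value_col: str = "thickness_um",
    by: tuple[str, ...] = ("age_label", "layer"),
) -> list[GroupSummary]:
    """Per-(age, layer) boxplot quantities: n, mean, median, quartiles, outliers."""
    out: list[GroupSummary] = []
    for key, sub in table.groupby(list(by), sort=True, observed=True):
        v = sub[value_col].to_numpy(dtype=float)
        if v.size == 0:
            raise ValueError(f"empty group {key}")
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            flags = iqr_outliers(v)
        out.append(
            GroupSummary(
                group=key if isinstance(key, tuple) else (key,),
                n=int(v.size),
                mean=float(v.mean()),
                median=float(med),
                q1=float(q1),
                q3=float(q3),
                outliers=sorted(float(x) for x in v[flags]),
            )
        )
    return out


@dataclass
class BlandAltmanResult:
    """Agreement between two paired measurement techniques."""

    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    coverage: float

    def max_abs_difference(self, coverage: float = 0.90) -> float:
        """Largest |difference| expected at a two-sided interval."""
        z = sps.norm.ppf(0.5 + coverage / 2.0)
        return max(abs(self.bias - z * self.sd), abs(self.bias + z * self.sd))


def bland_altman(a, b, coverage: float = 0.95) -> BlandAltmanResult:
    """Bland-Altman statistics for paired samples.

    bias = mean(a - b); limits of agreement = bias +/- z * SD(a - b)
    (sample SD, two-sided normal quantile for the requested coverage).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    z = float(sps.norm.ppf(0.5 + coverage / 2.0))
    return BlandAltmanResult(
        bias=bias, sd=sd,
        loa_lower=bias - z * sd, loa_upper=bias + z * sd,
        coverage=coverage,
    )
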