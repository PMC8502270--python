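"""Shared statistical machinery.

Geometric-law estimation, chi-square goodness of fit over integer supports
with tail pooling, Pearson correlation, Mann-Whitney U, and per-rank
quantile envelopes for ordered simulation output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GOFResult",
    "EnvelopeBand",
    "geometric_mle",
    "geometric_pmf",
    "chi2_gof",
    "pearson_with_p",
    "mann_whitney_u",
    "rank_envelope",
]


@dataclass(frozen=True)
class GOFResult:
    """Chi-square goodness-of-fit result.

    ``bins`` lists, per (possibly merged) bin, its category labels, the
    observed count and the expected count.
    """

    statistic: float
    df: int
    p_value: float
    bins: tuple[tuple[tuple[int, ...], float, float], ...]

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "bins": [
                {"categories": list(c), "observed": o, "expected": e}
                for c, o, e in self.bins
            ],
        }


@dataclass(frozen=True)
class EnvelopeBand:
    """Per-rank lower/upper quantile bounds at a coverage level."""

    lower: np.ndarray
    upper: np.ndarray
    level: float

    def __post_init__(self) -> None:
        if np.any(self.lower > self.upper):
            raise ValueError("envelope lower bound exceeds upper bound")

    def contains(self, ordered: Sequence[float]) -> np.ndarray:
        x = np.asarray(ordered, dtype=float)
        if x.shape != self.lower.shape:
            raise ValueError("length mismatch with envelope")
        return (x >= self.lower) & (x <= self.upper)


def geometric_mle(samples: Sequence[int]) -> float:
    """ML estimate of the geometric parameter on support {1, 2, ...}.

    With P(X=k) = p (1-p)^(k-1), the MLE is 1 / sample mean.
    """
    x = np.asarray(list(samples), dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if np.any(x < 1):
        raise ValueError("geometric samples must be >= 1")
    return float(1.0 / x.mean())


def geometric_pmf(k: int | np.ndarray, p: float) -> float | np.ndarray:
    """P(X=k) = p (1-p)^(k-1) on support {1, 2, ...}."""
    k = np.asarray(k)
    out = p * (1.0 - p) ** (k - 1)
    return float(out) if out.ndim == 0 else out


def chi2_gof(
    observed: Mapping[int, int] | Sequence[int],
    model_pmf: Callable[[int], float],
    n_fitted: int = 0,
    min_expected: float = 5.0,
) -> GOFResult:
    """Chi-square GOF of integer-valued observations against a model pmf.

    ``observed`` is either a mapping category -> count or a raw sample of
    integers (counted here). Categories run from the smallest observed value
    to the largest; any model mass beyond the largest category is pooled
    into an open tail bin. Bins are then merged from the right tail inward
    until every expected count reaches ``min_expected``. Degrees of freedom
    are (number of bins - 1 - n_fitted).
    """
    if isinstance(observed, Mapping):
        counts = {int(k): int(v) for k, v in observed.items() if v > 0}
    else:
        vals, cnt = np.unique(np.asarray(list(observed), dtype=int), return_counts=True)
        counts = {int(v): int(c) for v, c in zip(vals, cnt)}
    if not counts:
        raise ValueError("no observations")
    n = sum(counts.values())
    lo, hi = min(counts), max(counts)
    cats = list(range(lo, hi + 1))
    probs = np.array([model_pmf(k) for k in cats], dtype=float)
    if np.any(probs < -1e-12):
        raise ValueError("model pmf must be non-negative")
    head = float(sum(model_pmf(k) for k in range(1, lo)))  # mass below support
    tail = max(0.0, 1.0 - probs.sum() - head)

    # bins: list of (categories, observed, expected)
    bins: list[list] = [
        [[k], float(counts.get(k, 0)), float(n * pk)] for k, pk in zip(cats, probs)
    ]
    # open tail bin for mass above the largest observed category
    if n * tail > 1e-9:
        bins[-1][2] += n * tail  # pooled tail merges with the last category
    if n * head > 1e-9:
        bins[0][2] += n * head

    # merge from the right tail inward until every expected >= min_expected
    def merge(i: int, j: int) -> None:
        bins[i][0] = bins[i][0] + bins[j][0]
        bins[i][1] += bins[j][1]
        bins[i][2] += bins[j][2]
        del bins[j]

    while len(bins) > 2:
        exp = [b[2] for b in bins]
        if min(exp) >= min_expected:
            break
        # rightmost offending bin merges with its left neighbour
        idx = max(i for i, e in enumerate(exp) if e < min_expected)
        if idx == 0:
            merge(0, 1)
        else:
            merge(idx - 1, idx)

    df = len(bins) - 1 - n_fitted
    if len(bins) < 2 or df < 1 or min(b[2] for b in bins) < min_expected:
        raise ValueError("insufficient support for chi-square test after merging")

    obs = np.array([b[1] for b in bins])
    exp = np.array([b[2] for b in bins])
    # renormalise tiny drift so Pearson statistic is well defined
    exp = exp * (obs.sum() / exp.sum())
    stat = float(((obs - exp) ** 2 / exp).sum())
    p = float(sps.chi2.sf(stat, df))
    return GOFResult(
        statistic=stat,
        df=df,
        p_value=p,
        bins=tuple((tuple(b[0]), b[1], b[2]) for b in bins),
    )


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with the t-based two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


#: combined sample size above which Mann-Whitney switches to the
#: tie-corrected normal approximation
MWU_EXACT_MAX_N = 25


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration for small tie-free samples (combined n <= 25),
    otherwise the normal approximation with tie correction (and no
    continuity correction, so equal samples give p = 1 exactly).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if x.size + y.size <= MWU_EXACT_MAX_N and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(min(1.0, res.pvalue))


def rank_envelope(sim_sets: Sequence[Sequence[float]], level: float = 0.95) -> EnvelopeBand:
    """Per-rank empirical quantile band across ordered simulated vectors.

    Each of the N input vectors must be sorted ascending and of equal length.
    At each rank the central ``level`` quantile interval across simulations
    is returned (min/max when level == 1).
    """
    arr = np.asarray(sim_sets, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 equal-length simulation vectors")
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    if np.any(np.diff(arr, axis=1) < 0):
        raise ValueError("simulation vectors must be sorted ascending")
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(arr, alpha, axis=0)
    upper = np.quantile(arr, 1.0 - alpha, axis=0)
    return EnvelopeBand(lower=lower, upper=upper, level=level)
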