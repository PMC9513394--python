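"""Paired agreement statistics: Wilcoxon signed-rank, Bland-Altman,
summary statistics, and ratio statistics.

All operations act on :class:`PairedMeasurements` — per-lesion values from
two raters or two methods. The Wilcoxon signed-rank machinery reports the
positive and negative rank sums (W₊, W₋) explicitly, because for
inter-observer comparisons the rank sums themselves — not only the
p-value — are the quantity of interest: W₋ ≫ W₊ says one method's
inter-observer discrepancies are systematically larger.

Conventions pinned for the study reproduction (see ``study`` module):
differences are oriented first-rater minus second-rater; quartiles use
the ``"nearest"`` order-statistic rule; limits of agreement default to
bias ± 1.96·SD, while ratio intervals use mean ± 2·SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import DegenerateTestError, InsufficientDataError, RatioError

__all__ = [
    "PairedMeasurements",
    "WilcoxonResult",
    "BlandAltmanResult",
    "RatioSummary",
    "wilcoxon_signed_rank",
    "bland_altman",
    "summary_stats",
    "ratio_summary",
]

#: quantile rule that reproduces the study's printed quartiles
QUANTILE_METHOD = "nearest"

#: largest n for which the exact signed-rank null is enumerated
EXACT_N_MAX = 25


@dataclass(frozen=True)
class PairedMeasurements:
    """Per-lesion paired values (two raters or two methods), equal length."""

    a: np.ndarray
    b: np.ndarray
    labels: tuple = ()

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float).ravel()
        b = np.asarray(self.b, dtype=float).ravel()
        if a.size != b.size or a.size < 1:
            raise InsufficientDataError("paired samples must be equal-length and non-empty")
        if not (np.isfinite(a).all() and np.isfinite(b).all()):
            raise InsufficientDataError("paired samples must not contain missing values")
        labels = tuple(self.labels) if len(self.labels) else tuple(range(1, a.size + 1))
        if len(labels) != a.size:
            raise InsufficientDataError("labels must match sample length")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "labels", labels)

    @property
    def differences(self) -> np.ndarray:
        return self.a - self.b

    def __len__(self) -> int:
        return self.a.size


@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank test outcome: rank sums, sample size used, p-value."""

    w_plus: float
    w_minus: float
    n_used: int
    p_value: float
    p_mode: str
    zero_policy: str
    degenerate: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Wilcoxon signed-rank: W+={self.w_plus:g}, W-={self.w_minus:g}, "
            f"n={self.n_used}, p={self.p_value:.4g} ({self.p_mode})"
        )


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias, SD of paired differences, and limits of agreement."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    k: float
    outside_indices: tuple = field(default_factory=tuple)
    n: int = 0

    @property
    def n_outside(self) -> int:
        return len(self.outside_indices)


@dataclass(frozen=True)
class RatioSummary:
    """Per-pair ratio statistics: mean, SD, and mean ± 2·SD interval."""

    mean_ratio: float
    sd_ratio: float
    interval_low: float
    interval_high: float
    n: int


def _signed_rank_sums(d: np.ndarray, zero_policy: str) -> tuple[float, float, np.ndarray]:
    """Mid-ranked rank sums of positive/negative differences.

    ``drop`` discards zero differences before ranking (classical
    Wilcoxon); ``pratt`` ranks zeros with the rest but excludes their
    ranks from both sums.
    """
    if zero_policy not in ("drop", "pratt"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    if zero_policy == "drop":
        d = d[d != 0]
        if d.size == 0:
            raise DegenerateTestError("all differences are zero")
        ranks = rankdata(np.abs(d))
        nonzero = d
    else:
        ranks_all = rankdata(np.abs(d))
        nonzero_mask = d != 0
        if not nonzero_mask.any():
            raise DegenerateTestError("all differences are zero")
        ranks = ranks_all[nonzero_mask]
        nonzero = d[nonzero_mask]
    w_plus = float(ranks[nonzero > 0].sum())
    w_minus = float(ranks[nonzero < 0].sum())
    return w_plus, w_minus, ranks


def exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p over all 2ⁿ sign assignments.

    Counts assignments whose W₊ falls in either tail
    (min(W, total−W) ≤ min(W₊, W₋) observed), computed by convolving the
    rank generating polynomial — numerically identical to full
    enumeration but O(n · total) instead of O(2ⁿ). Mid-ranks (ties) are
    handled by doubling to an integer lattice.
    """
    # ranks are integers or half-integers; scale to an integer lattice
    scaled = np.rint(ranks * 2).astype(np.int64)
    total = int(scaled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    w_obs = min(w_plus, ranks.sum() - w_plus) * 2
    lo = int(np.floor(w_obs + 1e-9))
    tail = counts[: lo + 1].sum() + counts[total - lo :].sum()
    if 2 * lo == total:  # both tails meet in the middle; don't double-count
        tail -= counts[lo]
    return min(1.0, float(tail) / 2 ** ranks.size)


def _normal_signed_rank_p(d_nonzero: np.ndarray, ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided normal approximation with tie and continuity correction."""
    n = ranks.size
    total = ranks.sum()
    mean = total / 2.0
    # variance of W+ under random signs: sum(r_i^2)/4, which equals the
    # textbook n(n+1)(2n+1)/24 − Σ(t³−t)/48 when ranks are 1..n mid-ranked
    var = float(np.sum(ranks**2)) / 4.0
    if var == 0:
        return 1.0
    z = (abs(w_plus - mean) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    from scipy.stats import norm

    return float(2 * norm.sf(z))


def wilcoxon_signed_rank(
    pairs: PairedMeasurements | Sequence[float],
    zero_policy: str = "drop",
    p_mode: str = "auto",
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test reporting W₊ and W₋.

    Parameters
    ----------
    pairs
        :class:`PairedMeasurements` (tested on a − b) or a raw sequence
        of differences.
    zero_policy
        ``"drop"`` (classical; zeros discarded) or ``"pratt"`` (zeros
        ranked, their ranks excluded from both sums).
    p_mode
        ``"exact"`` — enumerate all 2ⁿ sign assignments; ``"normal"`` —
        normal approximation with tie and continuity correction;
        ``"auto"`` — exact when n ≤ 25 and the nonzero |d| are tie-free,
        normal otherwise.

    Notes
    -----
    If every difference is zero the test is degenerate: p = 1 is
    reported with ``degenerate=True`` rather than raising.
    """
    d = pairs.differences if isinstance(pairs, PairedMeasurements) else np.asarray(pairs, float)
    if d.size < 1:
        raise InsufficientDataError("need at least one pair")
    try:
        w_plus, w_minus, ranks = _signed_rank_sums(d, zero_policy)
    except DegenerateTestError:
        return WilcoxonResult(
            w_plus=0.0, w_minus=0.0, n_used=0, p_value=1.0,
            p_mode="degenerate", zero_policy=zero_policy, degenerate=True,
        )
    n_used = ranks.size
    abs_nonzero = np.abs(d[d != 0])
    tie_free = np.unique(abs_nonzero).size == abs_nonzero.size

    if p_mode == "auto":
        p_mode = "exact" if (n_used <= EXACT_N_MAX and tie_free) else "normal"
    if p_mode == "exact":
        p = exact_signed_rank_p(ranks, w_plus)
    elif p_mode == "normal":
        p = _normal_signed_rank_p(d[d != 0], ranks, w_plus)
    else:
        raise ValueError(f"unknown p_mode {p_mode!r}")
    return WilcoxonResult(
        w_plus=w_plus, w_minus=w_minus, n_used=n_used,
        p_value=p, p_mode=p_mode, zero_policy=zero_policy,
    )


def bland_altman(pairs: PairedMeasurements, k: float = 1.96) -> BlandAltmanResult:
    """Bland-Altman agreement: bias, SD of differences, bias ± k·SD limits.

    SD uses the n−1 denominator. Points strictly outside the limits are
    flagged by label.
    """
    if len(pairs) < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 pairs")
    d = pairs.differences
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias - k * sd, bias + k * sd
    outside = tuple(
        lbl for lbl, di in zip(pairs.labels, d) if di < lo or di > hi
    )
    return BlandAltmanResult(
        bias=bias, sd=sd, loa_low=lo, loa_high=hi, k=k,
        outside_indices=outside, n=len(pairs),
    )


def summary_stats(values: Sequence[float]) -> dict[str, float]:
    """Mean, sample SD (n−1), median and quartiles.

    Quartiles use the nearest-order-statistic rule (module default
    ``QUANTILE_METHOD``). SD is NaN for a single observation.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise InsufficientDataError("summary_stats needs at least one value")
    return {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
        "median": float(np.median(v)),
        "q1": float(np.quantile(v, 0.25, method=QUANTILE_METHOD)),
        "q3": float(np.quantile(v, 0.75, method=QUANTILE_METHOD)),
    }


def ratio_summary(pairs: PairedMeasurements) -> RatioSummary:
    """Per-pair ratio aᵢ/bᵢ statistics: mean, sample SD, mean ± 2·SD.

    Raises
    ------
    RatioError
        If any denominator is not strictly positive.
    """
    if (pairs.b <= 0).any():
        raise RatioError("ratio denominators must be strictly positive")
    r = pairs.a / pairs.b
    mean = float(r.mean())
    sd = float(r.std(ddof=1)) if r.size > 1 else 0.0
    return RatioSummary(
        mean_ratio=mean, sd_ratio=sd,
        interval_low=mean - 2 * sd, interval_high=mean + 2 * sd,
        n=r.size,
    )
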