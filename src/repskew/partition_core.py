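"""One-way grouped sums of squares: the shared ANOVA engine.

For groups ``g`` with members ``k_{i,g}``, group means ``kbar_g`` and grand
mean ``kbar``:

    SSE = sum_g sum_i (k_{i,g} - kbar_g)^2        (within groups)
    SSB = sum_g n_g (kbar_g - kbar)^2             (between groups)
    SST = SSE + SSB                               (additive identity)

Groups are ages (annual reproduction) or ages-at-death (lifetime reproductive
success); the algebra is identical.  Two variance conventions are carried
explicitly and never mixed: the *parametric* population variance divides the
total SS by N (``sigma2_k = SST / N``), while per-group *empirical* variances
use the unbiased n-1 denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .scaling import GroupRawStats


__all__ = ["SumsOfSquares", "grouped_ss", "grouped_ss_from_stats"]


@dataclass
class SumsOfSquares:
    SSE: float
    SSB: float
    SST: float
    n_groups: int
    N_total: int

    @property
    def sigma2_k(self) -> float:
        """Parametric overall variance, SST / N (denominator N, not N-1)."""
        return self.SST / self.N_total

    @property
    def frac_within(self) -> float:
        return self.SSE / self.SST if self.SST > 0 else float("nan")

    @property
    def frac_between(self) -> float:
        return self.SSB / self.SST if self.SST > 0 else float("nan")


def grouped_ss(groups: Sequence[Sequence[float]]) -> SumsOfSquares:
    """Within/between/total sums of squares from raw per-individual counts."""
    if len(groups) == 0:
        raise ValueError("need at least one group")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group: drop or merge before computing sums of squares")
    sizes = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    grand = float(np.concatenate(arrays).mean())
    sse = float(sum(((a - m) ** 2).sum() for a, m in zip(arrays, means)))
    ssb = float((sizes * (means - grand) ** 2).sum())
    return SumsOfSquares(
        SSE=sse, SSB=ssb, SST=sse + ssb,
        n_groups=len(arrays), N_total=int(sizes.sum()),
    )


def grouped_ss_from_stats(
    stats: Sequence[GroupRawStats], grand_mean: float | None = None
) -> SumsOfSquares:
    """Sums of squares from per-group sufficient statistics (n, kbar, s2).

    Equals :func:`grouped_ss` on any raw data with the same statistics, using
    ``SSE_g = (n_g - 1) * s2_g``.  Singleton groups contribute 0 to SSE (their
    sample variance is undefined; a flag is emitted when a nonzero ``s2`` was
    supplied for one).  The grand mean defaults to the size-weighted mean of
    the group means.
    """
    if len(stats) == 0:
        raise ValueError("need at least one group")
    n = np.array([s.n for s in stats], dtype=float)
    kbar = np.array([s.kbar for s in stats], dtype=float)
    s2 = np.array([s.s2 for s in stats], dtype=float)
    if grand_mean is None:
        grand_mean = float((n * kbar).sum() / n.sum())
    singleton = n == 1
    if np.any(singleton & (s2 > 0)):
        warnings.warn(
            "nonzero variance supplied for singleton group(s); treated as 0",
            stacklevel=2,
        )
    sse = float(((n - 1) * np.where(singleton, 0.0, s2)).sum())
    ssb = float((n * (kbar - grand_mean) ** 2).sum())
    return SumsOfSquares(
        SSE=sse, SSB=ssb, SST=sse + ssb,
        n_groups=len(stats), N_total=int(n.sum()),
    )
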