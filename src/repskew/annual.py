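"""Annual variance partitioning: within-age vs. between-age components.

Parametric expectations in a stable population are

    SSE_parametric = sum_x N_x phi_x b_x
    SSB_parametric = sum_x N_x (b_x - bbar)^2,      bbar = 2 N_1 / N_A,

and the estimators for empirical data sampled at intensity Q first rescale
the per-age raw statistics to the stable scale and then correct the between-
age component for its random part:

    SSE_hat = sum_x N_x sigma2_hat_x
    SSB_hat = sum_x N_x (b_hat_x - bbar_hat)^2  -  (n-1)/n * sum_x sigma2_hat_x

The (n-1)/n factor reflects the constraint that the rescaled age means are
anchored to their weighted grand mean, costing one degree of freedom; the
correction sums the rescaled variances *unweighted* over ages.

An age whose rescaled variance comes out negative (raw data more
underdispersed than subsampling any stable-scale distribution could produce,
``phi_raw < 1 - Q``) is by default excluded from the annual partition
entirely: the rescaling model is inconsistent for that group, and keeping it
with a clamped zero variance leaves a between-age bias at sparse sampling.
Set ``drop_negative_variance=False`` to keep such ages with variance 0
instead (the convention the lifetime estimator uses for death groups).
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .demography import VitalRates, estimate_Q_annual
from .partition_core import SumsOfSquares
from .scaling import GroupRawStats


__all__ = ["AnnualPartition", "parametric_ss_annual", "estimate_annual_partition"]


@dataclass
class AnnualPartition:
    """Estimated annual variance partition on the stable-population scale."""

    Q: float
    n_groups: int
    N_A: int
    bbar_hat: float          # rescaled overall mean offspring number
    SSE_hat: float           # sum N_x sigma2_hat_x
    SSB_scaled_raw: float    # sum N_x (b_hat_x - bbar_hat)^2, before correction
    SSB_random: float        # (n-1)/n * unweighted sum of sigma2_hat_x
    SSB_hat: float           # SSB_scaled_raw - SSB_random
    SSE_null: float          # Poisson-within-ages reference, sum N_x b_hat_x
    SSE_null_constant: float  # Wright-Fisher reference, bbar_hat * N_A
    sigma2_within_sum: float  # unweighted sum of sigma2_hat_x
    sum_ki2: float           # sum_x N_x (sigma2_hat_x + b_hat_x^2)
    per_age: pd.DataFrame = field(repr=False)

    @property
    def SST_hat(self) -> float:
        return self.SSE_hat + self.SSB_hat

    @property
    def SSE_gt_random(self) -> float:
        """Within-age component beyond the Poisson reference."""
        return self.SSE_hat - self.SSE_null

    @property
    def SSB_gt_random(self) -> float:
        """Between-age component beyond random (the corrected SSB itself)."""
        return self.SSB_hat

    @property
    def frac_within(self) -> float:
        return self.SSE_hat / self.SST_hat if self.SST_hat > 0 else float("nan")


def parametric_ss_annual(vr: VitalRates) -> SumsOfSquares:
    """Parametric annual sums of squares from stabilized vital rates.

    Requires ``b`` (stabilized) and ``phi``; group sizes are the census
    ``N_x = round(N1 l_x)`` and the parametric mean is ``bbar = 2 N1 / N_A``.
    Both SSE and SSB scale linearly with ``N1``, so the within/between split
    is independent of population size.
    """
    if vr.b is None or vr.phi is None:
        raise ValueError("vital rates must carry stabilized b and phi")
    N_x = vr.N_x
    N_A = int(N_x.sum())
    bbar = 2.0 * vr.N1 / N_A
    sse = float((N_x * vr.phi * vr.b).sum())
    ssb = float((N_x * (vr.b - bbar) ** 2).sum())
    return SumsOfSquares(SSE=sse, SSB=ssb, SST=sse + ssb,
                         n_groups=vr.n_classes, N_total=N_A)


def estimate_annual_partition(
    stats: Sequence[GroupRawStats],
    vr: VitalRates | None = None,
    Q: float | None = None,
    N_x: np.ndarray | None = None,
    l: np.ndarray | None = None,
    drop_negative_variance: bool = True,
) -> AnnualPartition:
    """Estimate the annual partition from per-age raw statistics.

    Parameters
    ----------
    stats
        One :class:`~repskew.scaling.GroupRawStats` per observed adult age,
        in age order.  Group sizes are the known census sizes ``N_x``.
    vr
        Vital rates providing ``N_x`` and survivorship ``l`` (used to
        estimate ``Q`` when not given).  Alternatively pass ``N_x``/``l``
        directly.
    Q
        Sampling intensity.  Estimated as ``sum(l_x kbar_x) / 2`` from the
        supplied survivorship when omitted.
    drop_negative_variance
        Exclude ages whose rescaled variance is negative from the partition
        (see module docstring).  Ages with zero raw mean are always kept
        (their rescaled variance is 0 by convention).
    """
    if vr is not None:
        N_x = vr.N_x
        if l is None:
            l = vr.l
    if N_x is None:
        N_x = np.array([s.n for s in stats], dtype=int)
    N_x = np.asarray(N_x, dtype=int)
    if len(N_x) != len(stats):
        raise ValueError("per-age stats and N_x are misaligned")

    kbar = np.array([s.kbar for s in stats], dtype=float)
    if Q is None:
        if l is None:
            raise ValueError("need survivorship l (or explicit Q) to rescale")
        Q = estimate_Q_annual(np.asarray(l, float), kbar)
    if Q <= 0:
        raise ValueError("sampling intensity Q must be positive")

    s2 = np.array([s.s2 for s in stats], dtype=float)
    b_hat = kbar / Q
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_scaled = b_hat * (1.0 + (s2 / kbar - 1.0) / Q)
    raw_scaled = np.where(kbar > 0, raw_scaled, 0.0)

    keep = np.ones(len(stats), dtype=bool)
    if np.any(raw_scaled < 0):
        labels = [stats[i].label for i in np.flatnonzero(raw_scaled < 0)]
        if drop_negative_variance:
            keep = raw_scaled >= 0
            warnings.warn(
                f"dropping age group(s) {labels} with negative rescaled "
                "variance (underdispersed raw data)", stacklevel=2)
        else:
            warnings.warn(
                f"clamping negative rescaled variance to 0 for age "
                f"group(s) {labels}", stacklevel=2)
    if not keep.any():
        raise ValueError("every age group was dropped: no partition possible")
    sigma2_hat = np.maximum(raw_scaled, 0.0)

    stats = [s for s, k in zip(stats, keep) if k]
    N_x, kbar = N_x[keep], kbar[keep]
    b_hat, sigma2_hat = b_hat[keep], sigma2_hat[keep]
    N_A = int(N_x.sum())
    n = len(stats)
    kbar_dot = float((N_x * kbar).sum() / N_A)
    bbar_hat = kbar_dot / Q

    sse_hat = float((N_x * sigma2_hat).sum())
    ssb_scaled_raw = float((N_x * (b_hat - bbar_hat) ** 2).sum())
    sigma2_within_sum = float(sigma2_hat.sum())
    ssb_random = (n - 1) / n * sigma2_within_sum
    ssb_hat = ssb_scaled_raw - ssb_random
    sse_null = float((N_x * b_hat).sum())
    sum_ki2 = float((N_x * (sigma2_hat + b_hat**2)).sum())

    per_age = pd.DataFrame(
        {
            "age": [s.label for s in stats],
            "N_x": N_x,
            "kbar_raw": kbar,
            "s2_raw": [s.s2 for s in stats],
            "b_hat": b_hat,
            "sigma2_hat": sigma2_hat,
            "phi_hat": np.divide(sigma2_hat, b_hat,
                                 out=np.full(n, np.nan), where=b_hat > 0),
            "SSE_x": N_x * sigma2_hat,
            "SSE_random_x": N_x * b_hat,
            "SSB_x": N_x * (b_hat - bbar_hat) ** 2,
            "sum_ki2_x": N_x * (sigma2_hat + b_hat**2),
        }
    )

    return AnnualPartition(
        Q=float(Q), n_groups=n, N_A=N_A, bbar_hat=bbar_hat,
        SSE_hat=sse_hat, SSB_scaled_raw=ssb_scaled_raw,
        SSB_random=ssb_random, SSB_hat=ssb_hat,
        SSE_null=sse_null, SSE_null_constant=bbar_hat * N_A,
        sigma2_within_sum=sigma2_within_sum, sum_ki2=sum_ki2,
        per_age=per_age,
    )
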