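"""Effective size (N_b, N_e) and opportunity-for-selection metrics.

The annual effective number of breeders follows the discrete-generation
inbreeding formula

    N_b = (kbar N_A - 1) / (kbar - 1 + sigma2_k / kbar),

with the overall variance assembled age by age through the identity
``sum(k_i^2) = N (sigma2 + kbar^2)``.  Per-generation effective size uses
Hill's approximation ``N_e ~ 4 N_1 T / (sigma2_LRS + 2)``.

Crow's opportunity for selection is ``I = sigma2_k / kbar^2`` (the variance
of relative fitness).  Its greater-than-random versions subtract the Poisson
expectation ``1/kbar`` (annual) and, for lifetime data, additionally the
expected contribution of random variation in longevity:

    dI  = I - 1/kbar
    dI. = I. - 1/mean_LRS - C,     C = sum D_q (q - qbar)^2 / (qbar^2 sum D_q).

Annual I is computed on the rescaled (stable-population) scale; lifetime I.
is deliberately computed on the raw scale, where C is sampling-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annual import AnnualPartition
from .demography import DeathStructure


__all__ = [
    "EffSizeResult",
    "OFSResult",
    "AttributionResult",
    "sum_k_squared",
    "overall_variance",
    "effective_breeders",
    "effective_size_generation",
    "wright_sex_ratio",
    "opportunity_annual",
    "opportunity_lifetime",
    "attribute_reductions",
    "annual_effective_size",
]


@dataclass
class EffSizeResult:
    kbar: float
    sigma2_k: float
    sum_ki2: float
    N_A: int
    Nb: float
    ratio: float


@dataclass
class OFSResult:
    I: float
    dI: float
    C: float = 0.0


@dataclass
class AttributionResult:
    """Within/between split of the greater-than-random components."""

    within_share: float
    between_share: float
    total_reduction: float       # 1 - Nb/N_A
    within_reduction: float
    between_reduction: float
    dI_within: float
    dI_between: float


def sum_k_squared(N: int, sigma2: float, kbar: float) -> float:
    """Sum of squared offspring numbers implied by (N, sigma2, kbar)."""
    if N < 0:
        raise ValueError("N must be non-negative")
    return N * (sigma2 + kbar**2)


def overall_variance(sum_ki2: float, N_A: int, kbar: float,
                     tol: float = 1e-9) -> float:
    """Overall parametric variance from the summed squares identity."""
    if N_A <= 0:
        raise ValueError("N_A must be positive")
    sigma2 = sum_ki2 / N_A - kbar**2
    if sigma2 < -tol * max(1.0, kbar**2):
        raise ValueError("inconsistent inputs: negative overall variance")
    return max(sigma2, 0.0)


def effective_breeders(kbar: float, sigma2: float, N_A: int) -> tuple[float, float]:
    """Effective number of breeders per year and the ratio Nb / N_A."""
    denom = kbar - 1.0 + sigma2 / kbar
    if denom <= 0:
        raise ValueError("non-positive denominator in the Nb formula")
    nb = (kbar * N_A - 1.0) / denom
    return nb, nb / N_A


def effective_size_generation(N1: int, T: float, sigma2_lrs: float) -> float:
    """Per-generation effective size, ``Ne ~ 4 N1 T / (sigma2_LRS + 2)``.

    With Poisson lifetime variance (``sigma2_LRS = mean LRS = 2``) this
    reduces to ``Ne = N1 T``, the newborns entering per generation.
    """
    if T <= 0:
        raise ValueError("generation length must be positive")
    if sigma2_lrs < 0:
        raise ValueError("lifetime variance must be non-negative")
    return 4.0 * N1 * T / (sigma2_lrs + 2.0)


def wright_sex_ratio(Nb_m: float, Nb_f: float) -> float:
    """Two-sex effective size from per-sex values: ``4ab / (a + b)``."""
    if Nb_m <= 0 or Nb_f <= 0:
        raise ValueError("per-sex effective sizes must be positive")
    return 4.0 * Nb_m * Nb_f / (Nb_m + Nb_f)


def opportunity_annual(kbar: float, sigma2: float) -> OFSResult:
    """Crow's I and its greater-than-Poisson part for annual reproduction."""
    if kbar <= 0:
        raise ValueError("mean offspring number must be positive")
    I = sigma2 / kbar**2
    return OFSResult(I=I, dI=I - 1.0 / kbar)


def opportunity_lifetime(
    mean_lrs: float, s2_lrs: float, deaths: DeathStructure
) -> OFSResult:
    """Lifetime opportunity for selection on the raw scale.

    ``C`` is the expected contribution of random variation in longevity,
    computed from the age-at-death distribution alone, so the subtraction
    isolates greater-than-random variance in LRS.
    """
    if mean_lrs <= 0:
        raise ValueError("mean LRS must be positive")
    if deaths.total <= 0:
        raise ValueError("death structure is empty")
    I_dot = s2_lrs / mean_lrs**2
    qbar = deaths.qbar
    C = float((deaths.D_q * (deaths.q - qbar) ** 2).sum()
              / (qbar**2 * deaths.total))
    return OFSResult(I=I_dot, dI=I_dot - 1.0 / mean_lrs - C, C=C)


def attribute_reductions(
    partition: AnnualPartition, ratio: float, dI: float
) -> AttributionResult:
    """Split effective-size reduction and dI into within/between-age parts.

    The greater-than-random within-age (SSE beyond Poisson) and between-age
    (corrected SSB) components define the shares; the total reduction in
    ``Nb/N_A`` (relative to the Wright-Fisher value of 1) and ``dI`` are
    apportioned proportionally.
    """
    sse_gt = partition.SSE_gt_random
    ssb_gt = partition.SSB_gt_random
    total = sse_gt + ssb_gt
    if total <= 0:
        raise ValueError("no greater-than-random component: shares undefined")
    w = sse_gt / total
    reduction = 1.0 - ratio
    return AttributionResult(
        within_share=w, between_share=1.0 - w,
        total_reduction=reduction,
        within_reduction=w * reduction,
        between_reduction=(1.0 - w) * reduction,
        dI_within=w * dI, dI_between=(1.0 - w) * dI,
    )


def annual_effective_size(partition: AnnualPartition) -> EffSizeResult:
    """Assemble Nb and the overall variance from an annual partition."""
    sigma2 = overall_variance(partition.sum_ki2, partition.N_A,
                              partition.bbar_hat)
    nb, ratio = effective_breeders(partition.bbar_hat, sigma2, partition.N_A)
    return EffSizeResult(
        kbar=partition.bbar_hat, sigma2_k=sigma2, sum_ki2=partition.sum_ki2,
        N_A=partition.N_A, Nb=nb, ratio=ratio,
    )
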