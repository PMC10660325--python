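"""Crow-Morton rescaling of raw offspring means and variances.

Raw means and variances of offspring number depend on how intensively
offspring were sampled.  Given the sampling-intensity index ``Q`` (observed
offspring relative to the stable-population expectation), raw group means are
rescaled as ``b_hat = kbar / Q`` and raw unbiased variances as

    sigma2_hat = b_target * (1 + (1/Q) * (phi_raw - 1)),   phi_raw = s2 / kbar,

which is the expected variance had sampling been at the level producing mean
``b_target``.  The same law applies to age groups (annual data) and
age-at-death groups (lifetime data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


__all__ = ["GroupRawStats", "rescale_mean", "rescale_variance", "rescale_group"]


@dataclass
class GroupRawStats:
    """Sufficient statistics for one ANOVA group of offspring counts.

    ``label`` is the age ``x`` (annual analysis) or age-at-death ``q``
    (lifetime analysis); ``n`` the group size (``N_x`` or ``D_q``); ``kbar``
    and ``s2`` the raw mean and unbiased (n-1 denominator) sample variance.
    """

    label: object
    n: int
    kbar: float
    s2: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.label!r}: size must be >= 1")
        if self.kbar < 0:
            raise ValueError(f"group {self.label!r}: mean must be >= 0")
        if self.s2 < 0:
            raise ValueError(f"group {self.label!r}: variance must be >= 0")

    @property
    def phi_raw(self) -> float:
        """Raw variance-to-mean ratio; ``nan`` when the mean is zero."""
        return self.s2 / self.kbar if self.kbar > 0 else float("nan")


def rescale_mean(kbar: float, Q: float) -> float:
    """Rescaled group mean ``b_hat = kbar / Q``."""
    if Q <= 0:
        raise ValueError("sampling intensity Q must be positive")
    return kbar / Q


def rescale_variance(b_target: float, kbar: float, s2: float, Q: float) -> float:
    """Rescaled within-group variance at target mean ``b_target``.

    Under-dispersed raw data (``phi_raw < 1``) can drive the rescaled value
    negative when ``Q < 1``; such values are clamped to 0 with a warning and
    the clamped value is what downstream sums use.  A zero raw mean leaves
    ``phi_raw`` undefined and also returns 0 with a warning.
    """
    if Q <= 0:
        raise ValueError("sampling intensity Q must be positive")
    if b_target < 0:
        raise ValueError("target mean must be non-negative")
    if kbar == 0:
        warnings.warn(
            "raw group mean is 0: phi_raw undefined, rescaled variance set to 0",
            stacklevel=2,
        )
        return 0.0
    value = b_target * (1.0 + (s2 / kbar - 1.0) / Q)
    if value < 0:
        warnings.warn(
            "rescaled variance was negative (under-dispersed raw data); "
            "clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return value


def rescale_group(stats: GroupRawStats, Q: float) -> tuple[float, float]:
    """Rescale one group's (mean, variance) with a common ``Q``."""
    b_hat = rescale_mean(stats.kbar, Q)
    sigma2_hat = rescale_variance(b_hat, stats.kbar, stats.s2, Q)
    return b_hat, sigma2_hat
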