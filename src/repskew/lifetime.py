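"""Lifetime reproductive success (LRS) partitioning by age-at-death.

Grouping individuals by the age ``q`` at which they last reproduced turns the
same one-way ANOVA algebra used for annual data into a partition of variance
in LRS.  Because individuals that die at different ages accumulate different
numbers of reproductive seasons, random variation in longevity contributes to
the between-group component; holding fecundity constant with age isolates it:

    SSE._parametric       = sum_q D_q sum_{x<=q} phi_x b_x
    SSB._parametric       = sum_q D_q (sum_{x<=q} b_x - 2)^2
    SSB._longevity        = sum_q D_q (q bbar - 2)^2

(the stable-population grand mean of LRS is 2 offspring per parent).  The
within-group expansion also carries covariances of an individual's counts
across years; the closed forms above assume reproduction at one age does not
affect survival or reproduction later, which empirical persistent individual
differences or skip breeding will violate (they load on SSE.).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .demography import DeathStructure, VitalRates, cohort_structure
from .scaling import GroupRawStats, rescale_group


__all__ = [
    "LifetimePartition",
    "lrs_from_matrix",
    "records_to_stats",
    "parametric_ss_lifetime",
    "estimate_lifetime_partition",
    "estimate_lifetime_from_records",
    "rho_alpha_plus",
]


@dataclass
class LifetimePartition:
    """Estimated lifetime variance partition on the stable-population scale."""

    Q: float
    n_groups: int
    N1: int
    bbar_hat: float            # 2 N1 / sum(q D_q), constant annual mean
    mean_lrs_raw: float
    s2_lrs_raw: float          # unbiased cohort variance of raw LRS
    SSE_dot_hat: float
    SSE_dot_random: float      # Poisson-within-years reference, sum D_q q bbar_hat
    SSB_dot_scaled_raw: float
    SSB_dot_random: float      # (n-1)/n correction
    SSB_dot_hat: float
    SSB_dot_longevity: float
    sigma2_within_sum: float
    deaths: DeathStructure
    per_group: pd.DataFrame = field(repr=False)

    @property
    def SST_dot_hat(self) -> float:
        return self.SSE_dot_hat + self.SSB_dot_hat

    @property
    def frac_within(self) -> float:
        return self.SSE_dot_hat / self.SST_dot_hat

    @property
    def frac_between(self) -> float:
        return self.SSB_dot_hat / self.SST_dot_hat


def lrs_from_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Derive age-at-death and LRS from a per-individual annual matrix.

    ``matrix`` has one row per parent (index = id) and one column per age;
    entries are offspring counts for observed years and NaN for years in
    which the individual was not observed.  Missing entries never extend the
    lifespan and contribute 0 to LRS; an observed 0 does count as a breeding
    attempt.  Age-at-death ``q`` is the oldest age with an observation.
    """
    values = matrix.to_numpy(dtype=float)
    observed = ~np.isnan(values)
    if values.shape[1] == 0:
        raise ValueError("matrix has no age columns")
    bad = ~observed.any(axis=1)
    if bad.any():
        ids = list(matrix.index[bad])
        raise ValueError(f"rows with no observed entries: {ids}")
    ages = np.arange(1, values.shape[1] + 1)
    q = ages[observed.shape[1] - 1 - np.argmax(observed[:, ::-1], axis=1)]
    lrs = np.nansum(values, axis=1)
    if not np.allclose(lrs, np.rint(lrs)):
        raise ValueError("offspring counts must be integers")
    return pd.DataFrame({"q": q.astype(int), "lrs": lrs.astype(int)},
                        index=matrix.index)


def records_to_stats(
    records: pd.DataFrame,
) -> tuple[list[GroupRawStats], DeathStructure]:
    """Per-age-at-death sufficient statistics from (q, lrs) records."""
    groups = []
    qs, counts = [], []
    for q, sub in records.groupby("q", sort=True):
        lrs = sub["lrs"].to_numpy(dtype=float)
        s2 = float(lrs.var(ddof=1)) if len(lrs) > 1 else 0.0
        groups.append(GroupRawStats(label=int(q), n=len(lrs),
                                    kbar=float(lrs.mean()), s2=s2))
        qs.append(int(q))
        counts.append(len(lrs))
    return groups, DeathStructure(q=np.array(qs), D_q=np.array(counts))


def parametric_ss_lifetime(vr: VitalRates) -> tuple[float, float, float]:
    """Parametric (SSE., SSB., SSB._longevity) from stabilized vital rates.

    Assumes independence of an individual's reproduction across ages, and a
    life table without a pooled plus-group (death counts must be derivable).
    """
    if vr.b is None or vr.phi is None:
        raise ValueError("vital rates must carry stabilized b and phi")
    N_x, deaths = cohort_structure(vr)
    if deaths is None:
        raise ValueError("death structure undefined for this life table")
    D = deaths.D_q.astype(float)
    cum_phib = np.cumsum(vr.phi * vr.b)
    cum_b = np.cumsum(vr.b)
    bbar = 2.0 * vr.N1 / N_x.sum()
    reps = deaths.q - vr.alpha + 1  # reproductive seasons lived
    sse = float((D * cum_phib).sum())
    ssb = float((D * (cum_b - 2.0) ** 2).sum())
    ssb_long = float((D * (reps * bbar - 2.0) ** 2).sum())
    return sse, ssb, ssb_long


def estimate_lifetime_partition(
    stats: Sequence[GroupRawStats],
    Q: float | None = None,
    N1: int | None = None,
    weighted_correction: bool = False,
) -> LifetimePartition:
    """Estimate the lifetime partition from per-age-at-death statistics.

    Parameters
    ----------
    stats
        One :class:`~repskew.scaling.GroupRawStats` per age-at-death ``q``
        (integer labels), with ``n = D_q`` individuals dying after age ``q``.
    Q
        Sampling intensity; defaults to (mean raw LRS) / 2.
    N1
        Cohort size; defaults to ``sum(D_q)`` (a complete cohort).
    weighted_correction
        The (n-1)/n random correction to SSB. sums the rescaled group
        variances unweighted by default; set True to weight them by ``D_q``
        instead (an alternative reading of the estimator).
    """
    if any(not isinstance(s.label, (int, np.integer)) for s in stats):
        raise ValueError("age-at-death labels must be integers")
    q = np.array([int(s.label) for s in stats])
    D = np.array([s.n for s in stats], dtype=float)
    kbar = np.array([s.kbar for s in stats], dtype=float)
    s2 = np.array([s.s2 for s in stats], dtype=float)
    if np.any(D < 0):
        raise ValueError("death counts must be non-negative")
    n = len(stats)
    total = D.sum()
    mean_lrs = float((D * kbar).sum() / total)
    if Q is None:
        Q = mean_lrs / 2.0
    if Q <= 0:
        raise ValueError("sampling intensity Q must be positive")
    if N1 is None:
        N1 = int(total)

    deaths = DeathStructure(q=q, D_q=D.astype(int))
    # sum(q D_q) reconstructs the adult census sum(N_x) when age at maturity
    # is 1 and the cohort is complete
    bbar_hat = 2.0 * N1 / deaths.adult_years

    scaled = [rescale_group(s, Q) for s in stats]
    sum_b_hat = np.array([m for m, _ in scaled])   # scaled group mean LRS
    sigma2_hat = np.array([v for _, v in scaled])

    sse_hat = float((D * sigma2_hat).sum())
    sse_random = float((D * q * bbar_hat).sum())
    ssb_scaled_raw = float((D * (sum_b_hat - 2.0) ** 2).sum())
    sigma2_within_sum = float(sigma2_hat.sum())
    if weighted_correction:
        ssb_random = (n - 1) / n * float((D * sigma2_hat).sum())
    else:
        ssb_random = (n - 1) / n * sigma2_within_sum
    ssb_hat = ssb_scaled_raw - ssb_random
    ssb_long = float((D * (q * bbar_hat - 2.0) ** 2).sum())

    # raw-scale cohort variance of LRS (used by the lifetime selection metrics)
    sse_raw = float(((D - 1) * s2).sum())
    ssb_raw = float((D * (kbar - mean_lrs) ** 2).sum())
    s2_lrs_raw = (sse_raw + ssb_raw) / (total - 1) if total > 1 else 0.0

    per_group = pd.DataFrame(
        {
            "q": q,
            "D_q": D.astype(int),
            "kbar_raw": kbar,
            "s2_raw": s2,
            "sum_b_hat": sum_b_hat,
            "sigma2_hat": sigma2_hat,
            "phi_hat": np.divide(sigma2_hat, sum_b_hat,
                                 out=np.full(n, np.nan), where=sum_b_hat > 0),
            "SSE_q": D * sigma2_hat,
            "SSE_random_q": D * q * bbar_hat,
            "SSB_q": D * (sum_b_hat - 2.0) ** 2,
            "SSB_longevity_q": D * (q * bbar_hat - 2.0) ** 2,
        }
    )

    return LifetimePartition(
        Q=float(Q), n_groups=n, N1=N1, bbar_hat=bbar_hat,
        mean_lrs_raw=mean_lrs, s2_lrs_raw=s2_lrs_raw,
        SSE_dot_hat=sse_hat, SSE_dot_random=sse_random,
        SSB_dot_scaled_raw=ssb_scaled_raw, SSB_dot_random=ssb_random,
        SSB_dot_hat=ssb_hat, SSB_dot_longevity=ssb_long,
        sigma2_within_sum=sigma2_within_sum, deaths=deaths,
        per_group=per_group,
    )


def estimate_lifetime_from_records(
    records: pd.DataFrame,
    Q: float | None = None,
    weighted_correction: bool = False,
) -> LifetimePartition:
    """Full lifetime pipeline from per-individual (q, lrs) records."""
    stats, _ = records_to_stats(records)
    return estimate_lifetime_partition(
        stats, Q=Q, N1=len(records), weighted_correction=weighted_correction
    )


def rho_alpha_plus(
    matrix: pd.DataFrame, alpha: int = 1
) -> tuple[float, float, int]:
    """Correlation between reproduction at maturity and the rest of life.

    Computes the product-moment correlation, across individuals, between the
    offspring count at the age at maturity ``alpha`` and the total offspring
    produced over the remainder of the lifetime (LRS minus the age-``alpha``
    count), with a two-tailed p-value from the t approximation.  Persistent
    individual differences push the correlation positive; skip breeding or
    survival costs of reproduction push it negative.  Unobserved (missing)
    age-``alpha`` entries are treated as 0 offspring, flagged with a warning.
    """
    derived = lrs_from_matrix(matrix)
    col = matrix.columns[alpha - 1]
    k_alpha = matrix[col].to_numpy(dtype=float)
    if np.isnan(k_alpha).any():
        warnings.warn(
            "missing age-at-maturity entries treated as 0 offspring",
            stacklevel=2,
        )
        k_alpha = np.nan_to_num(k_alpha)
    rest = derived["lrs"].to_numpy(dtype=float) - k_alpha
    n = len(k_alpha)
    if n < 3:
        raise ValueError("need at least 3 individuals")
    if np.var(k_alpha) == 0 or np.var(rest) == 0:
        raise ValueError("zero variance in a margin: correlation undefined")
    r, p = sp_stats.pearsonr(k_alpha, rest)
    return float(r), float(p), n
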