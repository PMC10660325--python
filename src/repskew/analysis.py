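"""High-level pipelines bundling partition, effective size and selection metrics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from . import __version__ as _version
from .annual import AnnualPartition, estimate_annual_partition
from .demography import VitalRates
from .lifetime import (
    LifetimePartition,
    estimate_lifetime_from_records,
    estimate_lifetime_partition,
)
from .scaling import GroupRawStats
from .selection import (
    AttributionResult,
    EffSizeResult,
    OFSResult,
    annual_effective_size,
    attribute_reductions,
    opportunity_annual,
    opportunity_lifetime,
)


__all__ = ["AnnualAnalysis", "LifetimeAnalysis", "analyze_annual",
           "analyze_lifetime"]


@dataclass
class AnnualAnalysis:
    partition: AnnualPartition
    effsize: EffSizeResult
    ofs: OFSResult
    attribution: AttributionResult

    def to_report(self) -> dict:
        p, e, o, a = self.partition, self.effsize, self.ofs, self.attribution
        return {
            "analysis": "annual variance partition",
            "version": _version,
            "Q": p.Q,
            "n_age_classes": p.n_groups,
            "N_A": p.N_A,
            "bbar_hat": p.bbar_hat,
            "SSE_hat": p.SSE_hat,
            "SSB_scaled_raw": p.SSB_scaled_raw,
            "SSB_random": p.SSB_random,
            "SSB_hat": p.SSB_hat,
            "SSE_null": p.SSE_null,
            "SST_hat": p.SST_hat,
            "frac_within": p.frac_within,
            "sum_ki2": p.sum_ki2,
            "sigma2_k": e.sigma2_k,
            "Nb": e.Nb,
            "Nb_over_NA": e.ratio,
            "I": o.I,
            "dI": o.dI,
            "within_share_gt_random": a.within_share,
            "between_share_gt_random": a.between_share,
            "per_age": self.partition.per_age.to_dict(orient="records"),
        }


@dataclass
class LifetimeAnalysis:
    partition: LifetimePartition
    ofs: OFSResult

    def to_report(self) -> dict:
        p, o = self.partition, self.ofs
        return {
            "analysis": "lifetime variance partition",
            "version": _version,
            "Q": p.Q,
            "n_death_groups": p.n_groups,
            "N1": p.N1,
            "mean_lrs_raw": p.mean_lrs_raw,
            "s2_lrs_raw": p.s2_lrs_raw,
            "bbar_hat": p.bbar_hat,
            "SSE_dot_hat": p.SSE_dot_hat,
            "SSE_dot_random": p.SSE_dot_random,
            "SSB_dot_scaled_raw": p.SSB_dot_scaled_raw,
            "SSB_dot_random": p.SSB_dot_random,
            "SSB_dot_hat": p.SSB_dot_hat,
            "SSB_dot_longevity": p.SSB_dot_longevity,
            "SST_dot_hat": p.SST_dot_hat,
            "frac_within": p.frac_within,
            "frac_between": p.frac_between,
            "qbar": p.deaths.qbar,
            "I_dot_raw": o.I,
            "C_longevity": o.C,
            "dI_dot": o.dI,
            "per_group": p.per_group.to_dict(orient="records"),
        }


def analyze_annual(
    stats: Sequence[GroupRawStats],
    vr: VitalRates,
    Q: float | None = None,
) -> AnnualAnalysis:
    """Annual pipeline: rescale, partition, effective size, selection metrics."""
    partition = estimate_annual_partition(stats, vr=vr, Q=Q)
    effsize = annual_effective_size(partition)
    ofs = opportunity_annual(effsize.kbar, effsize.sigma2_k)
    attribution = attribute_reductions(partition, effsize.ratio, ofs.dI)
    return AnnualAnalysis(partition=partition, effsize=effsize, ofs=ofs,
                          attribution=attribution)


def analyze_lifetime(
    stats: Sequence[GroupRawStats] | None = None,
    records: pd.DataFrame | None = None,
    Q: float | None = None,
    N1: int | None = None,
    weighted_correction: bool = False,
) -> LifetimeAnalysis:
    """Lifetime pipeline from group summaries or per-individual records."""
    if (stats is None) == (records is None):
        raise ValueError("pass exactly one of stats or records")
    if records is not None:
        partition = estimate_lifetime_from_records(
            records, Q=Q, weighted_correction=weighted_correction)
    else:
        partition = estimate_lifetime_partition(
            stats, Q=Q, N1=N1, weighted_correction=weighted_correction)
    ofs = opportunity_lifetime(partition.mean_lrs_raw, partition.s2_lrs_raw,
                               partition.deaths)
    return LifetimeAnalysis(partition=partition, ofs=ofs)
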