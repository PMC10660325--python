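"""Bootstrap uncertainty for the lifetime variance partition.

Individuals (whole lifetime rows) are resampled with replacement; within each
replicate the sampling intensity Q, the age-at-death groups, the rescaling
and the partition are all re-derived, so the intervals propagate every
data-dependent step.  Intervals are empirical percentiles (2.5 / 50 / 97.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lifetime import estimate_lifetime_from_records


__all__ = ["BootstrapResult", "bootstrap_lifetime"]

_STATS = ("SSE_dot_hat", "SSB_dot_hat", "frac_between")


@dataclass
class BootstrapResult:
    B: int
    seed: int | None
    n_failed: int
    intervals: pd.DataFrame          # rows: statistic; cols: lower/median/upper
    samples: pd.DataFrame = field(repr=False)

    def __getitem__(self, stat: str) -> tuple[float, float, float]:
        row = self.intervals.loc[stat]
        return float(row["lower"]), float(row["median"]), float(row["upper"])


def bootstrap_lifetime(
    records: pd.DataFrame,
    B: int = 1000,
    seed: int | None = None,
    weighted_correction: bool = False,
) -> BootstrapResult:
    """Percentile bootstrap of the lifetime partition.

    Parameters
    ----------
    records
        Per-individual table with columns ``q`` and ``lrs`` (as produced by
        :func:`repskew.lifetime.lrs_from_matrix`).
    B
        Number of bootstrap replicates (>= 100).
    seed
        Seed for the resampling generator; fixed seed gives identical output.

    Replicates in which every resampled individual shares one age-at-death
    have no between-group axis; they are skipped and counted in ``n_failed``.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 individuals to bootstrap")
    if B < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    rng = np.random.default_rng(seed)
    n = len(records)
    q = records["q"].to_numpy()
    # a cohort that already has a single death-age group is degenerate but
    # bootstrappable; otherwise single-group resamples lose the between axis
    min_groups = 2 if len(np.unique(q)) >= 2 else 1
    rows = []
    n_failed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clamped variances are routine here
        for _ in range(B):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(q[idx])) < min_groups:
                n_failed += 1
                continue
            part = estimate_lifetime_from_records(
                records.iloc[idx], weighted_correction=weighted_correction
            )
            rows.append((part.SSE_dot_hat, part.SSB_dot_hat,
                         part.frac_between))
    samples = pd.DataFrame(rows, columns=list(_STATS))
    quantiles = samples.quantile([0.025, 0.5, 0.975]).T
    quantiles.columns = ["lower", "median", "upper"]
    return BootstrapResult(B=B, seed=seed, n_failed=n_failed,
                           intervals=quantiles, samples=samples)
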