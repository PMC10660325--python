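"""Bundled worked-example inputs.

Two published field datasets, shipped as the raw columns printed in their
sources so the full estimation pipelines can be exercised end to end:

* Michigan black bear males -- age-specific annual survival, raw mean and
  unbiased variance of offspring number from sparse genetic parentage
  sampling (cohort size 260 yearling males/year; ages over 10 pooled into an
  ``11+`` class whose pooled survivorship is given directly).
* Hoge-Veluwe great tit females, 1980 cohort -- per-age-at-death summary of
  lifetime reproductive success for 81 females (counts, means, unbiased
  variances, and the reconstructed census sizes), plus the five-row excerpt
  of the per-individual annual matrix used to illustrate the missing-data
  semantics.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from ..demography import VitalRates
from ..io import read_lifetime_summary, read_lrs_matrix, read_vital_rates
from ..scaling import GroupRawStats


__all__ = [
    "load_black_bear_males",
    "load_great_tit_summary",
    "load_great_tit_matrix_excerpt",
]

BLACK_BEAR_N1 = 260  # yearling males recruited per year
GREAT_TIT_N1 = 81    # females in the 1980 cohort


def _path(name: str):
    return resources.files(__package__) / name


def load_black_bear_males() -> tuple[VitalRates, list[GroupRawStats]]:
    """Annual vital rates and raw per-age statistics for male black bears."""
    with resources.as_file(_path("black_bear_males.csv")) as p:
        return read_vital_rates(p, N1=BLACK_BEAR_N1)


def load_great_tit_summary() -> tuple[list[GroupRawStats], np.ndarray]:
    """Per-age-at-death LRS summary for the 1980 great tit female cohort."""
    with resources.as_file(_path("great_tit_1980_summary.csv")) as p:
        stats, N_x = read_lifetime_summary(p)
    return stats, N_x


def load_great_tit_matrix_excerpt() -> pd.DataFrame:
    """Five-row excerpt of the great tit per-individual annual matrix."""
    with resources.as_file(_path("great_tit_matrix_excerpt.csv")) as p:
        return read_lrs_matrix(p)
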