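"""Life-table bookkeeping for age-structured, birth-pulse populations.

The demographic model is a single-sex, discrete-time, birth-pulse life cycle:
an individual of age ``x`` produces on average ``b_x`` offspring (counted as
recruits that survive to age 1) and survives to age ``x + 1`` with probability
``v_x``.  Cumulative survivorship is ``l_x`` with ``l_1 = 1`` at the first age,
and in a constant population each cohort of ``N_1`` yearlings yields an
expected ``N_x = N_1 * l_x`` individuals of age ``x`` alive at any census.

A stable population of constant size requires each parent to replace itself
and one mate across its lifetime, i.e. ``sum(l_x * b_x) = 2`` in single-sex
accounting with an even primary sex ratio.  That identity anchors both the
fecundity stabilization and the sampling-intensity index ``Q`` used elsewhere
in the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


__all__ = [
    "VitalRates",
    "DeathStructure",
    "stabilize_fecundity",
    "survivorship_from_survival",
    "cohort_structure",
    "death_structure",
    "estimate_Q_annual",
    "estimate_Q_lifetime",
    "generation_length",
]


@dataclass
class VitalRates:
    """Age-specific vital rates for the adult portion of a life table.

    Parameters
    ----------
    ages
        Adult ages, ``alpha .. omega``, strictly increasing integers.  When
        ``plus_group`` is true the final entry is a pooled terminal class
        ("omega+") whose nominal age is its first pooled year.
    l
        Cumulative survivorship to each age (``l = 1`` at age 1 by
        convention).  A plus-group entry carries the *pooled* survivorship
        ``sum(l_x)`` over all pooled ages and is exempt from monotonicity.
    b
        Expected offspring per parent of each age, on the stable-population
        scale (``sum(l_x * b_x) = 2``).  Optional until stabilized.
    phi
        Age-specific variance-to-mean ratios ``sigma2_kx / b_x``.  Optional.
    N1
        Cohort size: single-sex recruits entering the population per year.
    plus_group
        Whether the last age class pools all older ages.
    """

    ages: np.ndarray
    l: np.ndarray
    N1: int
    b: np.ndarray | None = None
    phi: np.ndarray | None = None
    plus_group: bool = False
    v: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.l = np.asarray(self.l, dtype=float)
        if self.b is not None:
            self.b = np.asarray(self.b, dtype=float)
        if self.phi is not None:
            self.phi = np.asarray(self.phi, dtype=float)
        if self.ages.shape != self.l.shape:
            raise ValueError("ages and l must have the same length")
        if self.N1 <= 0:
            raise ValueError("cohort size N1 must be positive")
        if np.any(self.l < 0) or np.any(self.l > 1 + 1e-12):
            raise ValueError("survivorship l must lie in [0, 1]")
        core = self.l[:-1] if self.plus_group else self.l
        if np.any(np.diff(core) > 1e-12):
            raise ValueError("survivorship l must be non-increasing with age")
        if self.b is not None and np.any(self.b < 0):
            raise ValueError("fecundities b must be non-negative")

    @property
    def alpha(self) -> int:
        """First adult age."""
        return int(self.ages[0])

    @property
    def omega(self) -> int:
        """Last (nominal) adult age."""
        return int(self.ages[-1])

    @property
    def n_classes(self) -> int:
        return len(self.ages)

    @property
    def N_x(self) -> np.ndarray:
        """Census size per age class, ``round(N1 * l_x)``."""
        return np.rint(self.N1 * self.l).astype(int)

    @property
    def N_A(self) -> int:
        """Number of adults of all ages alive at a census."""
        return int(self.N_x.sum())

    def stabilized(self, relative_b: np.ndarray | None = None) -> "VitalRates":
        """Return a copy with ``b`` rescaled so that ``sum(l_x b_x) = 2``."""
        rel = self.b if relative_b is None else np.asarray(relative_b, float)
        if rel is None:
            raise ValueError("no fecundity schedule to stabilize")
        b = stabilize_fecundity(self.l, rel)
        return VitalRates(
            ages=self.ages, l=self.l, N1=self.N1, b=b, phi=self.phi,
            plus_group=self.plus_group, v=self.v,
        )


@dataclass
class DeathStructure:
    """Distribution of ages-at-death for one cohort.

    ``D_q`` individuals die after reproducing at age ``q`` (before reaching
    ``q + 1``); the groups it defines are the ANOVA groups for lifetime
    reproductive success.
    """

    q: np.ndarray
    D_q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=int)
        self.D_q = np.asarray(self.D_q, dtype=int)
        if np.any(self.D_q < 0):
            raise ValueError("death counts D_q must be non-negative")

    @property
    def total(self) -> int:
        return int(self.D_q.sum())

    @property
    def qbar(self) -> float:
        """Mean age at death, ``sum(q * D_q) / sum(D_q)``."""
        return float((self.q * self.D_q).sum() / self.D_q.sum())

    @property
    def adult_years(self) -> int:
        """Total adult-years lived by the cohort, ``sum(q * D_q) = sum(N_x)``."""
        return int((self.q * self.D_q).sum())


def stabilize_fecundity(l: np.ndarray, relative_b: np.ndarray) -> np.ndarray:
    """Scale a relative fecundity schedule so that ``sum(l_x b_x) = 2``.

    A single multiplicative constant is applied, so the *shape* of the
    schedule (constant, increasing, decreasing with age) is preserved while
    the level is pinned to the stable-population replacement expectation.
    """
    l = np.asarray(l, dtype=float)
    rel = np.asarray(relative_b, dtype=float)
    if l.shape != rel.shape:
        raise ValueError("l and relative_b must have the same length")
    if np.any(rel < 0):
        raise ValueError("relative fecundities must be non-negative")
    total = float((l * rel).sum())
    if total <= 0:
        raise ValueError("no reproduction: sum(l_x * relative_b_x) must be > 0")
    return rel * (2.0 / total)


def survivorship_from_survival(v: np.ndarray) -> np.ndarray:
    """Cumulative survivorship ``l_x`` from annual survival ``v_x``.

    ``l_1 = 1`` and ``l_{x+1} = l_x * v_x``; the returned vector has the same
    length as ``v`` and covers ages ``1 .. len(v)``.
    """
    v = np.asarray(v, dtype=float)
    l = np.empty_like(v)
    l[0] = 1.0
    l[1:] = np.cumprod(v[:-1])
    return l


def cohort_structure(vr: VitalRates) -> tuple[np.ndarray, DeathStructure | None]:
    """Census sizes ``N_x = round(N1 * l_x)`` and the implied death structure.

    The death counts are the successive differences ``D_q = N_q - N_{q+1}``
    (with everyone in the terminal class dying there), so ``sum(D_q)`` equals
    the census size at the first adult age by telescoping.  When a pooled
    plus-group makes the differences ill-defined (its census size can exceed
    the preceding single-age class), no death structure is returned.
    """
    N_x = vr.N_x
    D = np.empty_like(N_x)
    D[:-1] = N_x[:-1] - N_x[1:]
    D[-1] = N_x[-1]
    if np.any(D < 0):
        warnings.warn(
            "successive N_x differences are negative (pooled plus-group?); "
            "death structure is undefined for this life table",
            stacklevel=2,
        )
        return N_x, None
    return N_x, DeathStructure(q=vr.ages, D_q=D)


def death_structure(N_x: np.ndarray, ages: np.ndarray | None = None) -> DeathStructure:
    """Death structure from an observed census vector (first age = maturity)."""
    N_x = np.asarray(N_x, dtype=int)
    if ages is None:
        ages = np.arange(1, len(N_x) + 1)
    D = np.empty_like(N_x)
    D[:-1] = N_x[:-1] - N_x[1:]
    D[-1] = N_x[-1]
    if np.any(D < 0):
        raise ValueError("census sizes must be non-increasing to derive deaths")
    return DeathStructure(q=ages, D_q=D)


def estimate_Q_annual(l: np.ndarray, kbar_x: np.ndarray) -> float:
    """Sampling-intensity index for annual data, ``Q = sum(l_x * kbar_x) / 2``.

    ``Q`` compares the realized mean offspring numbers with the stable
    population expectation ``sum(l_x b_x) = 2``; ``Q = 1`` is comprehensive
    sampling, ``Q < 1`` sparse sampling, ``Q > 1`` supersampling (e.g. when
    offspring are counted at an earlier, more numerous life stage).  Carried
    at full precision; display rounding is left to reports.
    """
    l = np.asarray(l, dtype=float)
    kbar = np.asarray(kbar_x, dtype=float)
    if l.shape != kbar.shape:
        raise ValueError("l and kbar_x must have the same length")
    if not np.any(kbar > 0):
        raise ValueError("no offspring observed: cannot estimate Q")
    return float((l * kbar).sum() / 2.0)


def estimate_Q_lifetime(mean_lrs: float) -> float:
    """Sampling intensity for lifetime data: mean observed LRS over the stable
    expectation of 2 offspring per parent per lifetime."""
    if mean_lrs < 0:
        raise ValueError("mean LRS must be non-negative")
    return float(mean_lrs) / 2.0


def generation_length(vr: VitalRates) -> float:
    """Generation length ``T``: mean age of parents of newborns in the stable
    population, ``T = sum(x l_x b_x) / sum(l_x b_x)``.

    A pooled plus-group contributes at its nominal first age.
    """
    if vr.b is None:
        raise ValueError("vital rates must carry a stabilized fecundity schedule")
    w = vr.l * vr.b
    return float((vr.ages * w).sum() / w.sum())
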