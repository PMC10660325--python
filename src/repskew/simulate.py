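"""Age-structured birth-pulse Monte Carlo simulator.

A generalized Wright-Fisher scheme: each year a fixed number of offspring,
``round(Q * 2 N_1)``, is allocated among the living parents by a weighted
multinomial draw.  With equal weights the per-parent counts are effectively
Poisson (phi = 1); overdispersion is produced with per-individual gamma
weights.  A mean-1 gamma weight with variance ``c`` makes a parent's count
approximately Poisson-gamma with variance-to-mean ``1 + lambda c`` at mean
``lambda = Q b_x``, so setting

    c_x = (phi_x - 1) / b_x

yields a *rescaled* variance-to-mean ratio of exactly ``phi_x`` (raw ratio
``1 + Q (phi_x - 1)``), matching the Crow-Morton rescaling law.  Weight-based
overdispersion cannot generate phi < 1.

For lifetime cohorts, each member's yearly count is drawn as
Poisson(Q b_x w); with ``persistence=True`` an individual keeps its latent
weight rank for life (the same uniform is pushed through the age-specific
gamma quantile each year), creating positive temporal correlations in
reproductive success without changing group means.  Survival is an
independent Bernoulli(v_x) per individual-year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sp_stats

from .demography import (
    VitalRates,
    stabilize_fecundity,
    survivorship_from_survival,
)
from .scaling import GroupRawStats


__all__ = [
    "SimScenario",
    "fecundity_schedule",
    "simulate_annual",
    "simulate_lifetime",
    "subsample_offspring",
    "annual_counts_to_stats",
]


def fecundity_schedule(kind: str, n_ages: int) -> np.ndarray:
    """Relative fecundity shape: 'constant', 'increasing' or 'decreasing'."""
    if kind == "constant":
        return np.ones(n_ages)
    if kind == "increasing":
        return np.arange(1, n_ages + 1, dtype=float)
    if kind == "decreasing":
        return np.arange(n_ages, 0, -1, dtype=float)
    raise ValueError(f"unknown fecundity schedule {kind!r}")


@dataclass
class SimScenario:
    """One simulation configuration.

    Defaults mirror the reference hypothetical population used throughout for
    validation: 5 age classes, maturity at age 1, 50% annual survival with
    certain death after the last age, a stabilized fecundity schedule, and
    Poisson within-age variance (phi = 1).
    """

    N1: int = 500
    v: np.ndarray = field(default_factory=lambda: np.array([.5, .5, .5, .5, 0.]))
    relative_b: np.ndarray | str = "constant"
    phi: np.ndarray | float = 1.0
    Q: float = 1.0
    persistence: bool = False
    replicates: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        n = len(self.v)
        if isinstance(self.relative_b, str):
            self.relative_b = fecundity_schedule(self.relative_b, n)
        self.relative_b = np.asarray(self.relative_b, dtype=float)
        self.phi = np.broadcast_to(np.asarray(self.phi, dtype=float), (n,)).copy()
        if np.any(self.phi < 1):
            raise ValueError("phi targets must be >= 1 (weights cannot "
                             "generate underdispersion)")
        if self.Q <= 0:
            raise ValueError("sampling intensity Q must be positive")
        if self.N1 <= 0:
            raise ValueError("cohort size N1 must be positive")
        self.l = survivorship_from_survival(self.v)
        self.b = stabilize_fecundity(self.l, self.relative_b)
        self.ages = np.arange(1, n + 1)

    @property
    def n_ages(self) -> int:
        return len(self.v)

    @property
    def N_x(self) -> np.ndarray:
        return np.rint(self.N1 * self.l).astype(int)

    def vital_rates(self) -> VitalRates:
        return VitalRates(ages=self.ages, l=self.l, N1=self.N1,
                          b=self.b, phi=self.phi, v=self.v)

    @classmethod
    def from_config(cls, path) -> "SimScenario":
        """Load a scenario from a YAML key-value file."""
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(**cfg)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _gamma_weights(rng, b_x, phi_x, size):
    """Mean-1 gamma weights with variance (phi_x - 1) / b_x."""
    if phi_x <= 1:
        return np.ones(size)
    shape = b_x / (phi_x - 1.0)
    return rng.gamma(shape, 1.0 / shape, size=size)


def simulate_annual(scenario: SimScenario, seed=None):
    """Simulate annual offspring counts; one list of per-age arrays per rep.

    Each replicate represents one census year of the stable population: the
    standing age structure ``N_x = round(N1 l_x)`` receives a fixed total of
    ``round(Q * 2 N1)`` sampled offspring by weighted multinomial allocation.
    Returns a list of length ``scenario.replicates``.
    """
    rng = _rng(scenario.seed if seed is None else seed)
    N_x = scenario.N_x
    age_idx = np.repeat(np.arange(scenario.n_ages), N_x)
    b_i = scenario.b[age_idx]
    n_off = int(round(scenario.Q * 2 * scenario.N1))
    boundaries = np.cumsum(N_x)[:-1]

    out = []
    for _ in range(scenario.replicates):
        w = np.ones(len(age_idx))
        for j in range(scenario.n_ages):
            if scenario.phi[j] > 1 and N_x[j] > 0:
                sel = age_idx == j
                w[sel] = _gamma_weights(rng, scenario.b[j], scenario.phi[j],
                                        int(N_x[j]))
        p = w * b_i
        p /= p.sum()
        counts = rng.multinomial(n_off, p)
        out.append(np.split(counts, boundaries))
    return out


def annual_counts_to_stats(counts_by_age, ages=None) -> list[GroupRawStats]:
    """Per-age sufficient statistics from one replicate's count vectors."""
    stats = []
    for j, counts in enumerate(counts_by_age):
        counts = np.asarray(counts, dtype=float)
        label = j + 1 if ages is None else ages[j]
        s2 = float(counts.var(ddof=1)) if counts.size > 1 else 0.0
        stats.append(GroupRawStats(label=label, n=counts.size,
                                   kbar=float(counts.mean()), s2=s2))
    return stats


def simulate_lifetime(scenario: SimScenario, seed=None):
    """Simulate complete lifetimes for a cohort; one matrix per replicate.

    Each replicate follows ``N1`` individuals from maturity to death.  The
    returned DataFrames have one row per individual and columns ``age_1`` ..
    ``age_omega`` holding observed offspring counts, with NaN after death --
    the same dialect :func:`repskew.lifetime.lrs_from_matrix` consumes.
    Yearly counts are Poisson(Q b_x w) thinned to the sampling intensity;
    within a large stable population the cohort's draws are effectively
    independent of other cohorts, so no fixed yearly total is imposed here.
    """
    rng = _rng(scenario.seed if seed is None else seed)
    n_ages = scenario.n_ages
    cols = [f"age_{x}" for x in scenario.ages]

    out = []
    for _ in range(scenario.replicates):
        mat = np.full((scenario.N1, n_ages), np.nan)
        alive = np.ones(scenario.N1, dtype=bool)
        u = rng.uniform(size=scenario.N1) if scenario.persistence else None
        for x in range(n_ages):
            n_alive = int(alive.sum())
            if n_alive == 0:
                break
            if scenario.phi[x] > 1:
                shape = scenario.b[x] / (scenario.phi[x] - 1.0)
                if scenario.persistence:
                    w = sp_stats.gamma.ppf(u[alive], a=shape) / shape
                else:
                    w = rng.gamma(shape, 1.0 / shape, size=n_alive)
            else:
                w = np.ones(n_alive)
            lam = scenario.Q * scenario.b[x] * w
            mat[alive, x] = rng.poisson(lam)
            survived = rng.random(n_alive) < scenario.v[x]
            alive[np.flatnonzero(alive)[~survived]] = False
        out.append(pd.DataFrame(mat, columns=cols,
                                index=pd.RangeIndex(scenario.N1, name="id")))
    return out


def subsample_offspring(counts, Q: float, seed=None) -> np.ndarray:
    """Randomly thin offspring-to-parent assignments to intensity ``Q``.

    Draws ``round(Q * total)`` offspring without replacement from the pooled
    offspring (multivariate hypergeometric over parents), so the expected
    sampled total is ``Q * total`` and Poisson-shaped counts stay Poisson.
    ``Q >= 1`` returns the counts unchanged (no offspring can be invented).
    """
    counts = np.asarray(counts, dtype=int)
    if Q <= 0:
        raise ValueError("sampling intensity Q must be positive")
    if Q >= 1:
        return counts.copy()
    rng = _rng(seed)
    m = int(round(Q * counts.sum()))
    return rng.multivariate_hypergeometric(counts, m)
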