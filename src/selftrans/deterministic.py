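"""Closed-form, infinite-population machinery for the trioecy model.

Two distinct deterministic objects live here and they are *not* the same
recursion:

* :func:`male_maintenance_step` — the classical androdioecy male
  maintenance function m' = alpha*m / (2*alpha*m + B*(1 - alpha*m)),
  where B is the selfed brood weight 2*beta*(1 - delta).  With B = 2 it
  simplifies to m' = alpha*m/2, so a rare male lineage grows iff
  alpha > 2, matching :func:`androdioecy_maintenance_condition`.
* :func:`deterministic_trioecy_trajectory` — the exact infinite-N limit
  of the individual-based mating-pair algorithm (each XX individual
  mated with probability min(alpha*m, 1), uniform pair weights),
  iterated over the full (sex, genotype) class frequencies.  For a
  purely androdioecious population (all XX are hermaphrodites, B = 2)
  the recursion's male frequency reduces exactly to the maintenance
  function; in trioecy the two differ because unmated females leave no
  brood.  Both are exposed deliberately.

The symbol printed alongside the maintenance function in its source is a
bare "beta" where the maintenance condition uses 2*beta*(1 - delta); the
implementation takes the selfed brood weight B as the single parameter,
since B = 2 simultaneously reproduces the alpha > 2 threshold, the
m' = alpha*m/2 simplification and the reported outcross-fitness of the
lab-adapted population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    MENDEL,
    N_CLASSES,
    SimulationParams,
    WT_ALLELES_PER_CLASS,
    largest_remainder_round,
)

__all__ = [
    "ClassFrequencies",
    "DeterministicTrajectory",
    "male_maintenance_step",
    "rare_male_growth_factor",
    "estimate_alpha_from_male_frequencies",
    "androdioecy_maintenance_condition",
    "class_frequencies_hwe",
    "deterministic_trioecy_trajectory",
]

_MASS_TOL = 1e-12


@dataclass
class ClassFrequencies:
    """Frequencies of the six (sex, genotype) classes; sums to 1."""

    freq: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES))

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (N_CLASSES,):
            raise ValueError(f"freq must have shape ({N_CLASSES},)")
        if (self.freq < -_MASS_TOL).any() or (self.freq > 1 + _MASS_TOL).any():
            raise ValueError("frequencies must lie in [0, 1]")
        if abs(self.freq.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies must sum to 1, got {self.freq.sum()}")

    @property
    def male_frequency(self) -> float:
        return float(self.freq[:3].sum())

    @property
    def hermaphrodite_frequency(self) -> float:
        return float(self.freq[3] + self.freq[4])

    @property
    def female_frequency(self) -> float:
        return float(self.freq[5])

    @property
    def wt_allele_frequency(self) -> float:
        return float(np.dot(self.freq, WT_ALLELES_PER_CLASS) / 2.0)


@dataclass
class DeterministicTrajectory:
    states: list[ClassFrequencies]
    extinct: bool = False
    extinct_generation: int | None = None

    def male_frequency(self) -> np.ndarray:
        return np.array([s.male_frequency for s in self.states])

    def female_frequency(self) -> np.ndarray:
        return np.array([s.female_frequency for s in self.states])

    def hermaphrodite_frequency(self) -> np.ndarray:
        return np.array([s.hermaphrodite_frequency for s in self.states])

    def wt_allele_frequency(self) -> np.ndarray:
        return np.array([s.wt_allele_frequency for s in self.states])


def male_maintenance_step(m: float, alpha: float, brood_weight: float = 2.0) -> float:
    """One generation of the androdioecy male maintenance function.

    m' = alpha*m / (2*alpha*m + B*(1 - alpha*m)) with selfed brood
    weight B; with B = 2 this is alpha*m/2.
    """
    m = float(m)
    if not 0.0 <= m <= 0.5:
        raise ValueError("male frequency must lie in [0, 0.5]")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if brood_weight <= 0:
        raise ValueError("brood_weight must be > 0")
    am = alpha * m
    if am > 1.0:
        raise ValueError(
            f"alpha*m = {am} > 1 lies outside the maintenance function's domain"
        )
    if m == 0.0:
        return 0.0
    return am / (2.0 * am + brood_weight * (1.0 - am))


def rare_male_growth_factor(alpha: float, brood_weight: float = 2.0, eps: float = 1e-9) -> float:
    """Per-generation growth factor of a rare male lineage, evaluated
    numerically as m'/m at m = eps.  Equals alpha/B in the limit, so the
    maintenance boundary is the alpha at which this factor is 1."""
    return male_maintenance_step(eps, alpha, brood_weight) / eps


def estimate_alpha_from_male_frequencies(
    m0: float, m1: float, brood_weight: float = 2.0
) -> float:
    """Outcross-fitness alpha from male frequencies one generation apart.

    Exact algebraic inverse of :func:`male_maintenance_step`:
    alpha = B*m1 / (m0 * (1 - 2*m1 + B*m1)); with B = 2, alpha = 2*m1/m0.
    """
    m0, m1 = float(m0), float(m1)
    if not 0.0 < m0 <= 0.5:
        raise ValueError("m0 must lie in (0, 0.5]")
    if not 0.0 <= m1 <= 0.5:
        raise ValueError("m1 must lie in [0, 0.5]")
    if brood_weight <= 0:
        raise ValueError("brood_weight must be > 0")
    denom = m0 * (1.0 - 2.0 * m1 + brood_weight * m1)
    if denom <= 0:
        raise ValueError("inconsistent male frequencies: non-positive denominator")
    return brood_weight * m1 / denom


def androdioecy_maintenance_condition(
    alpha: float, sigma: float = 0.0, beta: float = 1.0, delta: float = 0.0
) -> bool:
    """True iff males (hence outcrossing) are maintained under
    androdioecy: alpha*(1 - sigma) > 2*beta*(1 - delta), strictly."""
    return alpha * (1.0 - sigma) > 2.0 * beta * (1.0 - delta)


def class_frequencies_hwe(wt_allele_freq: float, male_freq: float) -> ClassFrequencies:
    """Class frequencies with genotypes at Hardy-Weinberg proportions of
    ``wt_allele_freq`` in males and XX alike, males at ``male_freq``."""
    p = float(wt_allele_freq)
    m = float(male_freq)
    if not 0.0 <= p <= 1.0 or not 0.0 <= m <= 1.0:
        raise ValueError("frequencies must lie in [0, 1]")
    hw = np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2])
    freq = np.concatenate([m * hw, (1 - m) * hw])
    return ClassFrequencies(freq)


def _deterministic_step(
    freq: np.ndarray, alpha: float, beta: float, sigma: float
) -> np.ndarray | None:
    """One infinite-population generation; None signals extinction."""
    m = freq[:3].sum()
    xx = freq[3:]
    xx_tot = xx.sum()

    # Each XX individual is mated with probability min(alpha*m, 1).
    mated = min(alpha * m, 1.0) * xx_tot if m > 0 else 0.0
    # Mated XX are a uniform sample of XX, so unmated class masses scale down.
    unmated_scale = 0.0 if xx_tot == 0 else (xx_tot - mated) / xx_tot
    selfers = beta * unmated_scale * (xx[0] + xx[1])

    total_broods = mated + selfers
    if total_broods <= 0:
        return None

    new = np.zeros(N_CLASSES)
    male_w = 0.5 * (1.0 - sigma)  # viability-weighted male share of outcross broods
    xx_w = 0.5
    if mated > 0:
        dam = xx / xx_tot
        sire = freq[:3] / m
        q_out = np.einsum("i,j,ijg->g", dam, sire, MENDEL)
        new[:3] += mated * male_w * q_out
        new[3] += mated * xx_w * q_out[0]
        new[4] += mated * xx_w * q_out[1]
        new[5] += mated * xx_w * q_out[2]
    if selfers > 0:
        h = xx[:2] / (xx[0] + xx[1])
        q_self = h[0] * MENDEL[0, 0] + h[1] * MENDEL[1, 1]
        new[3] += selfers * q_self[0]
        new[4] += selfers * q_self[1]
        new[5] += selfers * q_self[2]
    return new / new.sum()


def deterministic_trioecy_trajectory(
    initial: ClassFrequencies,
    params: SimulationParams,
    n_generations: int | None = None,
) -> DeterministicTrajectory:
    """Iterate the infinite-population limit of the mating-pair algorithm.

    Per generation: a fraction min(alpha*m, 1-m) of XX individuals is
    mated (dams a uniform sample of XX, sires drawn from the male
    genotype distribution), unmated hermaphrodites self with
    probability beta, unmated females do not reproduce, every brood has
    equal weight, half of the outcross offspring are male (weighted by
    male viability 1 - sigma) and selfed offspring are all XX.

    A generation with no reproducers terminates the trajectory with
    ``extinct=True`` at that generation.
    """
    if n_generations is None:
        n_generations = params.n_generations
    states = [initial]
    freq = initial.freq.copy()
    for gen in range(1, n_generations + 1):
        nxt = _deterministic_step(freq, params.alpha, params.beta, params.sigma)
        if nxt is None:
            return DeterministicTrajectory(states, extinct=True, extinct_generation=gen)
        freq = nxt
        states.append(ClassFrequencies(freq.copy()))
    return DeterministicTrajectory(states)
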