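"""Elementary genetics of a trioecious *C. elegans* population.

The species segregates three sexes at a single autosomal locus, *fog-2*:
XX individuals carrying at least one wild-type (selfing) allele are
self-compatible hermaphrodites, XX homozygotes for the recessive
*fog-2(q71)* knockout are functional females, and XO individuals are
males regardless of genotype.  Everything else in the package — the
individual-based simulator, the deterministic recursions, the fitness
estimators — builds on the small set of identities defined here:
Mendelian segregation, sex determination from genotype, allele-frequency
arithmetic, the binomial detection-power formula used for genotyping
sample sizes, and the boundary-frequency clamping convention that keeps
log-ratio statistics finite.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FogGenotype",
    "Karyotype",
    "Sex",
    "PopulationState",
    "SimulationParams",
    "CLASSES",
    "CLASS_INDEX",
    "N_CLASSES",
    "MENDEL",
    "sex_from_genotype",
    "mendelian_offspring_distribution",
    "expected_homozygote_frequency",
    "expected_carrier_frequency",
    "offspring_allele_frequency",
    "selfing_rate_from_male_frequency",
    "male_frequency_from_selfing_rate",
    "detection_power",
    "clamp_frequency",
]


class FogGenotype(enum.IntEnum):
    """Diploid genotype at the *fog-2* locus.

    ``WT_WT`` and ``WT_Q71`` XX individuals are hermaphrodites (the
    knockout is recessive); ``Q71_Q71`` XX individuals are females.
    """

    WT_WT = 0
    WT_Q71 = 1
    Q71_Q71 = 2

    @property
    def n_wt_alleles(self) -> int:
        return 2 - int(self)


class Karyotype(enum.Enum):
    XX = "XX"
    XO = "XO"


class Sex(enum.IntEnum):
    MALE = 0
    HERMAPHRODITE = 1
    FEMALE = 2


# Canonical class layout used by every counts/frequency vector in the
# package.  Only genotype-compatible (sex, genotype) pairs appear: males of
# any genotype, hermaphrodites carrying >= 1 wild-type allele, and
# q71-homozygous females.
CLASSES: tuple[tuple[Sex, FogGenotype], ...] = (
    (Sex.MALE, FogGenotype.WT_WT),
    (Sex.MALE, FogGenotype.WT_Q71),
    (Sex.MALE, FogGenotype.Q71_Q71),
    (Sex.HERMAPHRODITE, FogGenotype.WT_WT),
    (Sex.HERMAPHRODITE, FogGenotype.WT_Q71),
    (Sex.FEMALE, FogGenotype.Q71_Q71),
)
CLASS_INDEX = {cls: i for i, cls in enumerate(CLASSES)}
N_CLASSES = len(CLASSES)

# Number of wild-type alleles carried by each class.
WT_ALLELES_PER_CLASS = np.array([g.n_wt_alleles for _, g in CLASSES], dtype=float)

# Mendelian offspring-genotype table: MENDEL[g1, g2] is the probability
# vector over offspring genotypes from parents g1 x g2, each contributing
# one uniformly drawn allele.
def _mendel_table() -> np.ndarray:
    table = np.zeros((3, 3, 3))
    wt_prob = np.array([1.0, 0.5, 0.0])  # P(transmit wild-type) per genotype
    for g1 in range(3):
        for g2 in range(3):
            a, b = wt_prob[g1], wt_prob[g2]
            table[g1, g2, 0] = a * b
            table[g1, g2, 2] = (1 - a) * (1 - b)
            table[g1, g2, 1] = 1.0 - table[g1, g2, 0] - table[g1, g2, 2]
    return table


MENDEL = _mendel_table()
MENDEL.setflags(write=False)


def sex_from_genotype(karyotype: Karyotype, genotype: FogGenotype) -> Sex:
    """Sex of an individual given its karyotype and *fog-2* genotype.

    XO animals are male whatever their genotype.  XX animals are females
    when homozygous for the recessive *fog-2(q71)* knockout and
    self-compatible hermaphrodites otherwise.
    """
    if karyotype is Karyotype.XO:
        return Sex.MALE
    if genotype is FogGenotype.Q71_Q71:
        return Sex.FEMALE
    return Sex.HERMAPHRODITE


def mendelian_offspring_distribution(
    parent1: FogGenotype, parent2: FogGenotype
) -> dict[FogGenotype, float]:
    """Offspring genotype distribution from two parents (selfing when
    ``parent1 == parent2`` and the parent is a hermaphrodite)."""
    probs = MENDEL[int(parent1), int(parent2)]
    return {FogGenotype(g): float(probs[g]) for g in range(3)}


def _check_frequency(p: float, name: str = "frequency") -> float:
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {p}")
    return p


def expected_homozygote_frequency(p: float) -> float:
    """Expected frequency of wild-type homozygotes, p^2, under random
    union of gametes.

    This is the quantity used to translate a rare selfing-allele
    frequency into an expected hermaphrodite frequency at the start of
    the transition experiments (2.6e-2 -> 6.8e-4).  Note that because
    the knockout is recessive, *carriers* are hermaphrodites too; see
    :func:`expected_carrier_frequency` for 1 - (1-p)^2.
    """
    p = _check_frequency(p, "allele frequency")
    return p * p


def expected_carrier_frequency(p: float) -> float:
    """Frequency of individuals carrying >= 1 copy, 1 - (1-p)^2."""
    p = _check_frequency(p, "allele frequency")
    return 1.0 - (1.0 - p) ** 2


def offspring_allele_frequency(maternal_p: float, paternal_p: float) -> float:
    """Expected offspring allele frequency, the parental average."""
    maternal_p = _check_frequency(maternal_p, "maternal frequency")
    paternal_p = _check_frequency(paternal_p, "paternal frequency")
    return 0.5 * (maternal_p + paternal_p)


def selfing_rate_from_male_frequency(m: float) -> float:
    """Selfing rate S = 1 - 2m from the adult male proportion.

    Valid when broods are either fully selfed or fully outcrossed and
    outcrossing yields 50% male progeny, so every male implies one
    outcrossed XX sib.
    """
    m = _check_frequency(m, "male frequency")
    if m > 0.5:
        raise ValueError(
            f"male frequency {m} > 0.5 is incompatible with the 1 - 2m estimator"
        )
    return 1.0 - 2.0 * m


def male_frequency_from_selfing_rate(s: float) -> float:
    """Inverse of :func:`selfing_rate_from_male_frequency`: m = (1 - S)/2."""
    s = _check_frequency(s, "selfing rate")
    return (1.0 - s) / 2.0


def detection_power(p: float, n_individuals: float) -> float:
    """Probability of observing >= 1 copy of an allele at frequency ``p``
    among ``2 * n_individuals`` sampled alleles: 1 - (1-p)^(2n).

    ``n_individuals`` may be fractional (a mean genotyping sample size).
    """
    p = _check_frequency(p, "allele frequency")
    n_individuals = float(n_individuals)
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    return 1.0 - (1.0 - p) ** (2.0 * n_individuals)


def clamp_frequency(k: float, n: float) -> float:
    """Frequency k/n with boundary counts pulled strictly inside (0, 1).

    ``k == 0`` maps to 1/(n+1) and ``k == n`` to n/(n+1), generalising
    the 48-individual genotyping convention (0/96 -> 1/97, 96/96 ->
    96/97) to any number of sampled alleles, so downstream log-ratios
    stay finite.
    """
    n = float(n)
    k = float(k)
    if n < 1:
        raise ValueError("total allele count n must be >= 1")
    if k < 0 or k > n:
        raise ValueError(f"count k={k} outside [0, {n}]")
    if k == 0:
        return 1.0 / (n + 1.0)
    if k == n:
        return n / (n + 1.0)
    return k / n


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the trioecy model.

    alpha
        Outcross-fitness: compound of all fitness components expressed
        under outcrossing relative to selfing; sets the per-generation
        mating quota alpha * m * N.
    beta
        Probability that a non-cross-fertilised hermaphrodite selfs
        (brood-level; no mixed broods).  Default 1.
    sigma
        Male-vs-hermaphrodite survivorship deficit.  Default 0.
    delta
        Inbreeding depression applied to selfed broods where the model
        calls for it (the one-cycle competition simulation).  Default 0.
    census_size
        Constant population census N.
    n_generations
        Number of generations to iterate.
    seed
        Seed for all randomness of a run.
    """

    alpha: float
    census_size: int
    n_generations: int = 0
    beta: float = 1.0
    sigma: float = 0.0
    delta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if not 0.0 <= self.sigma < 1.0:
            raise ValueError("sigma must lie in [0, 1)")
        if not 0.0 <= self.delta < 1.0:
            raise ValueError("delta must lie in [0, 1)")
        if self.census_size < 1:
            raise ValueError("census_size must be >= 1")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")

    @property
    def brood_weight(self) -> float:
        """Selfed brood weight B = 2 * beta * (1 - delta); 2 at defaults."""
        return 2.0 * self.beta * (1.0 - self.delta)


@dataclass
class PopulationState:
    """Census counts by (sex, genotype) class at one generation."""

    generation: int
    counts: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES, dtype=np.int64))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CLASSES,):
            raise ValueError(f"counts must have shape ({N_CLASSES},)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.generation < 0:
            raise ValueError("generation must be >= 0")

    @classmethod
    def from_dict(cls, generation: int, counts: dict[tuple[Sex, FogGenotype], int]) -> "PopulationState":
        arr = np.zeros(N_CLASSES, dtype=np.int64)
        for key, value in counts.items():
            if key not in CLASS_INDEX:
                if value != 0:
                    raise ValueError(f"class {key} is genotype-incompatible and must be 0")
                continue
            arr[CLASS_INDEX[key]] = value
        return cls(generation=generation, counts=arr)

    def count(self, sex: Sex, genotype: FogGenotype) -> int:
        """Count of one class; genotype-incompatible classes are 0."""
        key = (sex, genotype)
        if key not in CLASS_INDEX:
            return 0
        return int(self.counts[CLASS_INDEX[key]])

    @property
    def size(self) -> int:
        return int(self.counts.sum())

    @property
    def n_males(self) -> int:
        return int(self.counts[:3].sum())

    @property
    def n_hermaphrodites(self) -> int:
        return int(self.counts[3] + self.counts[4])

    @property
    def n_females(self) -> int:
        return int(self.counts[5])

    @property
    def male_frequency(self) -> float:
        return self.n_males / self.size

    @property
    def female_frequency(self) -> float:
        return self.n_females / self.size

    @property
    def hermaphrodite_frequency(self) -> float:
        return self.n_hermaphrodites / self.size

    @property
    def n_wt_alleles(self) -> int:
        return int(np.dot(self.counts, WT_ALLELES_PER_CLASS))

    @property
    def wt_allele_frequency(self) -> float:
        return self.n_wt_alleles / (2 * self.size)


def largest_remainder_round(total: int, probs: np.ndarray) -> np.ndarray:
    """Apportion ``total`` among classes with probabilities ``probs`` by
    largest-remainder rounding (deterministic, sums exactly to total)."""
    probs = np.asarray(probs, dtype=float)
    if total < 0:
        raise ValueError("total must be >= 0")
    if probs.sum() <= 0:
        raise ValueError("probs must have positive mass")
    probs = probs / probs.sum()
    quota = probs * total
    counts = np.floor(quota).astype(np.int64)
    short = int(total - counts.sum())
    if short > 0:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:short]] += 1
    dropped = (probs > 0) & (counts == 0)
    if dropped.any() and total > 0:
        warnings.warn(
            "largest-remainder rounding left one or more classes with positive "
            "expected mass empty; the census is too small to represent them",
            stacklevel=2,
        )
    return counts
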