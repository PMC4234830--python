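"""Individual-based Monte Carlo engine for trioecious populations.

One generation of the mating-pair algorithm at census N:

1. Each female or hermaphrodite is collected into a mating pair with
   probability min(alpha*m, 1), where m is the realised male frequency:
   ``K = min(round(alpha*m*n_XX), n_XX)`` dams are drawn uniformly
   *without* replacement from females and hermaphrodites
   indiscriminately, and sires uniformly *with* replacement from the
   males.  (For an androdioecious population this reduces exactly to the
   male maintenance function m' = alpha*m/2.)
2. Unmated hermaphrodites become selfing pseudo-pairs with probability
   beta (1 by default); unmated females are discarded.
3. N offspring are produced by sampling pairs and pseudo-pairs uniformly
   with replacement.  Offspring genotypes follow Mendelian segregation;
   offspring of true pairs are male with probability 1/2 (weighted by
   male viability 1 - sigma), offspring of pseudo-pairs are always XX;
   XX sex follows from the genotype.

The same transition kernel is exposed in two forms: a single-population
step (:func:`advance_generation`) and a batched step over R replicate
populations (:func:`run_replicates`) in which all replicates share one
generator and every sampling call is vectorised across the batch — this
is what makes the grid-likelihood machinery affordable.  Batched
replicates are reproducible as a batch; isolated single trajectories get
their own spawned substream in :func:`run_trajectory`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    MENDEL,
    N_CLASSES,
    PopulationState,
    SimulationParams,
    WT_ALLELES_PER_CLASS,
    largest_remainder_round,
)

__all__ = [
    "ExtinctionError",
    "SimulationResult",
    "CompetitionCycleResult",
    "initialize_population",
    "advance_generation",
    "run_trajectory",
    "run_replicates",
    "simulate_competition_cycle",
]


class ExtinctionError(RuntimeError):
    """Raised when a population has no reproducers left."""


def initialize_population(
    census_size: int, wt_allele_freq: float, male_freq: float
) -> PopulationState:
    """Deterministic starting census.

    Males are ``round(male_freq * N)``; genotypes within males and
    within XX individuals are apportioned at Hardy-Weinberg proportions
    of ``wt_allele_freq`` by largest-remainder rounding (male genotype
    frequencies are assumed equal to those of hermaphrodites/females).
    XX sex follows from genotype.
    """
    n = int(census_size)
    if n < 1:
        raise ValueError("census_size must be >= 1")
    p = float(wt_allele_freq)
    m = float(male_freq)
    if not 0.0 <= p <= 1.0:
        raise ValueError("wt_allele_freq must lie in [0, 1]")
    if not 0.0 <= m <= 0.5:
        raise ValueError("male_freq must lie in [0, 0.5]")
    n_male = int(np.rint(m * n))
    hw = np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2])
    counts = np.zeros(N_CLASSES, dtype=np.int64)
    counts[:3] = largest_remainder_round(n_male, hw)
    counts[3:] = largest_remainder_round(n - n_male, hw)
    return PopulationState(generation=0, counts=counts)


def _advance_batch(
    counts: np.ndarray,
    alpha: float,
    beta: float,
    sigma: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One generation for a batch of replicate populations.

    Parameters
    ----------
    counts : int array (R, 6)
        Per-replicate class counts.  Rows with zero total are carried as
        already-extinct.
    Returns
    -------
    (new_counts, extinct) : (int array (R, 6), bool array (R,))
        ``extinct`` marks rows with no reproducers this generation
        (their new counts are all zero).
    """
    counts = np.asarray(counts, dtype=np.int64)
    R = counts.shape[0]
    n_tot = counts.sum(axis=1)
    alive = n_tot > 0
    n_male = counts[:, :3].sum(axis=1)
    xx = counts[:, 3:]
    n_xx = xx.sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(alive, n_male / np.maximum(n_tot, 1), 0.0)
    # Per-XX mating quota: each female/hermaphrodite is mated with
    # probability min(alpha*m, 1).
    quota = np.rint(np.minimum(alpha * m, 1.0) * n_xx).astype(np.int64)
    K = np.minimum(quota, n_xx)
    K = np.where(n_male > 0, K, 0)

    # Dams: multivariate hypergeometric over the three XX genotype classes,
    # realised as two nested (vectorised) hypergeometric draws.
    g0, g1, g2 = xx[:, 0], xx[:, 1], xx[:, 2]
    d0 = rng.hypergeometric(g0, g1 + g2, K)
    d1 = rng.hypergeometric(g1, g2, K - d0)
    # d2 (mated females) is implied: K - d0 - d1; females never self so it
    # only matters through the pair counts below.

    # Sires: with replacement from the male genotype distribution.
    safe_males = np.where(n_male[:, None] > 0, counts[:, :3], 1)
    pm = safe_males / safe_males.sum(axis=1, keepdims=True)
    dams = np.stack([d0, d1, K - d0 - d1], axis=1)
    # Pair counts by (dam genotype, sire genotype): sires are i.i.d., so the
    # sires of the dams of genotype i are multinomial(d_i, pm).
    pair_counts = np.empty((R, 3, 3), dtype=np.int64)
    for i in range(3):
        pair_counts[:, i, :] = rng.multinomial(dams[:, i], pm)

    # Selfing pseudo-pairs: unmated hermaphrodites, thinned by beta.
    u0 = g0 - d0
    u1 = g1 - d1
    if beta < 1.0:
        u0 = rng.binomial(u0, beta)
        u1 = rng.binomial(u1, beta)

    weights = np.concatenate(
        [pair_counts.reshape(R, 9), u0[:, None], u1[:, None]], axis=1
    ).astype(float)
    w_tot = weights.sum(axis=1)
    extinct = w_tot <= 0
    safe_w = np.where(extinct[:, None], np.eye(11)[0], weights / np.maximum(w_tot, 1)[:, None])
    n_offspring = np.where(extinct, 0, n_tot)
    per_class = rng.multinomial(n_offspring, safe_w)

    new = np.zeros((R, N_CLASSES), dtype=np.int64)
    # Offspring of true pairs: male with viability-weighted probability.
    p_male = 0.5 * (1.0 - sigma) / (0.5 * (1.0 - sigma) + 0.5)
    for c in range(9):
        i, j = divmod(c, 3)
        n_c = per_class[:, c]
        n_m = rng.binomial(n_c, p_male)
        new[:, :3] += rng.multinomial(n_m, MENDEL[i, j])
        new[:, 3:] += rng.multinomial(n_c - n_m, MENDEL[i, j])
    # Selfed offspring: all XX.
    new[:, 3:] += rng.multinomial(per_class[:, 9], MENDEL[0, 0])
    new[:, 3:] += rng.multinomial(per_class[:, 10], MENDEL[1, 1])
    new[extinct] = 0
    return new, extinct


def advance_generation(
    state: PopulationState, params: SimulationParams, rng: np.random.Generator
) -> PopulationState:
    """One generation of the mating-pair algorithm for one population.

    Raises :class:`ExtinctionError` when no mating pair or selfing
    hermaphrodite exists.
    """
    new, extinct = _advance_batch(
        state.counts[None, :], params.alpha, params.beta, params.sigma, rng
    )
    if extinct[0]:
        raise ExtinctionError(
            f"no reproducers at generation {state.generation} "
            f"(males={state.n_males}, hermaphrodites={state.n_hermaphrodites})"
        )
    return PopulationState(generation=state.generation + 1, counts=new[0])


@dataclass
class SimulationResult:
    """A single simulated trajectory."""

    states: list[PopulationState]
    params: SimulationParams
    rng_seed: int
    extinct: bool = False
    extinct_generation: int | None = None

    def wt_allele_frequency(self) -> np.ndarray:
        return np.array([s.wt_allele_frequency for s in self.states])

    def male_frequency(self) -> np.ndarray:
        return np.array([s.male_frequency for s in self.states])

    def female_frequency(self) -> np.ndarray:
        return np.array([s.female_frequency for s in self.states])

    def hermaphrodite_frequency(self) -> np.ndarray:
        return np.array([s.hermaphrodite_frequency for s in self.states])


def run_trajectory(
    params: SimulationParams, initial: PopulationState | None = None
) -> SimulationResult:
    """Simulate one trajectory of ``params.n_generations`` generations.

    Deterministic given ``params.seed`` (the run draws from its own
    spawned substream).  On extinction the trajectory is truncated and
    flagged rather than padded with empty states.
    """
    if initial is None:
        raise ValueError("an initial PopulationState is required")
    if initial.size != params.census_size:
        raise ValueError(
            f"initial census {initial.size} != params.census_size {params.census_size}"
        )
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(params.seed).spawn(1)[0]))
    states = [initial]
    state = initial
    for gen in range(1, params.n_generations + 1):
        try:
            state = advance_generation(state, params, rng)
        except ExtinctionError:
            warnings.warn(
                f"population extinct at generation {gen}; trajectory truncated",
                stacklevel=2,
            )
            return SimulationResult(
                states, params, params.seed, extinct=True, extinct_generation=gen
            )
        states.append(state)
    return SimulationResult(states, params, params.seed)


def run_replicates(
    params: SimulationParams,
    initial: PopulationState,
    n_reps: int,
    n_generations: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n_reps`` replicate trajectories with batched sampling.

    Returns ``(history, extinct_at)`` where ``history`` is an int array
    of shape (n_reps, n_generations + 1, 6) of class counts (extinct
    replicates stay all-zero from their extinction generation on) and
    ``extinct_at`` holds the extinction generation per replicate (-1 if
    none).
    """
    if n_generations is None:
        n_generations = params.n_generations
    if rng is None:
        rng = np.random.default_rng(params.seed)
    counts = np.tile(initial.counts, (n_reps, 1))
    history = np.zeros((n_reps, n_generations + 1, N_CLASSES), dtype=np.int64)
    history[:, 0] = counts
    extinct_at = np.full(n_reps, -1, dtype=np.int64)
    for gen in range(1, n_generations + 1):
        counts, extinct = _advance_batch(counts, params.alpha, params.beta, params.sigma, rng)
        newly = extinct & (extinct_at < 0)
        extinct_at[newly] = gen
        history[:, gen] = counts
    return history, extinct_at


def batch_wt_allele_frequency(history: np.ndarray) -> np.ndarray:
    """Wild-type allele frequency per (replicate, generation); NaN where
    the replicate is extinct."""
    n = history.sum(axis=2)
    wt = history.astype(float) @ WT_ALLELES_PER_CLASS
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(n > 0, wt / (2 * n), np.nan)


def batch_male_frequency(history: np.ndarray) -> np.ndarray:
    n = history.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(n > 0, history[:, :, :3].sum(axis=2) / n, np.nan)


def batch_female_frequency(history: np.ndarray) -> np.ndarray:
    n = history.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(n > 0, history[:, :, 5] / n, np.nan)


# ---------------------------------------------------------------------------
# One-cycle competition against a GFP-marked tester
# ---------------------------------------------------------------------------

@dataclass
class CompetitionCycleResult:
    """Outcome of a simulated one-generation competition.

    ``w`` is the mean log-ratio fitness over replicates in which both
    marker allele classes survived; replicates that lost a class are
    counted in ``n_wt_lost`` / ``n_gfp_lost``.  When *every* replicate
    lost the same class, ``w`` is signed infinity and ``degenerate`` is
    True — the caller gets a flag, not a silent +/-inf average.
    """

    w: float
    w_replicates: np.ndarray
    n_wt_lost: int
    n_gfp_lost: int
    degenerate: bool = False


def simulate_competition_cycle(
    alpha: float,
    delta: float = 0.0,
    setup_wt_alleles: int = 50,
    setup_gfp_alleles: int = 50,
    male_freqs: tuple[float, float] = (0.0, 0.05),
    census_size: int = 10_000,
    n_reps: int = 20,
    seed: int = 0,
    fog_wt_freqs: tuple[float, float] = (1.0, 1.0),
    alpha_gfp: float | None = None,
) -> CompetitionCycleResult:
    """One life cycle of competition between a focal population and a
    GFP-marked tester sharing a single mating pool.

    The GFP transgene is carried as a fully linked, neutral, codominant
    second locus fixed within each competitor origin (focal individuals
    are marker-homozygous non-GFP, tester individuals marker-homozygous
    GFP), so after one generation of random mating and selfing the
    offspring marker-allele frequencies are exact book-keeping over the
    mating classes.  Inbreeding depression ``delta`` down-weights the
    selfing pseudo-pairs of GFP hermaphrodites.  Fitness per replicate:

        w = ln(p_wt,t1 / p_gfp,t1) - ln(p_wt,t0 / p_gfp,t0)

    ``male_freqs`` and ``fog_wt_freqs`` give each origin's male
    frequency and *fog-2* wild-type allele frequency (the tester and
    monoecious/androdioecious focal populations are fixed wild-type at
    *fog-2*).  ``alpha_gfp`` is accepted for signature symmetry; the
    mating quota uses the single pool-level ``alpha`` (pairs form
    indiscriminately), so it must equal ``alpha`` when given.
    """
    if setup_wt_alleles <= 0 or setup_gfp_alleles <= 0:
        raise ValueError("setup allele counts must be > 0")
    if alpha_gfp is not None and alpha_gfp != alpha:
        raise ValueError("a single mating pool has one alpha; alpha_gfp must match")
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    n = int(census_size)
    frac_wt = setup_wt_alleles / (setup_wt_alleles + setup_gfp_alleles)
    n_by_origin = largest_remainder_round(n, np.array([frac_wt, 1 - frac_wt]))

    # Parent classes: origin (0 = wt, 1 = gfp) x the six (sex, genotype)
    # classes.  All parents are marker-homozygous for their origin.
    parents = np.zeros((2, N_CLASSES), dtype=np.int64)
    for o in range(2):
        parents[o] = initialize_population(
            max(int(n_by_origin[o]), 1), fog_wt_freqs[o], male_freqs[o]
        ).counts
    n = int(parents.sum())

    flat = parents.reshape(-1)  # 12 classes: origin-major
    male_idx = np.array([0, 1, 2, 6, 7, 8])
    xx_idx = np.array([3, 4, 5, 9, 10, 11])
    p0_wt = setup_wt_alleles / (setup_wt_alleles + setup_gfp_alleles)
    lr0 = np.log(p0_wt / (1 - p0_wt))

    w_vals = np.full(n_reps, np.nan)
    n_wt_lost = 0
    n_gfp_lost = 0
    for rep in range(n_reps):
        males = flat[male_idx]
        xxs = flat[xx_idx]
        n_male = males.sum()
        n_xx = xxs.sum()
        m = n_male / n
        K = int(min(np.rint(min(alpha * m, 1.0) * n_xx), n_xx)) if n_male > 0 else 0
        dams = rng.multivariate_hypergeometric(xxs, K)
        pair = np.zeros((6, 6), dtype=np.int64)
        if K > 0:
            pmale = males / n_male
            for i in range(6):
                pair[i] = rng.multinomial(dams[i], pmale)
        unmated = xxs - dams
        # Selfing pseudo-pairs: hermaphrodite classes only (fog WT_WT and
        # WT_Q71 within each origin); GFP hermaphrodites weighted by 1-delta.
        self_w = np.array(
            [unmated[0], unmated[1], (1 - delta) * unmated[3], (1 - delta) * unmated[4]],
            dtype=float,
        )
        weights = np.concatenate([pair.reshape(-1).astype(float), self_w])
        tot = weights.sum()
        if tot <= 0:
            raise ExtinctionError("no reproducers in the competition cycle")
        n_off = rng.multinomial(n, weights / tot)

        # GFP alleles carried by the offspring of each class: outcross pair
        # (dam class i, sire class j) yields 2 GFP alleles per offspring if
        # both parents are GFP-origin, 1 if exactly one is, 0 otherwise;
        # selfed offspring carry their parent's marker dose.
        origin_xx = np.array([0, 0, 0, 1, 1, 1])
        origin_male = np.array([0, 0, 0, 1, 1, 1])
        dose = origin_xx[:, None] + origin_male[None, :]
        gfp_alleles = float(
            (n_off[:36].reshape(6, 6) * dose).sum()
            + 2 * (n_off[38] + n_off[39])  # selfed GFP-origin hermaphrodites
        )
        p_gfp = gfp_alleles / (2 * n)
        if p_gfp <= 0.0:
            n_gfp_lost += 1
            continue
        if p_gfp >= 1.0:
            n_wt_lost += 1
            continue
        w_vals[rep] = np.log((1 - p_gfp) / p_gfp) - lr0

    valid = ~np.isnan(w_vals)
    if not valid.any():
        sign = np.inf if n_gfp_lost >= n_wt_lost else -np.inf
        return CompetitionCycleResult(
            w=sign,
            w_replicates=w_vals,
            n_wt_lost=n_wt_lost,
            n_gfp_lost=n_gfp_lost,
            degenerate=True,
        )
    return CompetitionCycleResult(
        w=float(w_vals[valid].mean()),
        w_replicates=w_vals,
        n_wt_lost=n_wt_lost,
        n_gfp_lost=n_gfp_lost,
    )
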