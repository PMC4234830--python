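"""Synthetic datasets with known ground truth for every pipeline stage.

Each generator emulates the structure of one of the study's five data
tables — *fog-2* genotype counts over time, male-count assays,
GFP-competition counts with block structure, male-fitness mating-plate
counts and SNP genotype matrices — at the assay's own sampling depths
(48 genotyped individuals per time point, 12 blocks of 4-6 competition
replicates scored at roughly 330 GFP / 902 wild-type larvae, ~17
females per mating plate, 58 SNPs on one chromosome).  Every generator
is deterministic under its seed and returns the generating truth
alongside the table, so recovery tests read the truth from the output
rather than re-deriving it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .core import SimulationParams
from .diversity import SNPGenotypeMatrix, equilibrium_inbreeding
from .fitness import CompetitionRecord, MaleFitnessRecord
from .infer import TrajectoryObservation
from .simulate import (
    batch_male_frequency,
    batch_wt_allele_frequency,
    initialize_population,
    run_replicates,
)

__all__ = [
    "SyntheticTruth",
    "gen_trajectory_dataset",
    "gen_competition_dataset",
    "gen_snp_dataset",
    "gen_male_fitness_dataset",
]


@dataclass
class SyntheticTruth:
    """Ground truth attached to every generated table."""

    seed: int
    true_alpha: float | None = None
    true_s: float | None = None
    true_w: float | None = None
    true_w_m: float | None = None
    selfing_rate: float | None = None
    snp_inbreeding_F: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


def gen_trajectory_dataset(
    true_alpha: float,
    n_populations: int = 3,
    sample_generations: tuple[int, ...] = (5, 15, 25, 35),
    n_genotyped: int = 48,
    census_size: int = 10_000,
    initial_wt_freq: float = 0.026,
    initial_male_freq: float = 0.45,
    n_sexed: int = 300,
    seed: int = 0,
) -> tuple[list[TrajectoryObservation], SyntheticTruth]:
    """Simulated *fog-2* genotyping tables from replicate populations.

    Each replicate population is one simulator trajectory from the
    trioecious starting conditions; at every sampled generation
    ``n_genotyped`` individuals are drawn binomially against the
    population genotype frequencies (wild-type allele count out of
    ``2 * n_genotyped``) and ``n_sexed`` individuals are sexed for the
    male-frequency column.
    """
    rng = np.random.default_rng(seed)
    params = SimulationParams(
        alpha=true_alpha,
        census_size=census_size,
        n_generations=max(sample_generations),
        seed=seed,
    )
    initial = initialize_population(census_size, initial_wt_freq, initial_male_freq)
    history, extinct_at = run_replicates(params, initial, n_populations, rng=rng)
    if (extinct_at >= 0).any():
        raise RuntimeError("a synthetic replicate went extinct; enlarge the census")
    p = batch_wt_allele_frequency(history)
    m = batch_male_frequency(history)
    observations: list[TrajectoryObservation] = []
    for rep in range(n_populations):
        for gen in sample_generations:
            k = int(rng.binomial(2 * n_genotyped, p[rep, gen]))
            n_males = int(rng.binomial(n_sexed, m[rep, gen]))
            observations.append(
                TrajectoryObservation(
                    population_id=f"P{rep + 1}",
                    generation=int(gen),
                    n_individuals=n_genotyped,
                    n_wt_alleles=k,
                    male_freq=min(n_males / n_sexed, 0.5),
                )
            )
    return observations, SyntheticTruth(seed=seed, true_alpha=true_alpha)


def _phenotype_fractions(
    p_gfp: float, m_wt: float, m_gfp: float
) -> tuple[float, float, float]:
    """(non-GFP, heterozygote, GFP-homozygote) progeny fractions from
    competitor allele frequencies under the heterozygote-aware
    mating-class model (the forward counterpart of the assay's
    correction)."""
    a_gfp, a_wt = p_gfp, 1.0 - p_gfp
    o_wt = min(2.0 * m_wt, 1.0)
    o_gfp = min(2.0 * m_gfp, 1.0)
    supply = a_wt * m_wt + a_gfp * m_gfp
    s_gfp = a_gfp * m_gfp / supply if supply > 0 else 0.0
    s_wt = 1.0 - s_gfp
    ww = a_wt * ((1.0 - o_wt) + o_wt * s_wt)
    het = a_wt * o_wt * s_gfp + a_gfp * o_gfp * s_wt
    gg = a_gfp * ((1.0 - o_gfp) + o_gfp * s_gfp)
    return ww, het, gg


def gen_competition_dataset(
    true_w: float,
    n_blocks: int = 12,
    reps_per_block: tuple[int, int] = (4, 6),
    mean_scored: int = 1232,
    male_freqs: tuple[float, float] = (0.0, 0.05),
    block_sd: float = 0.25,
    reference_label: str = "ANC",
    population_id: str = "EXP",
    seed: int = 0,
) -> tuple[list[CompetitionRecord], SyntheticTruth]:
    """Competition tables with block structure and a known fitness.

    Every block holds 4-6 replicates of the focal population at
    log-ratio fitness ``true_w`` plus the block's shared shift, and the
    same number of reference-population replicates at fitness equal to
    the block shift alone — so block centring recovers ``true_w`` while
    raw w is confounded by the shifts.  Setup is a 50:50 allele mix;
    final counts are multinomial over (non-GFP, heterozygote, GFP
    homozygote) phenotype classes at the allele frequencies implied by
    each record's fitness, with total scored larvae Poisson around the
    assay's printed scoring depth (~330 GFP / 902 wild type).
    """
    rng = np.random.default_rng(seed)
    records: list[CompetitionRecord] = []
    m_wt, m_gfp = male_freqs
    for b in range(n_blocks):
        shift = rng.normal(0.0, block_sd)
        n_reps = int(rng.integers(reps_per_block[0], reps_per_block[1] + 1))
        for pop, w_pop in ((population_id, true_w + shift), (reference_label, shift)):
            for _ in range(n_reps):
                p1_wt = 1.0 / (1.0 + math.exp(-w_pop))  # logit(p0)=0 at 50:50
                ww, het, gg = _phenotype_fractions(1.0 - p1_wt, m_wt, m_gfp)
                total = max(int(rng.poisson(mean_scored)), 1)
                neg, pos_het, pos_hom = rng.multinomial(total, [ww, het, gg])
                records.append(
                    CompetitionRecord(
                        block=f"B{b + 1}",
                        population_id=pop,
                        setup_wt_count=50,
                        setup_gfp_count=50,
                        final_gfp_pos=int(pos_het + pos_hom),
                        final_gfp_neg=int(neg),
                        male_freq_wt=m_wt,
                        male_freq_gfp=m_gfp,
                    )
                )
    return records, SyntheticTruth(seed=seed, true_w=true_w)


def gen_snp_dataset(
    n_individuals: int = 48,
    n_loci: int = 58,
    selfing_rate: float = 0.5,
    n_blocks: int = 6,
    within_block_corr: float = 0.6,
    missing_rate: float = 0.05,
    population: str = "POP",
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
) -> tuple[SNPGenotypeMatrix, SyntheticTruth]:
    """SNP genotype matrix under partial selfing with block LD.

    Haplotypes are built per contiguous locus block: each haplotype
    copies a block-level latent allele with some probability and draws
    independently otherwise, giving gametic correlation within blocks
    and none between.  Selfing enters twice.  Individuals are autozygous
    (both haplotypes identical by descent) with probability F = S/(2-S),
    Wright's equilibrium inbreeding for selfing rate S, producing the
    selfing-typical excess homozygosity.  And because sustained selfing
    suppresses effective recombination, haplotype blocks are transmitted
    more coherently: the within-block copying probability is raised from
    its outcrossed baseline ``within_block_corr`` to
    1 - (1 - within_block_corr) * (1 - F), so composite r^2 rises with
    the selfing rate (autozygosity alone cancels out of Burrows' r).
    Missing calls are injected uniformly at ``missing_rate``.
    """
    rng = np.random.default_rng(seed)
    F = equilibrium_inbreeding(selfing_rate)
    corr = 1.0 - (1.0 - within_block_corr) * (1.0 - F)
    freqs = rng.uniform(*maf_range, size=n_loci)
    block_of = np.repeat(np.arange(n_blocks), math.ceil(n_loci / n_blocks))[:n_loci]

    def draw_haplotype() -> np.ndarray:
        hap = np.empty(n_loci)
        for b in range(n_blocks):
            idx = block_of == b
            latent = rng.random() < freqs[idx].mean()
            copy = rng.random(idx.sum()) < corr
            indep = rng.random(idx.sum()) < freqs[idx]
            hap[idx] = np.where(copy, latent, indep)
        return hap

    genos = np.empty((n_individuals, n_loci))
    for i in range(n_individuals):
        h1 = draw_haplotype()
        if rng.random() < F:
            h2 = h1
        else:
            h2 = draw_haplotype()
        genos[i] = h1 + h2
    genos[rng.random(genos.shape) < missing_rate] = np.nan
    matrix = SNPGenotypeMatrix(
        genotypes=genos,
        populations=np.full(n_individuals, population),
        loci=[f"IV:{100_000 * (i + 1)}" for i in range(n_loci)],
    )
    truth = SyntheticTruth(
        seed=seed, selfing_rate=selfing_rate, snp_inbreeding_F=F
    )
    return matrix, truth


def gen_male_fitness_dataset(
    true_w_m: float,
    n_plates: int = 20,
    mean_females: float = 16.9,
    sd_females: float = 4.2,
    progeny_per_female: float = 6.0,
    qc_violation_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[MaleFitnessRecord], SyntheticTruth]:
    """Male-fitness mating-plate tables with known w_m.

    Progeny sired by wild-type males are binomial with success
    probability logit^-1(true_w_m); plate sizes follow the assay's
    printed female-transfer distribution.  A ``qc_violation_rate``
    fraction of extra plates violates each QC rule (too few females /
    too few progeny) to exercise the filters.
    """
    rng = np.random.default_rng(seed)
    p_wt = 1.0 / (1.0 + math.exp(-true_w_m))
    records: list[MaleFitnessRecord] = []
    for i in range(n_plates):
        females = max(int(round(rng.normal(mean_females, sd_females))), 6)
        total = max(int(rng.poisson(progeny_per_female * females)), 20)
        wt_sired = int(rng.binomial(total, p_wt))
        records.append(
            MaleFitnessRecord(
                plate=f"plate{i + 1}",
                females_transferred=females,
                progeny_gfp_pos=total - wt_sired,
                progeny_gfp_neg=wt_sired,
            )
        )
    n_bad = int(round(qc_violation_rate * n_plates))
    for i in range(n_bad):
        records.append(
            MaleFitnessRecord(
                plate=f"badF{i + 1}",
                females_transferred=int(rng.integers(1, 6)),
                progeny_gfp_pos=50,
                progeny_gfp_neg=50,
            )
        )
        total = int(rng.integers(1, 20))
        wt_sired = int(rng.binomial(total, p_wt))
        records.append(
            MaleFitnessRecord(
                plate=f"badP{i + 1}",
                females_transferred=10,
                progeny_gfp_pos=total - wt_sired,
                progeny_gfp_neg=wt_sired,
            )
        )
    return records, SyntheticTruth(seed=seed, true_w_m=true_w_m)
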