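"""Fitness estimators for the transition-to-selfing assays.

Four related haploid log-ratio fitness coefficients:

* transition fitness ``s`` — OLS slope of ln(p_wt/p_q71) on generation
  during an invasion of the selfing allele;
* competitive fitness ``w`` = ln(p_wt,t1/p_GFP,t1) - ln(p_wt,t0/p_GFP,t0)
  against a GFP tester over one life cycle, after correcting scored GFP
  phenotype counts for unseen heterozygosity;
* block-centred ``w_t`` (ancestral-reference mean subtracted per assay
  block) and ancestor-subtracted ``Delta w_t``;
* male fitness ``w_m`` = logit of the wild-type-sired progeny share in
  male-male competition plates (setup frequency fixed at 0.5).

GFP scoring is presence/absence (the transgene is dominant), so the
scored "GFP-positive" larvae mix marker homozygotes and heterozygotes.
:func:`gfp_phenotype_to_allele_counts` reconstructs expected allele
counts under random mating and selfing with no sex-ratio distortion:
each competitor outcrosses a fraction o_i = 2*m_i of its progeny (the
selfing-rate identity), sires are apportioned by male supply, cross-
competitor progeny are heterozygous, and the competitor adult
frequencies are estimated from the final counts by fixed-point
iteration.  The equations are a reconstruction pinned by an enumeration
oracle in the tests; only the inputs and assumptions of the original
algorithm are on record.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import clamp_frequency

__all__ = [
    "CompetitionRecord",
    "FitnessEstimate",
    "MaleFitnessRecord",
    "FertilityObservation",
    "transition_fitness",
    "gfp_phenotype_to_allele_counts",
    "competition_fitness",
    "block_center_and_delta",
    "male_fitness",
    "qc_filter_male_plates",
    "qc_filter_fertility",
    "flag_setup_deviation",
]


@dataclass(frozen=True)
class CompetitionRecord:
    """One replicate competition against the GFP tester."""

    block: str
    population_id: str
    setup_wt_count: float
    setup_gfp_count: float
    final_gfp_pos: float
    final_gfp_neg: float
    male_freq_wt: float
    male_freq_gfp: float

    def __post_init__(self) -> None:
        for name in ("setup_wt_count", "setup_gfp_count", "final_gfp_pos", "final_gfp_neg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.final_gfp_pos + self.final_gfp_neg <= 0:
            raise ValueError("a usable record needs at least one final count > 0")
        for name in ("male_freq_wt", "male_freq_gfp"):
            if not 0.0 <= getattr(self, name) <= 0.5:
                raise ValueError(f"{name} must lie in [0, 0.5]")


@dataclass
class FitnessEstimate:
    block: str
    population_id: str
    w: float
    w_t: float | None = None
    delta_w_t: float | None = None


@dataclass(frozen=True)
class MaleFitnessRecord:
    """One mating plate of the male-fitness competition assay."""

    plate: str
    females_transferred: int
    progeny_gfp_pos: int
    progeny_gfp_neg: int

    def __post_init__(self) -> None:
        if self.females_transferred < 0:
            raise ValueError("females_transferred must be >= 0")
        if self.progeny_gfp_pos < 0 or self.progeny_gfp_neg < 0:
            raise ValueError("progeny counts must be >= 0")

    @property
    def total_progeny(self) -> int:
        return self.progeny_gfp_pos + self.progeny_gfp_neg


@dataclass(frozen=True)
class FertilityObservation:
    """One fertility observation (selfed or outcrossed treatment)."""

    progeny: int
    outcrossed: bool
    male_progeny: int | None = None


def transition_fitness(
    series: list[list[tuple[int, int, int]]] | list[tuple[int, int, int]],
) -> tuple[float, float]:
    """Transition fitness s and its standard error.

    ``series`` is a list of replicate-population series, each a sequence
    of ``(generation, n_wt_alleles, n_total_alleles)``; a single flat
    series is also accepted.  Frequencies are clamped at the boundaries
    (0 -> 1/(n+1), n -> n/(n+1)), the response is the log allele ratio
    y = ln(p/(1-p)), and s is the pooled OLS slope of y on generation
    (one shared slope and intercept across replicate series).
    """
    if series and isinstance(series[0], tuple):
        series = [series]  # type: ignore[list-item]
    rows = [(g, k, n) for ser in series for (g, k, n) in ser]
    if len(rows) < 2:
        raise ValueError("need >= 2 observations")
    gens = np.array([r[0] for r in rows], dtype=float)
    if np.unique(gens).size < 2:
        raise ValueError("need >= 2 distinct generations to estimate a slope")
    y = np.array([math.log(clamp_frequency(k, n) / (1 - clamp_frequency(k, n))) for _, k, n in rows])
    X = sm.add_constant(gens)
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.bse[1])


def gfp_phenotype_to_allele_counts(
    record: CompetitionRecord,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> tuple[float, float]:
    """Expected (wild-type, GFP) allele counts from scored phenotypes.

    Model: with competitor adult frequencies (a_wt, a_gfp) and male
    frequencies (m_wt, m_gfp), each competitor outcrosses o_i = 2*m_i of
    its progeny and selfs the rest; among outcross events the sire is of
    competitor j with probability proportional to a_j * m_j; progeny of
    mixed pairs are marker heterozygotes, all other progeny are marker
    homozygotes of their origin.  The heterozygote share theta among
    GFP-positive larvae gives

        wt alleles  = 2 * final_gfp_neg + theta * final_gfp_pos
        GFP alleles = (2 - theta) * final_gfp_pos

    The adult frequencies are unknown; they are initialised from the
    final phenotype frequencies and the implied GFP allele frequency is
    iterated to a fixed point (parents are marker-homozygous per origin,
    so origin frequency and allele frequency coincide).  Total allele
    mass is exactly 2 * (final_gfp_pos + final_gfp_neg).
    """
    P = float(record.final_gfp_pos)
    Q = float(record.final_gfp_neg)
    o_wt = min(2.0 * record.male_freq_wt, 1.0)
    o_gfp = min(2.0 * record.male_freq_gfp, 1.0)

    def theta_of(a_gfp: float) -> float:
        a_wt = 1.0 - a_gfp
        supply = a_wt * record.male_freq_wt + a_gfp * record.male_freq_gfp
        if supply <= 0:  # no males anywhere: pure selfing, no heterozygotes
            return 0.0
        s_gfp = a_gfp * record.male_freq_gfp / supply
        s_wt = 1.0 - s_gfp
        het = a_wt * o_wt * s_gfp + a_gfp * o_gfp * s_wt
        gg = a_gfp * ((1.0 - o_gfp) + o_gfp * s_gfp)
        if het + gg <= 0:
            return 0.0
        return het / (het + gg)

    a = P / (P + Q)
    for _ in range(max_iter):
        theta = theta_of(a)
        a_new = (2.0 - theta) * P / (2.0 * (P + Q))
        if abs(a_new - a) < tol:
            wt = 2.0 * Q + theta * P
            return wt, 2.0 * (P + Q) - wt
        a = a_new
    raise RuntimeError(
        f"heterozygote correction did not converge in {max_iter} iterations "
        f"(last a_gfp={a:.6g}, record {record.block}/{record.population_id})"
    )


def competition_fitness(record: CompetitionRecord) -> FitnessEstimate:
    """One-cycle competitive fitness w of a record.

    w = ln(p_wt,t1/p_GFP,t1) - ln(p_wt,t0/p_GFP,t0), with t1 allele
    frequencies reconstructed by :func:`gfp_phenotype_to_allele_counts`
    and boundary counts clamped (with a warning) so w stays finite.
    """
    wt1, gfp1 = gfp_phenotype_to_allele_counts(record)
    n1 = wt1 + gfp1
    if wt1 == 0 or gfp1 == 0:
        warnings.warn(
            "one allele class absent after correction; boundary clamped",
            stacklevel=2,
        )
    p1 = clamp_frequency(wt1, n1)
    n0 = record.setup_wt_count + record.setup_gfp_count
    p0 = clamp_frequency(record.setup_wt_count, n0)
    w = math.log(p1 / (1 - p1)) - math.log(p0 / (1 - p0))
    return FitnessEstimate(block=record.block, population_id=record.population_id, w=w)


def block_center_and_delta(
    estimates: list[FitnessEstimate],
    reference_label: str,
    ancestor_means: dict[str, float] | None = None,
    system_of: dict[str, str] | None = None,
) -> list[FitnessEstimate]:
    """Block-centre fitness estimates and subtract ancestral means.

    ``w_t = w - mean(w of reference_label in the same block)``; blocks
    lacking a reference record are excluded with a warning.  When
    ``ancestor_means`` (keyed by reproduction system) and ``system_of``
    (population -> system) are given, ``delta_w_t = w_t - ancestor_mean``
    for non-reference populations.
    """
    df = pd.DataFrame(
        {
            "block": [e.block for e in estimates],
            "population_id": [e.population_id for e in estimates],
            "w": [e.w for e in estimates],
        }
    )
    ref_mean = (
        df[df.population_id == reference_label].groupby("block")["w"].mean()
    )
    out: list[FitnessEstimate] = []
    skipped: set[str] = set()
    for est in estimates:
        if est.block not in ref_mean.index:
            skipped.add(est.block)
            continue
        w_t = est.w - float(ref_mean[est.block])
        delta = None
        if (
            ancestor_means is not None
            and system_of is not None
            and est.population_id != reference_label
            and est.population_id in system_of
        ):
            system = system_of[est.population_id]
            if system in ancestor_means:
                delta = w_t - ancestor_means[system]
        out.append(replace(est, w_t=w_t, delta_w_t=delta))
    if skipped:
        warnings.warn(
            f"blocks without a {reference_label!r} reference excluded: "
            f"{sorted(skipped)}",
            stacklevel=2,
        )
    return out


def male_fitness(record: MaleFitnessRecord) -> float:
    """Male fitness w_m = logit(p_t1); setup p_t0 = 0.5 so logit(p_t0) = 0.

    Wild-type-sired progeny are GFP-negative (tester males are GFP
    homozygotes and the females carry no transgene).  Boundary counts
    are clamped with a warning.
    """
    n = record.total_progeny
    if n == 0:
        raise ValueError("no progeny scored")
    if record.progeny_gfp_neg in (0, n):
        warnings.warn("all progeny from one sire class; boundary clamped", stacklevel=2)
    p1 = clamp_frequency(record.progeny_gfp_neg, n)
    return math.log(p1 / (1 - p1))


def qc_filter_male_plates(
    records: list[MaleFitnessRecord],
    min_females: int = 6,
    min_progeny: int = 20,
) -> tuple[list[MaleFitnessRecord], dict[str, int]]:
    """Keep plates with >= 6 females transferred and >= 20 progeny scored."""
    kept: list[MaleFitnessRecord] = []
    tally = {"few_females": 0, "few_progeny": 0}
    for rec in records:
        if rec.females_transferred < min_females:
            tally["few_females"] += 1
        elif rec.total_progeny < min_progeny:
            tally["few_progeny"] += 1
        else:
            kept.append(rec)
    return kept, tally


def qc_filter_fertility(
    observations: list[FertilityObservation],
    min_progeny: int = 5,
    min_male_fraction: float = 0.10,
) -> tuple[list[FertilityObservation], dict[str, int]]:
    """Keep observations with >= 5 progeny and, in the outcrossed
    treatment, >= 10% male progeny."""
    kept: list[FertilityObservation] = []
    tally = {"few_progeny": 0, "few_males": 0}
    for obs in observations:
        if obs.progeny < min_progeny:
            tally["few_progeny"] += 1
            continue
        if obs.outcrossed:
            if obs.male_progeny is None:
                raise ValueError("outcrossed observations need a male progeny count")
            if obs.male_progeny / obs.progeny < min_male_fraction:
                tally["few_males"] += 1
                continue
        kept.append(obs)
    return kept, tally


def flag_setup_deviation(
    record: CompetitionRecord, band: float = 0.15
) -> bool:
    """True when the setup wild-type frequency deviates from the expected
    50:50 mix by more than ``band`` (exclusion is the caller's, opt-in,
    decision)."""
    total = record.setup_wt_count + record.setup_gfp_count
    if total <= 0:
        return True
    return abs(record.setup_wt_count / total - 0.5) > band
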