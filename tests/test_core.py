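"""Elementary genetics: sex determination, segregation, frequency
identities, detection power and boundary clamping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from selftrans.core import (
    CLASSES,
    FogGenotype,
    Karyotype,
    PopulationState,
    Sex,
    SimulationParams,
    clamp_frequency,
    detection_power,
    expected_carrier_frequency,
    expected_homozygote_frequency,
    largest_remainder_round,
    male_frequency_from_selfing_rate,
    mendelian_offspring_distribution,
    offspring_allele_frequency,
    selfing_rate_from_male_frequency,
    sex_from_genotype,
)

GENOTYPES = list(FogGenotype)
FREQS = st.floats(0.0, 1.0, allow_nan=False)


@pytest.mark.parametrize(
    "karyotype, genotype, expected",
    [
        (Karyotype.XX, FogGenotype.Q71_Q71, Sex.FEMALE),
        (Karyotype.XX, FogGenotype.WT_Q71, Sex.HERMAPHRODITE),
        (Karyotype.XX, FogGenotype.WT_WT, Sex.HERMAPHRODITE),
        (Karyotype.XO, FogGenotype.Q71_Q71, Sex.MALE),
        (Karyotype.XO, FogGenotype.WT_Q71, Sex.MALE),
        (Karyotype.XO, FogGenotype.WT_WT, Sex.MALE),
    ],
)
def test_sex_determination_partitions_all_combinations(karyotype, genotype, expected):
    assert sex_from_genotype(karyotype, genotype) is expected


@pytest.mark.parametrize(
    "p1, p2, expected",
    [
        (
            FogGenotype.WT_Q71,
            FogGenotype.WT_Q71,
            {FogGenotype.WT_WT: 0.25, FogGenotype.WT_Q71: 0.5, FogGenotype.Q71_Q71: 0.25},
        ),
        (FogGenotype.Q71_Q71, FogGenotype.Q71_Q71, {FogGenotype.Q71_Q71: 1.0}),
        (FogGenotype.WT_WT, FogGenotype.Q71_Q71, {FogGenotype.WT_Q71: 1.0}),
    ],
)
def test_mendelian_segregation_examples(p1, p2, expected):
    dist = mendelian_offspring_distribution(p1, p2)
    for g in FogGenotype:
        assert dist[g] == pytest.approx(expected.get(g, 0.0))


@given(st.sampled_from(GENOTYPES), st.sampled_from(GENOTYPES))
def test_mendelian_distribution_sums_to_one_and_is_symmetric(g1, g2):
    d12 = mendelian_offspring_distribution(g1, g2)
    d21 = mendelian_offspring_distribution(g2, g1)
    assert sum(d12.values()) == pytest.approx(1.0, abs=0)
    assert d12 == d21


def test_mendelian_distribution_conserves_allele_frequency():
    # offspring wt frequency = parental average, for every cross
    for g1 in FogGenotype:
        for g2 in FogGenotype:
            dist = mendelian_offspring_distribution(g1, g2)
            off = sum(p * g.n_wt_alleles / 2 for g, p in dist.items())
            assert off == pytest.approx((g1.n_wt_alleles + g2.n_wt_alleles) / 4)


def test_expected_homozygote_frequency_matches_introgression_arithmetic():
    # wild-type allele at 2.6e-2 implies homozygotes at 6.76e-4 (~6.8e-4)
    assert expected_homozygote_frequency(0.026) == pytest.approx(6.76e-4)
    assert expected_homozygote_frequency(0.0) == 0.0
    assert expected_homozygote_frequency(1.0) == 1.0
    with pytest.raises(ValueError):
        expected_homozygote_frequency(1.5)


def test_carrier_frequency_dominates_homozygote_frequency():
    assert expected_carrier_frequency(0.026) == pytest.approx(1 - 0.974**2)
    assert expected_carrier_frequency(0.026) > expected_homozygote_frequency(0.026)


def test_offspring_allele_frequency_is_parental_average():
    # q71/q71 mothers crossed to fathers at 5.2e-2 give F4 frequency 2.6e-2
    assert offspring_allele_frequency(0.0, 0.052) == pytest.approx(0.026)
    assert offspring_allele_frequency(0.5, 0.5) == 0.5
    assert offspring_allele_frequency(1.0, 0.0) == 0.5


def test_selfing_rate_identity_and_inverse():
    assert selfing_rate_from_male_frequency(0.0) == 1.0
    assert selfing_rate_from_male_frequency(0.5) == 0.0
    # inversion of the identity at the high-salt selfing rate 0.38
    assert male_frequency_from_selfing_rate(0.38) == pytest.approx(0.31)
    with pytest.raises(ValueError):
        selfing_rate_from_male_frequency(0.6)


@given(st.floats(0.0, 0.5, allow_nan=False))
def test_selfing_rate_round_trip(m):
    assert male_frequency_from_selfing_rate(selfing_rate_from_male_frequency(m)) == pytest.approx(m, abs=1e-12)


def test_detection_power_examples():
    assert detection_power(0.02, 42.7) == pytest.approx(0.822, abs=5e-4)
    assert detection_power(0.02, 48) == pytest.approx(0.856, abs=5e-4)
    assert detection_power(0.0, 48) == 0.0


@pytest.mark.parametrize("n", [1, 7, 48, 96])
def test_detection_power_equals_binomial_complement(n):
    for p in (0.005, 0.02, 0.2):
        brute = 1.0 - stats.binom.pmf(0, 2 * n, p)
        assert detection_power(p, n) == pytest.approx(brute, rel=1e-12)


@given(
    st.floats(1e-6, 0.999, allow_nan=False),
    st.floats(1e-6, 0.999, allow_nan=False),
    st.floats(1.0, 500.0, allow_nan=False),
    st.floats(1.0, 500.0, allow_nan=False),
)
def test_detection_power_monotone(p1, p2, n1, n2):
    lo_p, hi_p = sorted((p1, p2))
    lo_n, hi_n = sorted((n1, n2))
    assert detection_power(lo_p, lo_n) <= detection_power(hi_p, lo_n) + 1e-15
    assert detection_power(lo_p, lo_n) <= detection_power(lo_p, hi_n) + 1e-15


def test_clamp_frequency_boundary_convention():
    # 48 genotyped individuals: 0/96 -> 1/97, 96/96 -> 96/97
    assert clamp_frequency(0, 96) == pytest.approx(1 / 97)
    assert clamp_frequency(96, 96) == pytest.approx(96 / 97)
    assert clamp_frequency(48, 96) == 0.5
    with pytest.raises(ValueError):
        clamp_frequency(97, 96)


@given(st.integers(1, 10_000), st.integers(0, 10_000))
def test_clamp_frequency_strictly_interior(n, k):
    if k > n:
        k = n
    f = clamp_frequency(k, n)
    assert 0.0 < f < 1.0
    assert math.isfinite(math.log(f / (1 - f)))


def test_largest_remainder_round_is_exact():
    probs = np.array([0.5**2, 2 * 0.5 * 0.5, 0.5**2])
    counts = largest_remainder_round(800, probs)
    assert counts.tolist() == [200, 400, 200]
    assert largest_remainder_round(0, probs).sum() == 0


def test_population_state_counts_and_frequencies():
    state = PopulationState.from_dict(
        0,
        {
            (Sex.MALE, FogGenotype.Q71_Q71): 30,
            (Sex.HERMAPHRODITE, FogGenotype.WT_Q71): 20,
            (Sex.FEMALE, FogGenotype.Q71_Q71): 50,
        },
    )
    assert state.size == 100
    assert state.male_frequency == pytest.approx(0.3)
    assert state.count(Sex.FEMALE, FogGenotype.WT_WT) == 0  # structural zero
    assert state.n_wt_alleles == 20
    with pytest.raises(ValueError):
        PopulationState.from_dict(0, {(Sex.FEMALE, FogGenotype.WT_WT): 1})


def test_simulation_params_validation_and_brood_weight():
    params = SimulationParams(alpha=1.41, census_size=1000)
    assert params.brood_weight == 2.0  # B = 2*beta*(1-delta) at defaults
    assert SimulationParams(alpha=1, census_size=10, beta=0.5, delta=0.5).brood_weight == 0.5
    with pytest.raises(ValueError):
        SimulationParams(alpha=-0.1, census_size=10)
    with pytest.raises(ValueError):
        SimulationParams(alpha=1, census_size=0)
    with pytest.raises(ValueError):
        SimulationParams(alpha=1, census_size=10, sigma=1.0)


def test_class_layout_has_no_invalid_combinations():
    assert len(CLASSES) == 6
    for sex, genotype in CLASSES:
        if sex is Sex.FEMALE:
            assert genotype is FogGenotype.Q71_Q71
        if sex is Sex.HERMAPHRODITE:
            assert genotype is not FogGenotype.Q71_Q71
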