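"""Fitness estimators: transition fitness, GFP-corrected competitive
fitness, block centring, male fitness and the QC filters."""

import math

import numpy as np
import pytest
from scipy.special import expit, logit

from selftrans.fitness import (
    CompetitionRecord,
    FertilityObservation,
    FitnessEstimate,
    MaleFitnessRecord,
    block_center_and_delta,
    competition_fitness,
    flag_setup_deviation,
    gfp_phenotype_to_allele_counts,
    male_fitness,
    qc_filter_fertility,
    qc_filter_male_plates,
    transition_fitness,
)


def comp_record(final_pos, final_neg, m_wt=0.0, m_gfp=0.0, setup=(50, 50), **kw):
    return CompetitionRecord(
        block=kw.get("block", "B1"),
        population_id=kw.get("population_id", "EXP"),
        setup_wt_count=setup[0],
        setup_gfp_count=setup[1],
        final_gfp_pos=final_pos,
        final_gfp_neg=final_neg,
        male_freq_wt=m_wt,
        male_freq_gfp=m_gfp,
    )


# --- transition fitness -----------------------------------------------------

def test_transition_fitness_exact_on_logit_linear_data():
    pts = []
    for g in (0, 5, 10, 15):
        p = expit(0.3 * (g - 7.5))
        k = p * 1000  # exact fractional counts
        pts.append((g, k, 1000))
    s, se = transition_fitness(pts)
    assert s == pytest.approx(0.3, abs=1e-12)
    assert se == pytest.approx(0.0, abs=1e-9)


def test_transition_fitness_two_point_clamp_example():
    # gen 0 at 48/96 (logit 0), gen 10 at 96/96 clamped to 96/97 (logit ln 96)
    s, _ = transition_fitness([(0, 48, 96), (10, 96, 96)])
    assert s == pytest.approx(math.log(96) / 10)


def test_transition_fitness_constant_frequency_is_zero():
    s, _ = transition_fitness([(0, 30, 96), (10, 30, 96), (20, 30, 96)])
    assert s == pytest.approx(0.0)


def test_transition_fitness_pools_replicate_series():
    series = [
        [(g, expit(0.25 * (g - 10)) * 500, 500) for g in (0, 10, 20)]
        for _ in range(3)
    ]
    s, _ = transition_fitness(series)
    assert s == pytest.approx(0.25, abs=1e-12)


def test_transition_fitness_rejects_degenerate_input():
    with pytest.raises(ValueError):
        transition_fitness([(5, 10, 96)])
    with pytest.raises(ValueError):
        transition_fitness([(5, 10, 96), (5, 20, 96)])


# --- GFP heterozygote correction ---------------------------------------------

def _enumeration_oracle(P, Q, m_wt, m_gfp, tol=1e-12):
    """Independent oracle: enumerate the mating-class x Mendelian-outcome
    table over explicit marker genotypes.  Parents are WW (wild-type
    origin) or GG (GFP origin); selfing transmits the parent genotype,
    crosses follow one-allele-per-parent segregation."""
    def progeny_table(a_gfp):
        a = {"WW": 1 - a_gfp, "GG": a_gfp}
        o = {"WW": min(2 * m_wt, 1.0), "GG": min(2 * m_gfp, 1.0)}
        supply = a["WW"] * m_wt + a["GG"] * m_gfp
        counts = {"WW": 0.0, "WG": 0.0, "GG": 0.0}
        for dam in ("WW", "GG"):
            counts[dam] += a[dam] * (1 - o[dam])  # selfed brood
            if supply > 0:
                for sire in ("WW", "GG"):
                    share = a[sire] * (m_wt if sire == "WW" else m_gfp) / supply
                    # one allele from each homozygous parent
                    child = "".join(sorted(dam[0] + sire[0]))
                    child = {"GW": "WG", "WW": "WW", "GG": "GG"}[child]
                    counts[child] += a[dam] * o[dam] * share
        return counts

    a_gfp = P / (P + Q)
    for _ in range(500):
        t = progeny_table(a_gfp)
        pos = t["WG"] + t["GG"]
        theta = t["WG"] / pos if pos > 0 else 0.0
        new = (2 - theta) * P / (2 * (P + Q))
        if abs(new - a_gfp) < tol:
            break
        a_gfp = new
    wt = 2 * Q + theta * P
    return wt, 2 * (P + Q) - wt


def test_gfp_correction_is_identity_without_males():
    wt, gfp = gfp_phenotype_to_allele_counts(comp_record(500, 500))
    assert (wt, gfp) == (1000.0, 1000.0)
    wt, gfp = gfp_phenotype_to_allele_counts(comp_record(400, 0))
    assert wt == 0.0 and gfp == 800.0


@pytest.mark.parametrize(
    "P, Q, m_wt, m_gfp",
    [
        (600, 400, 0.2, 0.2),
        (330, 902, 0.05, 0.05),
        (500, 500, 0.0, 0.3),
        (250, 750, 0.45, 0.1),
    ],
)
def test_gfp_correction_matches_enumeration_oracle(P, Q, m_wt, m_gfp):
    got = gfp_phenotype_to_allele_counts(comp_record(P, Q, m_wt, m_gfp))
    expected = _enumeration_oracle(P, Q, m_wt, m_gfp)
    assert got[0] == pytest.approx(expected[0], abs=1e-8)
    assert got[1] == pytest.approx(expected[1], abs=1e-8)


def test_gfp_correction_conserves_allele_mass():
    for P, Q, m in [(613, 387, 0.31), (10, 990, 0.08), (77, 3, 0.5)]:
        wt, gfp = gfp_phenotype_to_allele_counts(comp_record(P, Q, m, m))
        assert wt + gfp == pytest.approx(2 * (P + Q), abs=1e-9)
        assert wt >= 0 and gfp >= 0


# --- competitive fitness -----------------------------------------------------

def test_competition_fitness_examples():
    assert competition_fitness(comp_record(500, 500)).w == pytest.approx(0.0)
    # 0.5 -> 0.75 gives w = ln 3
    assert competition_fitness(comp_record(250, 750)).w == pytest.approx(math.log(3))


def test_competition_fitness_label_swap_negates_w():
    # exact antisymmetry where the correction is the identity (no males);
    # with males the GFP-positive class absorbs the heterozygotes, so the
    # phenotype table itself is not label-symmetric
    fwd = competition_fitness(comp_record(300, 700)).w
    rev = competition_fitness(comp_record(700, 300)).w
    assert fwd == pytest.approx(-rev, abs=1e-9)


def test_competition_fitness_clamps_boundary_with_warning():
    with pytest.warns(UserWarning, match="clamp"):
        w = competition_fitness(comp_record(1000, 0)).w
    assert math.isfinite(w)


# --- block centring ----------------------------------------------------------

def test_block_centering_examples():
    ests = [
        FitnessEstimate("B1", "REF", 0.2),
        FitnessEstimate("B1", "EXP", 0.5),
    ]
    out = block_center_and_delta(ests, "REF", {"trioecy": 0.1}, {"EXP": "trioecy"})
    exp = next(e for e in out if e.population_id == "EXP")
    assert exp.w_t == pytest.approx(0.3)
    assert exp.delta_w_t == pytest.approx(0.2)
    ref = next(e for e in out if e.population_id == "REF")
    assert ref.w_t == pytest.approx(0.0)


def test_block_centering_reference_mean_is_zero_within_block():
    rng = np.random.default_rng(0)
    ests = []
    for b in range(4):
        for _ in range(5):
            ests.append(FitnessEstimate(f"B{b}", "REF", rng.normal()))
            ests.append(FitnessEstimate(f"B{b}", "EXP", rng.normal()))
    out = block_center_and_delta(ests, "REF")
    for b in range(4):
        refs = [e.w_t for e in out if e.block == f"B{b}" and e.population_id == "REF"]
        assert np.mean(refs) == pytest.approx(0.0, abs=1e-12)


def test_block_without_reference_is_excluded_with_warning():
    ests = [
        FitnessEstimate("B1", "REF", 0.0),
        FitnessEstimate("B1", "EXP", 0.4),
        FitnessEstimate("B2", "EXP", 0.9),
    ]
    with pytest.warns(UserWarning, match="B2"):
        out = block_center_and_delta(ests, "REF")
    assert {e.block for e in out} == {"B1"}


# --- male fitness and QC ------------------------------------------------------

def test_male_fitness_examples():
    assert male_fitness(MaleFitnessRecord("p", 10, 50, 50)) == pytest.approx(0.0)
    assert male_fitness(MaleFitnessRecord("p", 10, 10, 30)) == pytest.approx(math.log(3))
    with pytest.warns(UserWarning, match="clamp"):
        w = male_fitness(MaleFitnessRecord("p", 10, 40, 0))
    assert w == pytest.approx(math.log(1 / 40))


def test_male_plate_qc_rules():
    plates = [
        MaleFitnessRecord("few_females", 5, 50, 50),
        MaleFitnessRecord("few_progeny", 10, 9, 10),
        MaleFitnessRecord("ok", 6, 10, 10),
    ]
    kept, tally = qc_filter_male_plates(plates)
    assert [p.plate for p in kept] == ["ok"]
    assert tally == {"few_females": 1, "few_progeny": 1}
    # idempotence
    kept2, tally2 = qc_filter_male_plates(kept)
    assert kept2 == kept and tally2 == {"few_females": 0, "few_progeny": 0}


def test_fertility_qc_rules():
    observations = [
        FertilityObservation(progeny=4, outcrossed=False),
        FertilityObservation(progeny=50, outcrossed=True, male_progeny=4),  # 8% males
        FertilityObservation(progeny=50, outcrossed=True, male_progeny=5),  # 10% kept
        FertilityObservation(progeny=8, outcrossed=False),
    ]
    kept, tally = qc_filter_fertility(observations)
    assert len(kept) == 2
    assert tally == {"few_progeny": 1, "few_males": 1}
    kept2, tally2 = qc_filter_fertility(kept)
    assert kept2 == kept


def test_setup_deviation_flag():
    assert not flag_setup_deviation(comp_record(1, 1, setup=(55, 45)))
    assert flag_setup_deviation(comp_record(1, 1, setup=(70, 30)))
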