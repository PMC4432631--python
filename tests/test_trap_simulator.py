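"""Trap simulator: shearing, classification rules, exact/MC agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sigmatrap import (
    ClassificationResult,
    FragmentLengthModel,
    Insert,
    SigmaRecognitionModel,
    SyntheticGenomeParams,
    VectorMode,
    classify_insert,
    estimate_gfp_fraction_mc,
    estimate_recognized_fraction,
    generate_genome,
    gfp_fraction_exact,
    promoter_firing_weights,
    recognized_fraction_ci,
    shear,
)

ALL = SigmaRecognitionModel("all")
NONE = SigmaRecognitionModel("none")
TRAP = VectorMode("promoterless")
LAC = VectorMode("upstream_promoter")


class TestShear:
    def test_fixed_model_yields_constant_lengths(self, g1):
        lm = FragmentLengthModel("fixed", 200, min_bp=1, max_bp=200)
        inserts = shear(g1, lm, 1000, seed=1)
        assert len(inserts) == 1000
        assert all(i.length == 200 for i in inserts)

    def test_deterministic_given_seed(self, g1):
        lm = FragmentLengthModel("fixed", 200, min_bp=1, max_bp=200)
        assert shear(g1, lm, 500, seed=3) == shear(g1, lm, 500, seed=3)

    def test_truncated_normal_mean_matches_analytic_oracle(self):
        """Empirical mean of resampled lengths lies within 3 s.e. of the
        truncated-normal mean computed analytically with scipy."""
        g = generate_genome(SyntheticGenomeParams(n_units=30, seed=2))
        lm = FragmentLengthModel("truncated_normal", 726, 150, 200, 1000)
        lengths = np.array([i.length for i in shear(g, lm, 100_000, seed=4)], dtype=float)
        a, b = (200 - 726) / 150, (1000 - 726) / 150
        expected = stats.truncnorm.mean(a, b, loc=726, scale=150)
        se = lengths.std(ddof=1) / np.sqrt(lengths.size)
        assert abs(lengths.mean() - expected) < 3 * se
        assert lengths.min() >= 200 and lengths.max() <= 1000

    def test_linear_genome_starts_never_overrun(self, two_strand_genome):
        lm = FragmentLengthModel("fixed", 500, min_bp=1, max_bp=500)
        inserts = shear(two_strand_genome, lm, 2000, seed=5)
        assert all(i.end <= two_strand_genome.length for i in inserts)

    def test_errors(self, g1):
        lm = FragmentLengthModel("fixed", 200, min_bp=1, max_bp=200)
        with pytest.raises(ValueError):
            shear(g1, lm, 0, seed=1)
        tiny = generate_genome(SyntheticGenomeParams(n_units=0, seed=0))
        with pytest.raises(ValueError, match="must exceed"):
            shear(tiny, lm, 10, seed=1)

    def test_invalid_length_model(self):
        with pytest.raises(ValueError):
            FragmentLengthModel("fixed", 100, min_bp=200, max_bp=1000)
        with pytest.raises(ValueError):
            FragmentLengthModel("gamma", 500)


class TestClassifyInsert:
    def test_featureless_insert_is_negative(self, g1):
        r = classify_insert(Insert(450, 200, "A"), g1, TRAP, ALL)
        assert r == ClassificationResult(False, "none")

    def test_sense_promoter_without_terminator_fires(self, g1):
        r = classify_insert(Insert(50, 200, "A"), g1, TRAP, ALL)
        assert r.gfp_positive and r.cause == "promoter_fired" and r.cause_id == "P_TU0"

    def test_upstream_mode_terminator_blocks(self, g1):
        """Induction-control rule: any sense terminator in the insert kills
        the signal when internal rescue is off."""
        r = classify_insert(Insert(350, 200, "A"), g1, LAC, ALL)
        assert not r.gfp_positive and r.blocking_terminator == "T_TU0"

    def test_no_recognition_means_no_signal(self, g1):
        r = classify_insert(Insert(50, 200, "A"), g1, TRAP, NONE)
        assert not r.gfp_positive

    def test_antisense_promoter_does_not_fire(self, g1):
        # orientation B makes '-' the sense strand; G1 only has a '+' promoter
        r = classify_insert(Insert(50, 200, "B"), g1, TRAP, ALL)
        assert not r.gfp_positive

    def test_internal_rescue_refires_after_terminator(self, g1):
        # insert [50, 450): contains promoter 100 then terminator 400 (sense '+')
        # upstream transcription is blocked, but promoter 100 precedes the
        # terminator, so it cannot rescue; a promoter *after* the last
        # terminator can.
        r = classify_insert(Insert(50, 400, "A"), g1, VectorMode("upstream_promoter", True), ALL)
        assert not r.gfp_positive  # promoter upstream of the terminator cannot rescue
        # an antisense terminator never blocks: the same window read in
        # orientation B sees no sense terminator and simply reads through
        r2 = classify_insert(Insert(350, 200, "B"), g1, VectorMode("upstream_promoter", True), ALL)
        assert r2.gfp_positive and r2.cause == "read_through"

    def test_wrapping_on_linear_genome_rejected(self, two_strand_genome):
        with pytest.raises(ValueError, match="linear"):
            classify_insert(Insert(2900, 200, "A"), two_strand_genome, TRAP, ALL)

    def test_wrapped_insert_sees_origin_spanning_features(self, g1):
        # insert [950, 1150) wraps and covers promoter 100
        r = classify_insert(Insert(950, 200, "A"), g1, TRAP, ALL)
        assert r.gfp_positive and r.cause_id == "P_TU0"

    def test_result_invariant_enforced(self):
        with pytest.raises(ValueError):
            ClassificationResult(True, "none")
        with pytest.raises(ValueError):
            ClassificationResult(False, "promoter_fired", cause_id="P")


class TestLeakyTerminators:
    def test_read_through_probability_recovered(self):
        """With read_through_prob rho, a blocked configuration fires in about
        rho of repeated classifications (and an rng is then mandatory)."""
        from sigmatrap import Gene, GenomeAnnotation, PromoterSite, TerminatorSite, TranscriptionUnit

        g = GenomeAnnotation("leaky", 1000, True, units=[
            TranscriptionUnit(
                id="TU0", strand="+", genes=(Gene("g0", 100, 400, "+"),),
                promoter=PromoterSite("P_TU0", 100, "+", "TU0"),
                terminator=TerminatorSite("T_TU0", 400, "+", read_through_prob=0.4)),
        ])
        g.validate()
        ins = Insert(350, 200, "A")  # terminator inside, upstream mode
        with pytest.raises(ValueError, match="rng"):
            classify_insert(ins, g, LAC, ALL)
        rng = np.random.default_rng(123)
        n = 4000
        fires = sum(classify_insert(ins, g, LAC, ALL, rng=rng).gfp_positive for _ in range(n))
        se = np.sqrt(0.4 * 0.6 / n)
        assert abs(fires / n - 0.4) < 4 * se


class TestExactEnumeration:
    def test_g1_reference_fraction(self, g1):
        assert gfp_fraction_exact(g1, TRAP, ALL, 200) == pytest.approx(0.10)

    def test_g1_early_terminator_fraction(self, g1_early_terminator):
        assert gfp_fraction_exact(g1_early_terminator, TRAP, ALL, 200) == pytest.approx(0.025)

    def test_no_recognition_gives_zero(self, g1):
        assert gfp_fraction_exact(g1, TRAP, NONE, 200) == 0.0

    def test_upstream_mode_on_terminator_free_genome_is_one(self, terminator_free_genome):
        assert gfp_fraction_exact(terminator_free_genome, LAC, ALL, 300) == 1.0

    def test_fragment_longer_than_genome_rejected(self, g1):
        with pytest.raises(ValueError):
            gfp_fraction_exact(g1, TRAP, ALL, 1001)

    def test_firing_weights_sum_to_positive_placements(self, g1):
        w = promoter_firing_weights(g1, TRAP, 200)
        assert w == {"P_TU0": 200}  # 0.10 of 2,000 placements


class TestMonteCarlo:
    def test_g1_estimate_within_three_se_of_exact(self, g1):
        lm = FragmentLengthModel("fixed", 200, min_bp=1, max_bp=200)
        est = estimate_gfp_fraction_mc(g1, TRAP, ALL, lm, 100_000, seed=11)
        assert abs(est.fraction - 0.10) < 3 * est.se
        assert est.ci_low < est.fraction < est.ci_high

    def test_no_recognition_exactly_zero(self, g1):
        lm = FragmentLengthModel("fixed", 200, min_bp=1, max_bp=200)
        est = estimate_gfp_fraction_mc(g1, TRAP, NONE, lm, 10_000, seed=1)
        assert est.fraction == 0.0

    def test_deterministic_given_seed(self, g1):
        lm = FragmentLengthModel("fixed", 200, min_bp=1, max_bp=200)
        a = estimate_gfp_fraction_mc(g1, TRAP, ALL, lm, 5_000, seed=2)
        b = estimate_gfp_fraction_mc(g1, TRAP, ALL, lm, 5_000, seed=2)
        assert a == b

    def test_cause_breakdown_consistent(self, g1):
        lm = FragmentLengthModel("fixed", 200, min_bp=1, max_bp=200)
        est = estimate_gfp_fraction_mc(g1, LAC, ALL, lm, 20_000, seed=3)
        assert est.cause_counts["read_through"] == est.n_positive
        assert est.cause_counts["none"] == est.n - est.n_positive

    def test_wilson_ci_option(self, g1):
        lm = FragmentLengthModel("fixed", 200, min_bp=1, max_bp=200)
        est = estimate_gfp_fraction_mc(g1, TRAP, ALL, lm, 5_000, seed=2, ci_method="wilson")
        assert 0 < est.ci_low < est.fraction < est.ci_high < 1


class TestRecognizedFraction:
    @pytest.mark.parametrize("observed,predicted,expected", [
        (0.23, 0.25, 0.92),
        (0.065, 0.25, 0.26),
        (0.4, 0.4, 1.0),
    ])
    def test_ratio(self, observed, predicted, expected):
        r = estimate_recognized_fraction(observed, predicted)
        assert r.estimate == pytest.approx(expected)
        assert not r.clipped

    def test_clipping_flag(self):
        r = estimate_recognized_fraction(0.5, 0.25)
        assert r.estimate == 1.0 and r.clipped

    def test_zero_predicted_rejected(self):
        with pytest.raises(ValueError):
            estimate_recognized_fraction(0.1, 0.0)

    def test_ci_contains_point_estimate(self):
        lo, hi = recognized_fraction_ci(500, 10_000, 0.2, firing_weights=[10] * 100)
        assert lo <= 0.05 / 0.2 <= hi


class TestSigmaModels:
    def test_bernoulli_sets_nested_in_p_rec(self, g1):
        g = generate_genome(SyntheticGenomeParams(n_units=200, seed=8))
        sets = [SigmaRecognitionModel("bernoulli", p_rec=p, seed=5).resolve(g)
                for p in (0.1, 0.3, 0.6, 0.9)]
        for small, big in zip(sets, sets[1:]):
            assert small <= big

    def test_subset_requires_known_ids(self, g1):
        with pytest.raises(ValueError, match="not in genome"):
            SigmaRecognitionModel("subset", recognized_ids=frozenset({"nope"})).resolve(g1)

    def test_extremes(self, g1):
        assert SigmaRecognitionModel("all").resolve(g1) == {"P_TU0"}
        assert SigmaRecognitionModel("none").resolve(g1) == frozenset()


class TestModelInvariants:
    """Structural monotonicity properties of the trap model."""

    def test_fraction_monotone_in_p_rec(self):
        g = generate_genome(SyntheticGenomeParams(n_units=150, seed=21))
        fracs = [gfp_fraction_exact(g, TRAP, SigmaRecognitionModel("bernoulli", p_rec=p, seed=9), 500)
                 for p in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert fracs == sorted(fracs)
        assert fracs[0] == 0.0

    def test_fraction_monotone_under_subset_growth(self):
        g = generate_genome(SyntheticGenomeParams(n_units=60, seed=22))
        ids = sorted(p.id for p in g.promoters())
        prev = -1.0
        for k in (0, 20, 40, 60):
            f = gfp_fraction_exact(
                g, TRAP, SigmaRecognitionModel("subset", recognized_ids=frozenset(ids[:k])), 500)
            assert f >= prev
            prev = f

    def test_adding_terminator_never_increases_fraction(self, terminator_free_genome, g1):
        from sigmatrap import GenomeAnnotation, TerminatorSite, TranscriptionUnit
        base = terminator_free_genome
        for mode in (TRAP, LAC):
            f_before = gfp_fraction_exact(base, mode, ALL, 300)
            modified_units = []
            for u in base.units:
                term_pos = u.span[1] if u.strand == "+" else u.span[0]
                modified_units.append(TranscriptionUnit(
                    id=u.id, strand=u.strand, genes=u.genes, promoter=u.promoter,
                    terminator=TerminatorSite(f"T_{u.id}", term_pos, u.strand)))
            with_terms = GenomeAnnotation(base.name, base.length, base.circular, modified_units)
            with_terms.validate()
            f_after = gfp_fraction_exact(with_terms, mode, ALL, 300)
            assert f_after <= f_before

    def test_short_fragment_limits(self, g1):
        """Trap fraction vanishes as L -> 0; induction-control fraction
        approaches 1 (no room for a terminator)."""
        trap_fracs = [gfp_fraction_exact(g1, TRAP, ALL, L) for L in (200, 50, 10, 1)]
        assert trap_fracs == sorted(trap_fracs, reverse=True)
        assert trap_fracs[-1] == pytest.approx(1 / 2000)  # only s == promoter fires
        lac_fracs = [gfp_fraction_exact(g1, LAC, ALL, L) for L in (200, 50, 10, 1)]
        assert lac_fracs == sorted(lac_fracs)
        assert lac_fracs[-1] == pytest.approx(1 - 1 / 2000)
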