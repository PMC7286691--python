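"""Footprinting statistics: probabilities, rates, normalization, PRI, FO."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import rates_for_q
from rloopflank.reactivity import (
    CorrectionModel,
    LaneProfile,
    OxidationProfile,
    ValidationError,
    aggregate_replicates,
    build_correction,
    correct_and_index,
    fraction_oxidized,
    oxidation_probabilities,
    quantify_experiment,
    rate_constants,
)
from rloopflank.synthetic import (
    ReplicateActivity,
    SimulationConfig,
    TrueRateProfile,
    enumerate_expected_lane,
    simulate_experiment,
)


def make_lane(volumes, first_present=1, **kw):
    n = len(volumes)
    return LaneProfile(
        substrate_id=kw.pop("substrate_id", "s"),
        replicate_set_id=kw.pop("replicate_set_id", "r"),
        band_volumes=tuple(float(v) for v in volumes),
        thymine_positions=tuple(range(1, n)),
        first_present_band=first_present,
        **kw,
    )


def make_ox(p, t_positions=None, **kw):
    return OxidationProfile(
        substrate_id=kw.pop("substrate_id", "s"),
        replicate_set_id=kw.pop("replicate_set_id", "r"),
        thymine_positions=t_positions or tuple(range(1, len(p) + 1)),
        p=tuple(p),
        missing=tuple(not math.isfinite(x) for x in p),
        **kw,
    )


class TestOxidationProbabilities:
    def test_uncleaved_lane_gives_zero_probabilities(self):
        prof = oxidation_probabilities(make_lane([0, 0, 100]))
        assert prof.p == (0.0, 0.0)

    def test_conditional_frequency_formula(self):
        # p1 = 10/100, p2 = 10/90
        prof = oxidation_probabilities(make_lane([10, 10, 80]))
        assert prof.p[0] == pytest.approx(0.1)
        assert prof.p[1] == pytest.approx(10 / 90)

    def test_enumeration_oracle_round_trip(self, two_thymine_profile, unit_activity):
        lane = enumerate_expected_lane(two_thymine_profile, unit_activity)
        prof = oxidation_probabilities(lane)
        assert prof.p == pytest.approx((0.2, 0.5), abs=1e-15)

    @settings(max_examples=50, deadline=None)
    @given(q=st.lists(st.floats(min_value=0.0, max_value=0.95), min_size=1, max_size=6))
    def test_estimator_inverts_generative_model_exactly(self, q):
        prof = TrueRateProfile("s", rates_for_q(q), 2.0)
        lane = enumerate_expected_lane(prof, ReplicateActivity("r", 1.0))
        if sum(lane.band_volumes) == 0:
            return
        est = oxidation_probabilities(lane)
        for qi, pi, miss in zip(q, est.p, est.missing):
            if not miss:
                assert pi == pytest.approx(qi, abs=1e-12)

    def test_truncated_bands_yield_missing_and_leave_the_rest_unchanged(self):
        full = oxidation_probabilities(make_lane([10, 20, 30, 40]))
        cut = oxidation_probabilities(make_lane([10, 20, 30, 40]).truncate(2))
        assert cut.missing[0] and not full.missing[0]
        assert cut.p[1:] == pytest.approx(full.p[1:], rel=1e-15)

    def test_annotated_non_thymine_band_can_be_excluded_from_denominators(self):
        lane = make_lane([10, 4, 10, 76])  # band 2 is a faint cytosine band
        default = oxidation_probabilities(lane)
        assert default.p[0] == pytest.approx(0.1)
        toggled = oxidation_probabilities(lane, exclude_positions={2})
        assert toggled.missing[1] and math.isnan(toggled.p[1])
        assert toggled.p[0] == pytest.approx(10 / 96)
        assert toggled.p[2] == pytest.approx(10 / 86)

    def test_all_zero_lane_is_an_error(self):
        with pytest.raises(ValidationError, match="zero"):
            oxidation_probabilities(make_lane([0, 0, 0]))

    def test_zero_denominator_yields_missing_not_exception(self, caplog):
        # all volume below band 3: denominator for band 3 is zero
        prof = oxidation_probabilities(make_lane([5, 5, 0, 0]))
        assert prof.missing[2]
        assert math.isnan(prof.p[2])


class TestRateConstants:
    def test_zero_probability_gives_zero_rate(self):
        k, sat, miss = rate_constants(make_ox([0.0]), t=2.0)
        assert k[0] == 0.0 and not sat[0] and not miss[0]

    def test_half_oxidized_in_two_minutes(self):
        k, _, _ = rate_constants(make_ox([0.5]), t=2.0)
        assert k[0] == pytest.approx(math.log(2) / 2)

    def test_certain_oxidation_is_flagged_not_quantified(self):
        k, sat, miss = rate_constants(make_ox([1.0]), t=2.0)
        assert miss[0] and sat[0] and math.isnan(k[0])

    def test_saturation_threshold_flags_but_quantifies(self):
        k, sat, miss = rate_constants(make_ox([0.995]), t=2.0)
        assert sat[0] and not miss[0] and math.isfinite(k[0])

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValidationError):
            rate_constants(make_ox([0.5]), t=0.0)


class TestCorrection:
    def test_single_set_has_unit_factor(self):
        model = build_correction({"r1": [0.3, 0.3]})
        assert model.mu_ref == pytest.approx(0.3)
        assert model.factor("r1") == pytest.approx(1.0)

    def test_two_sets_factor_arithmetic(self):
        model = build_correction({"a": [0.2], "b": [0.4]})
        assert model.mu_ref == pytest.approx(0.3)
        assert model.factor("a") == pytest.approx(1.5)
        assert model.factor("b") == pytest.approx(0.75)

    def test_set_without_reference_measurement_is_named_in_error(self):
        with pytest.raises(ValidationError, match="r2"):
            build_correction({"r1": [0.3], "r2": []})

    def test_unknown_replicate_set_rejected(self):
        model = build_correction({"r1": [0.3]})
        with pytest.raises(ValidationError, match="r9"):
            model.factor("r9")

    def test_correction_equalizes_simulated_activity_extremes(self):
        # activity factors {0.5, 2.0} at equal true rates: corrected reference
        # rates agree across sets within Monte-Carlo error
        profs = [TrueRateProfile("s1", rates_for_q([0.3, 0.2, 0.1]), 2.0, reference_index=2)]
        sets = [ReplicateActivity("lo", 0.5), ReplicateActivity("hi", 2.0)]
        lanes = simulate_experiment(profs, sets, SimulationConfig(10**6, seed=13))
        maps = [_substrate_for(profs[0])]
        corrected, model = quantify_experiment(lanes, maps)
        k_ref = {p.replicate_set_id: p.k_corr[2] for p in corrected}
        assert k_ref["lo"] == pytest.approx(k_ref["hi"], rel=0.02)


def _substrate_for(profile):
    from rloopflank.reactivity import SubstrateMap

    m = profile.n_thymines
    seq = "T" * (m + 2)
    return SubstrateMap(
        substrate_id=profile.substrate_id,
        strand_sequences={"top": seq, "bottom": "A" * (m + 2)},
        labeled_strand="top",
        probed_thymines=profile.band_positions(),
        reference_thymine=profile.band_positions()[profile.reference_index],
        quench_time_min=profile.quench_time_min,
    )


class TestCorrectAndIndex:
    def _profile(self, p, t=2.0, model=None):
        model = model or CorrectionModel(kbar_ref={"r": 0.5}, mu_ref=0.5)
        return correct_and_index(make_ox(list(p)), model, t)

    def test_single_stranded_rate_scores_pri_one(self):
        # corrected rate equal to kss_corr -> PRI = 1
        t = 2.0
        p = -math.expm1(-0.79 * t)
        prof = self._profile([p], t)
        assert prof.pri[0] == pytest.approx(1.0, rel=1e-12)

    def test_pri_is_linear_in_corrected_rate(self):
        # twice the corrected rate of a PRI = 0.2 thymine -> PRI = 0.4
        t = 2.0
        k1 = 0.2 * 0.79
        p = [-math.expm1(-k1 * t), -math.expm1(-2 * k1 * t)]
        prof = self._profile(p, t)
        assert prof.pri[0] == pytest.approx(0.2, rel=1e-12)
        assert prof.pri[1] == pytest.approx(0.4, rel=1e-12)

    def test_zero_rate_gives_zero_everything(self):
        prof = self._profile([0.0])
        assert prof.pri[0] == 0.0 and prof.p_corr[0] == 0.0 and prof.k_corr[0] == 0.0

    def test_correction_factor_is_applied(self):
        model = CorrectionModel(kbar_ref={"r": 0.2}, mu_ref=0.3)
        prof = self._profile([0.5], t=2.0, model=model)
        assert prof.k_corr[0] == pytest.approx(1.5 * math.log(2) / 2)

    def test_pri_scales_multiplicatively(self):
        t, c = 2.0, 3.7
        k = 0.11
        base = self._profile([-math.expm1(-k * t)], t).pri[0]
        scaled = self._profile([-math.expm1(-c * k * t)], t).pri[0]
        assert scaled == pytest.approx(c * base, rel=1e-9)


class TestFractionOxidized:
    def _reactivity(self, p_corr, positions, strand, sub="sub1", t=2.0):
        n = len(p_corr)
        k_corr = tuple(-math.log1p(-p) / t for p in p_corr)
        from rloopflank.reactivity import ReactivityProfile

        return ReactivityProfile(
            substrate_id=sub,
            replicate_set_id="r",
            thymine_positions=tuple(positions),
            p=tuple(p_corr),
            k=k_corr,
            k_corr=k_corr,
            pri=tuple(k / 0.79 for k in k_corr),
            p_corr=tuple(p_corr),
            saturated=(False,) * n,
            missing=(False,) * n,
            truncated=(False,) * n,
            labeled_strand=strand,
        )

    def test_no_oxidation_means_fo_zero(self, flank_substrate):
        prof = self._reactivity([0.0] * 6, (3, 4, 5, 6, 7, 10), "NTS")
        assert fraction_oxidized([prof], flank_substrate).fo == 0.0

    def test_two_half_oxidized_members_give_three_quarters(self, flank_substrate):
        import dataclasses

        sub = dataclasses.replace(flank_substrate, rlf_members=flank_substrate.rlf_members[:2])
        prof = self._reactivity([0.5, 0.5, 0, 0, 0, 0], (3, 4, 5, 6, 7, 10), "NTS")
        assert fraction_oxidized([prof], sub).fo == pytest.approx(0.75, rel=1e-12)

    def test_product_and_exponential_sum_forms_agree(self, flank_substrate, rng):
        from rloopflank.reactivity import fo_from_rates

        p_corr = rng.uniform(0.01, 0.6, 5)
        prof = self._reactivity(list(p_corr) + [0.1], (3, 4, 5, 6, 7, 10), "NTS")
        res = fraction_oxidized([prof], flank_substrate)
        t = flank_substrate.quench_time_min
        k_sum = sum(-math.log1p(-p) / t for p in p_corr)
        assert res.fo == pytest.approx(fo_from_rates(k_sum, t), rel=1e-12)

    def test_members_resolved_across_both_strand_labelings(self, flank_substrate):
        import dataclasses

        members = flank_substrate.rlf_members[:3] + tuple(
            dataclasses.replace(m, strand="TS", position=m.position + 20)
            for m in flank_substrate.rlf_members[3:]
        )
        sub = dataclasses.replace(flank_substrate, rlf_members=members)
        nts = self._reactivity([0.2, 0.2, 0.2, 0, 0, 0], (3, 4, 5, 6, 7, 10), "NTS")
        ts = self._reactivity([0.3, 0.3], (26, 27), "TS")
        res = fraction_oxidized([nts, ts], sub)
        assert res.fo == pytest.approx(1 - (1 - 0.2) ** 3 * (1 - 0.3) ** 2, rel=1e-12)

    def test_missing_member_listed_in_error(self, flank_substrate):
        prof = self._reactivity([0.1, 0.1], (3, 4), "NTS")
        with pytest.raises(ValidationError, match="T3"):
            fraction_oxidized([prof], flank_substrate)

    def test_duplicate_assignment_rejected(self, flank_substrate):
        prof = self._reactivity([0.1] * 6, (3, 4, 5, 6, 7, 10), "NTS")
        with pytest.raises(ValidationError, match="exactly one"):
            fraction_oxidized([prof, prof], flank_substrate)

    def test_fo_matches_monte_carlo_molecule_counting(self, flank_substrate, rng):
        p_corr = np.array([0.15, 0.08, 0.3, 0.05, 0.12])
        prof = self._reactivity(list(p_corr) + [0.1], (3, 4, 5, 6, 7, 10), "NTS")
        fo = fraction_oxidized([prof], flank_substrate).fo
        n = 10**6
        hits = (rng.random((n, 5)) < p_corr).any(axis=1).mean()
        sigma = math.sqrt(fo * (1 - fo) / n)
        assert abs(hits - fo) < 3 * sigma


class TestAggregateReplicates:
    def test_identical_replicates_have_zero_sd(self):
        agg = aggregate_replicates([0.5, 0.5, 0.5])
        assert agg.mean == 0.5 and agg.sd == 0.0

    def test_sample_standard_deviation_uses_n_minus_one(self):
        agg = aggregate_replicates([0.1, 0.2, 0.3])
        assert agg.mean == pytest.approx(0.2)
        assert agg.sd == pytest.approx(0.1)

    def test_single_replicate_has_no_sd(self):
        agg = aggregate_replicates([0.7])
        assert agg.mean == 0.7 and not agg.sd_available

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_replicates([])

    def test_vector_replicates_aggregate_elementwise(self):
        agg = aggregate_replicates([np.array([1.0, 2.0]), np.array([3.0, 4.0])])
        assert np.allclose(agg.mean, [2.0, 3.0])
        assert np.allclose(agg.sd, [math.sqrt(2), math.sqrt(2)])


class TestPipelineInvariances:
    @settings(max_examples=25, deadline=None)
    @given(
        volumes=st.lists(st.floats(min_value=0.1, max_value=1e6), min_size=3, max_size=8),
        c=st.floats(min_value=1e-3, max_value=1e3),
        cut=st.integers(min_value=1, max_value=3),
    )
    def test_scale_and_truncation_invariance(self, volumes, c, cut):
        lane = make_lane(volumes)
        base = oxidation_probabilities(lane)
        scaled = oxidation_probabilities(lane.scale(c))
        assert scaled.p == pytest.approx(base.p, rel=1e-9)
        cut = min(cut, lane.n_bands)
        trunc = oxidation_probabilities(lane.truncate(cut))
        for j in range(cut - 1, lane.n_bands - 1):
            assert trunc.p[j] == pytest.approx(base.p[j], rel=1e-12)

    def test_normalization_shrinks_between_set_scatter(self):
        profs = [
            TrueRateProfile("s1", rates_for_q([0.4, 0.25, 0.15, 0.1]), 2.0, reference_index=3)
        ]
        rng = np.random.default_rng(5)
        sets = [ReplicateActivity(f"r{i}", f) for i, f in enumerate((0.5, 1.0, 2.0))]
        lanes = simulate_experiment(profs, sets, SimulationConfig(10**6, seed=17))
        corrected, _ = quantify_experiment(lanes, [_substrate_for(profs[0])])
        k_raw = np.array([p.k for p in corrected])
        k_corr = np.array([p.k_corr for p in corrected])

        def cv(mat):
            return (mat.std(axis=0, ddof=1) / mat.mean(axis=0)).mean()

        assert cv(k_corr) < cv(k_raw) / 3
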