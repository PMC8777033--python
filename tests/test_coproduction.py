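"""Secretory enumeration, target intersection, mutant validation, scoring."""

import pytest
from hypothesis import given, settings, strategies as st

import cofseof as cf
import oracle
from cofseof.coproduction import (
    CoProductionConfig,
    ScoreReport,
    ValidationResult,
    evaluate_intervention,
    score,
)
from cofseof.fseof import TargetClassification


def _validation(mut, wt, bio_wt, bio_mut, product="EX_P_e"):
    return ValidationResult(
        intervention=cf.InterventionSet((cf.Intervention("R3", cf.AMP, 1.0),)),
        products=(product,),
        wt_flux={product: wt},
        mut_flux={product: mut},
        bio_wt=bio_wt,
        bio_mut=bio_mut,
        gain_pass={product: mut > wt},
        biomass_pass=True,
    )


class TestSecretory:
    def test_single_product_network(self, toy_a):
        found = cf.secretory_metabolites(toy_a)
        assert [(s.metabolite_id, s.exchange_id) for s in found] == [("P_e", "EX_P_e")]
        assert found[0].wt_flux == pytest.approx(0.0, abs=1e-6)

    def test_coupled_network_secretes_both(self, toy_b):
        assert [s.exchange_id for s in cf.secretory_metabolites(toy_b)] == [
            "EX_P_e",
            "EX_Q_e",
        ]

    def test_closed_secretion_yields_empty_list(self, toy_a):
        toy_a.reactions.EX_P_e.upper_bound = 0.0
        assert cf.secretory_metabolites(toy_a) == []

    @pytest.mark.parametrize("seed", [6, 17])
    def test_matches_capability_oracle(self, seed):
        model = cf.random_toy(seed)
        mine = [(s.exchange_id, s.wt_flux) for s in cf.secretory_metabolites(model)]
        expected = oracle.secretory(model)
        assert [eid for eid, _ in mine] == [eid for eid, _ in expected]
        for (_, wt_mine), (_, wt_oracle) in zip(mine, expected):
            assert wt_mine == pytest.approx(wt_oracle, abs=1e-6)


class TestWildTypeReference:
    def test_toynet_a(self, toy_a):
        bio_wt, wt_flux = cf.wild_type_reference(toy_a, ["EX_P_e"])
        assert bio_wt == pytest.approx(20.0, abs=1e-6)
        assert wt_flux["EX_P_e"] == pytest.approx(0.0, abs=1e-6)

    def test_zero_carbon_medium(self, toy_a):
        toy_a.reactions.EX_glc_e.lower_bound = 0.0
        bio_wt, _ = cf.wild_type_reference(toy_a, ["EX_P_e"])
        assert bio_wt == pytest.approx(0.0, abs=1e-6)


class TestCommonTargets:
    def _classification(self, product, labels, directions=None):
        return TargetClassification(product, labels, directions or {})

    def test_identity_intersection(self):
        a = self._classification("A", {"R3": cf.AMP_CANDIDATE}, {"R3": 1})
        b = self._classification("B", {"R3": cf.AMP_CANDIDATE}, {"R3": 1})
        assert cf.common_targets(a, b) == [("R3", cf.AMP, 1)]

    def test_label_mismatch_excluded(self):
        a = self._classification("A", {"R3": cf.AMP_CANDIDATE}, {"R3": 1})
        b = self._classification("B", {"R3": cf.KO_CANDIDATE}, {"R3": 1})
        assert cf.common_targets(a, b) == []

    def test_opposite_amp_directions_excluded(self):
        a = self._classification("A", {"R3": cf.AMP_CANDIDATE}, {"R3": 1})
        b = self._classification("B", {"R3": cf.AMP_CANDIDATE}, {"R3": -1})
        assert cf.common_targets(a, b) == []

    def test_coupled_branch_found_on_toynet_b(self, toy_b):
        class_p = cf.candidate_targets(toy_b, "EX_P_e")
        class_q = cf.candidate_targets(toy_b, "EX_Q_e")
        common = cf.common_targets(class_p, class_q)
        assert ("R5", cf.AMP, 1) in common
        assert ("R2", cf.KO, 0) in common


class TestValidation:
    def test_amplified_coupled_branch_passes(self, toy_b):
        level = cf.theoretical_max(toy_b, "R5")
        assert level == pytest.approx(12.0, abs=1e-6)
        result = cf.validate_intervention(
            toy_b,
            cf.InterventionSet((cf.Intervention("R5", cf.AMP, level),)),
            ["EX_P_e", "EX_Q_e"],
        )
        assert result.bio_mut == pytest.approx(8.0, abs=1e-6)
        assert result.mut_flux["EX_P_e"] == pytest.approx(12.0, abs=1e-6)
        assert result.mut_flux["EX_Q_e"] == pytest.approx(12.0, abs=1e-6)
        assert result.biomass_pass  # 8 = 40% of wild-type 20
        assert result.pass_overall

    def test_knocking_out_sole_growth_route_fails_biomass(self, toy_a):
        result = cf.validate_intervention(
            toy_a, cf.InterventionSet((cf.Intervention("R2", cf.KO),)), ["EX_P_e"]
        )
        assert result.bio_mut == pytest.approx(0.0, abs=1e-6)
        assert not result.biomass_pass
        assert not result.pass_overall

    def test_infeasible_mutant_reported_not_raised(self, toy_b):
        # pin the coupled branch above what carbon supply allows
        result = cf.validate_intervention(
            toy_b,
            cf.InterventionSet((cf.Intervention("R5", cf.AMP, 500.0),)),
            ["EX_P_e", "EX_Q_e"],
        )
        assert result.bio_mut == 0.0
        assert not result.pass_overall

    def test_empty_product_list_reduces_to_biomass_flag(self, toy_b):
        result = cf.validate_intervention(
            toy_b, cf.InterventionSet((cf.Intervention("R5", cf.AMP, 12.0),)), []
        )
        assert result.pass_overall == result.biomass_pass

    def test_fva_maximum_contains_fba_flux(self, toy_b):
        mutant = cf.apply_interventions(
            toy_b, cf.InterventionSet((cf.Intervention("R5", cf.AMP, 12.0),))
        )
        fba_flux = cf.fba(mutant).fluxes["EX_P_e"]
        result = cf.validate_intervention(
            toy_b,
            cf.InterventionSet((cf.Intervention("R5", cf.AMP, 12.0),)),
            ["EX_P_e"],
        )
        assert result.mut_flux["EX_P_e"] >= fba_flux - 1e-6


class TestScore:
    def test_quotient_formula(self):
        report = score(_validation(mut=10.0, wt=2.0, bio_wt=1.0, bio_mut=0.6))
        assert report.scores["EX_P_e"] == pytest.approx(20.0)

    def test_zero_gain_zero_score(self):
        report = score(_validation(mut=2.0, wt=2.0, bio_wt=1.0, bio_mut=0.6))
        assert report.scores["EX_P_e"] == 0.0

    def test_near_zero_wild_type_flux_treated_as_zero(self):
        report = score(_validation(mut=5.0, wt=9e-6, bio_wt=1.0, bio_mut=0.5))
        assert report.scores["EX_P_e"] == pytest.approx(10.0)

    def test_unchanged_growth_floored_denominator(self):
        report = score(_validation(mut=1.0, wt=0.0, bio_wt=20.0, bio_mut=20.0))
        assert report.scores["EX_P_e"] == pytest.approx(1.0 / 1e-4)

    def test_overall_is_sum_of_parts(self, toy_b):
        record = evaluate_intervention(
            toy_b,
            cf.InterventionSet((cf.Intervention("R5", cf.AMP, 12.0),)),
            ["EX_P_e", "EX_Q_e"],
        )
        assert record.score_report.overall == pytest.approx(
            sum(record.score_report.scores.values()), abs=1e-9
        )
        assert record.score_report.scores == {"EX_P_e": 1.0, "EX_Q_e": 1.0}

    @settings(derandomize=True, max_examples=40)
    @given(
        mut=st.floats(0.0, 50.0),
        gain=st.floats(0.1, 10.0),
        bio_mut=st.floats(0.0, 19.0),
    )
    def test_score_strictly_increases_with_mutant_flux(self, mut, gain, bio_mut):
        low = score(_validation(mut=mut, wt=0.0, bio_wt=20.0, bio_mut=bio_mut))
        high = score(_validation(mut=mut + gain, wt=0.0, bio_wt=20.0, bio_mut=bio_mut))
        assert high.scores["EX_P_e"] > low.scores["EX_P_e"]
        assert high.overall > low.overall


class TestPairwiseSweep:
    def test_toynet_b_finds_the_coupled_amplification(self, toy_b):
        records = cf.pairwise_coproduction(toy_b)
        assert [r.intervention.reaction_ids for r in records] == [("R5",), ("R2",)]
        top = records[0]
        assert top.passed and top.intervention.signature() == "A"
        assert top.overall_score == pytest.approx(2.0, abs=1e-6)
        assert cf.passing_pairs(records) == [("EX_P_e", "EX_Q_e")]

    def test_single_secretory_metabolite_yields_nothing(self, toy_a):
        assert cf.pairwise_coproduction(toy_a) == []

    def test_rerun_is_identical(self, toy_b):
        first = cf.pairwise_coproduction(toy_b)
        second = cf.pairwise_coproduction(toy_b)
        assert cf.records_to_frame(first).equals(cf.records_to_frame(second))

    def test_cached_sweep_equals_per_pair_recomputation(self, toy_b):
        config = CoProductionConfig()
        records = cf.pairwise_coproduction(toy_b, config)
        for record in records:
            fresh = evaluate_intervention(
                toy_b,
                record.intervention,
                list(record.products),
                amp_levels={
                    a.reaction_id: a.level
                    for a in record.intervention
                    if a.kind == cf.AMP
                },
                config=config,
            )
            assert fresh.validation.bio_mut == pytest.approx(
                record.validation.bio_mut, abs=1e-6
            )
            assert fresh.overall_score == pytest.approx(record.overall_score, abs=1e-6)
            assert fresh.passed == record.passed

    def test_passing_records_satisfy_thresholds_when_rechecked(self, toy_b):
        config = CoProductionConfig()
        for record in cf.pairwise_coproduction(toy_b, config):
            if not record.passed:
                continue
            v = record.validation
            assert v.bio_mut >= config.biomass_retention * v.bio_wt  # <=75% drop
            for p in record.products:
                if v.wt_flux[p] < config.wt_zero:
                    assert v.mut_flux[p] > config.absolute_gain
                else:
                    assert v.mut_flux[p] > 1.05 * v.wt_flux[p]  # >5% gain

    def test_report_frame_layout(self, toy_b):
        frame = cf.records_to_frame(cf.pairwise_coproduction(toy_b))
        assert list(frame["product_a"]) == ["EX_P_e", "EX_P_e"]
        assert list(frame["signature"]) == ["A", "K"]
        assert set(frame.columns) >= {
            "wt_flux_a",
            "wt_flux_b",
            "intervention",
            "mut_biomass",
            "overall_score",
            "passed",
        }
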