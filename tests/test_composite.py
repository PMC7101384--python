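"""Normalisation, AHP weighting, component indices, risk aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from heatrisk.composite import (NormalizationWarning, PairwiseMatrix,
                                WeightSet, aggregate_risk, ahp_weights,
                                categorize, consistent_matrix, ensemble_hhri,
                                exposure_index, hazard_index, minmax_normalize,
                                risk_table, screen_experts,
                                vulnerability_index, weights_from_matrices)
from heatrisk.raster import ZoneMap


class TestMinMax:
    def test_plain_linear_map(self):
        assert np.allclose(minmax_normalize([2, 4, 6]), [0, 0.5, 1])

    def test_floor_anchoring_at_mmt(self):
        # values at or below the MMT threshold carry zero hazard
        out = minmax_normalize([37, 38.3, 40, 41.7], floor=38.3)
        assert np.allclose(out, [0, 0, 0.5, 1])

    def test_constant_input_zeroes_with_warning(self):
        with pytest.warns(NormalizationWarning):
            out = minmax_normalize([3.0, 3.0, 3.0])
        assert np.allclose(out, 0.0)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize([np.nan, np.nan])

    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=2, max_size=40))
    def test_output_always_within_unit_interval(self, values):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NormalizationWarning)
            out = minmax_normalize(values)
        finite = out[np.isfinite(out)]
        assert np.all((finite >= 0) & (finite <= 1))


class TestCategorize:
    @pytest.mark.parametrize("value, label", [
        (0.0, "very low"), (0.2, "very low"), (0.21, "low"), (0.4, "low"),
        (0.6, "moderate"), (0.80, "high"), (0.81, "very high"), (1.0, "very high"),
    ])
    def test_upper_inclusive_five_level_scale(self, value, label):
        assert categorize(value) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize(1.2)


class TestAHP:
    def test_consistent_matrix_recovers_weights_exactly(self):
        pm = consistent_matrix(("h", "e", "v"), (0.5, 0.3, 0.2))
        w, cr = ahp_weights(pm)
        assert np.allclose(w, (0.5, 0.3, 0.2), atol=1e-9)
        assert cr == pytest.approx(0.0, abs=1e-9)

    def test_all_ones_matrix_gives_equal_weights(self):
        pm = PairwiseMatrix(("a", "b", "c", "d"), np.ones((4, 4)))
        w, cr = ahp_weights(pm)
        assert np.allclose(w, 0.25) and cr == pytest.approx(0.0, abs=1e-12)

    def test_saaty_three_item_example(self):
        pm = PairwiseMatrix(("a", "b", "c"),
                            [[1, 2, 4], [0.5, 1, 2], [0.25, 0.5, 1]])
        w, cr = ahp_weights(pm)
        assert np.allclose(w, (4 / 7, 2 / 7, 1 / 7), atol=1e-12)
        assert cr == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6, 7])
    def test_eigenvector_inverts_construction_for_sizes_2_to_7(self, n, rng):
        true = rng.dirichlet(np.ones(n)) + 0.01
        true /= true.sum()
        w, cr = ahp_weights(consistent_matrix(range(n), true))
        assert np.allclose(w, true, atol=1e-9)
        assert cr <= 1e-9

    def test_non_reciprocal_rejected(self):
        with pytest.raises(ValueError, match="reciprocal"):
            PairwiseMatrix(("a", "b"), [[1, 2], [1, 1]])


class TestScreening:
    def ws(self, eid, cr):
        return WeightSet(eid, (0.2, 0.5, 0.3), (0.5, 0.5), (1 / 3,) * 3,
                         (1 / 3,) * 3, {"risk": cr})

    def test_all_consistent_all_retained(self):
        sets = [self.ws(i, 0.02) for i in range(5)]
        assert len(screen_experts(sets)) == 5

    def test_inconsistent_experts_dropped(self):
        sets = [self.ws(0, 0.02), self.ws(1, 0.25), self.ws(2, 0.1)]
        kept = screen_experts(sets, cr_threshold=0.1)
        assert [w.expert_id for w in kept] == [0, 2]

    def test_infinite_threshold_is_identity(self):
        sets = [self.ws(i, 5.0) for i in range(3)]
        assert screen_experts(sets, cr_threshold=np.inf) == sets


def toy_zones():
    """3 cities of 4 pixels each, one province."""
    city = np.array([[0, 0, 0, 0], [1, 1, 1, 1], [2, 2, 2, 2]])
    return ZoneMap(np.zeros((3, 4), dtype=int), city, {0: 0, 1: 0, 2: 0})


class TestHazardIndex:
    # hand-computed oracle: phase maps floored at the MMTs, averaged
    # pixelwise, city means, re-normalised (spreadsheet arithmetic)
    DAY = np.array([[39, 40, 41, 42], [38, 38, 38, 38], [36, 40, 44, 38.3]])
    NIGHT = np.array([[25.0] * 4, [24.0] * 4, [25.0] * 4])

    def test_twelve_pixel_fixture_matches_hand_computation(self):
        out = hazard_index(self.DAY, self.NIGHT, 38.3, 24.3, toy_zones())
        assert np.allclose(out.to_numpy(), [1.0, 0.0, 0.9556962025316454],
                           atol=1e-12)

    def test_city_below_both_mmts_has_zero_hazard(self):
        out = hazard_index(self.DAY, self.NIGHT, 38.3, 24.3, toy_zones())
        assert out[1] == 0.0

    def test_uniform_warming_of_hot_city_does_not_decrease_index(self):
        base = hazard_index(self.DAY, self.NIGHT, 38.3, 24.3, toy_zones())
        warmed = self.DAY.copy()
        warmed[0] += 1.0
        out = hazard_index(warmed, self.NIGHT, 38.3, 24.3, toy_zones())
        assert out[0] >= base[0] - 1e-12


class TestExposureIndex:
    def test_three_city_fixture_matches_hand_computation(self):
        dens = np.array([[100.0] * 4, [500.0] * 4, [900.0] * 4])
        out = exposure_index(dens, toy_zones())
        assert np.allclose(out.to_numpy(), [0.0, 0.5, 1.0], atol=1e-12)

    def test_densest_city_maps_to_one(self, rng):
        dens = rng.uniform(50, 5000, (3, 4))
        out = exposure_index(dens, toy_zones())
        assert out.max() == pytest.approx(1.0)

    def test_equal_density_everywhere_gives_zeros(self):
        with pytest.warns(NormalizationWarning):
            out = exposure_index(np.full((3, 4), 250.0), toy_zones())
        assert np.allclose(out, 0.0)


class TestVulnerabilityIndex:
    TABLE = pd.DataFrame({
        "city": [0, 1, 2, 3],
        "young_prop": [0.30, 0.40, 0.25, 0.35],
        "old_prop": [0.05, 0.08, 0.04, 0.06],
        "poverty_incidence": [0.10, 0.50, 0.05, 0.30],
        "mean_evi": [0.20, 0.60, 0.70, 0.40],
        "city_net_income": [5e9, 1e9, 8e9, 2e9],
        "per_capita_income": [30000, 15000, 40000, 20000],
    })
    WS = WeightSet(0, (0.22, 0.45, 0.33), (0.44, 0.56),
                   (0.5, 0.2, 0.3), (0.4, 0.3, 0.3))

    def test_four_city_fixture_matches_spreadsheet_oracle(self):
        out = vulnerability_index(self.TABLE, self.WS)
        assert np.allclose(out.to_numpy(),
                           [0.5765107212, 1.0, 0.0, 0.8245614035], atol=1e-9)

    def test_extremal_city_scores_one(self):
        out = vulnerability_index(self.TABLE, self.WS)
        assert out[1] == pytest.approx(1.0)  # poorest, most sensitive city

    def test_zero_capacity_weight_preserves_sensitivity_ordering(self):
        ws = WeightSet(0, (0.22, 0.45, 0.33), (1.0, 0.0),
                       (0.5, 0.2, 0.3), (0.4, 0.3, 0.3))
        out = vulnerability_index(self.TABLE, ws)
        norm = {c: minmax_normalize(self.TABLE[c].to_numpy())
                for c in ("young_prop", "old_prop", "poverty_incidence")}
        S = (0.5 * norm["young_prop"] + 0.2 * norm["old_prop"]
             + 0.3 * norm["poverty_incidence"])
        assert list(out.sort_values().index) == list(pd.Series(S).sort_values().index)

    def test_missing_indicator_rejected(self):
        with pytest.raises(ValueError, match="lacks"):
            vulnerability_index(self.TABLE.drop(columns="mean_evi"), self.WS)


class TestAggregateRisk:
    def test_equal_components_are_invariant_to_weights(self, rng):
        for _ in range(5):
            w = rng.dirichlet(np.ones(3))
            out = aggregate_risk([0.5], [0.5], [0.5], w)
            assert out[0] == pytest.approx(0.5)

    def test_reported_mean_weights_worked_example(self):
        assert aggregate_risk([1.0], [1.0], [1.0], (0.22, 0.45, 0.33))[0] == \
            pytest.approx(1.0)
        assert aggregate_risk([0.9], [1.0], [0.4], (0.22, 0.45, 0.33))[0] == \
            pytest.approx(0.780)

    def test_weight_sum_violation_rejected(self):
        with pytest.raises(ValueError):
            aggregate_risk([0.5], [0.5], [0.5], (0.5, 0.5, 0.5))

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
           st.floats(0.001, 1), st.floats(0, 0.3))
    def test_monotone_in_every_component(self, h, e, v, bump, wshift):
        w = np.array([0.22 + wshift, 0.45 - wshift, 0.33])
        w /= w.sum()
        base = aggregate_risk([h], [e], [v], w)[0]
        assert aggregate_risk([min(h + bump, 1)], [e], [v], w)[0] >= base - 1e-12
        assert aggregate_risk([h], [min(e + bump, 1)], [v], w)[0] >= base - 1e-12
        assert aggregate_risk([h], [e], [min(v + bump, 1)], w)[0] >= base - 1e-12


class TestEnsemble:
    def test_identical_experts_give_zero_width_ci(self):
        ri = pd.DataFrame({e: [0.4, 0.7] for e in range(5)})
        out = ensemble_hhri(ri)
        assert np.allclose(out["ci_low"], out["hhri"])
        assert np.allclose(out["ci_high"], out["hhri"])

    def test_twelve_expert_t_interval_oracle(self):
        # 12 evenly spaced assessments 0.70..0.92: closed-form t interval
        vals = 0.70 + 0.02 * np.arange(12)
        out = ensemble_hhri(pd.DataFrame([vals]))
        assert out.loc[0, "hhri"] == pytest.approx(0.81)
        assert out.loc[0, "ci_low"] == pytest.approx(0.7641828402690772, abs=1e-10)
        assert out.loc[0, "ci_high"] == pytest.approx(0.8558171597309229, abs=1e-10)
        assert out.loc[0, "category"] == "very high"

    def test_ranking_invariant_to_expert_order(self, rng):
        ri = pd.DataFrame(rng.uniform(0, 1, (6, 8)))
        shuffled = ri[rng.permutation(ri.columns)]
        a = ensemble_hhri(ri)["hhri"].rank()
        b = ensemble_hhri(shuffled)["hhri"].rank()
        pd.testing.assert_series_equal(a, b)

    def test_single_expert_ci_unavailable(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            out = ensemble_hhri(pd.DataFrame({0: [0.5]}))
        assert np.isnan(out.loc[0, "ci_low"])


def test_risk_table_assembles_all_columns():
    hazard = pd.Series([1.0, 0.0, 0.5, 0.2])
    exposure = pd.Series([0.8, 0.1, 0.0, 1.0])
    table = TestVulnerabilityIndex.TABLE
    sets = [TestVulnerabilityIndex.WS,
            WeightSet(1, (0.3, 0.4, 0.3), (0.5, 0.5), (0.4, 0.3, 0.3),
                      (0.2, 0.4, 0.4))]
    out = risk_table(hazard, exposure, table, sets)
    assert {"hazard", "exposure", "hhri", "ci_low", "ci_high",
            "category"} <= set(out.columns)
    assert {"ri_expert_0", "ri_expert_1"} <= set(out.columns)
    # indices lie in [0,1]; t-based CI bounds may legitimately extend beyond
    inner = out[[c for c in out.columns
                 if c not in ("category", "ci_low", "ci_high")]]
    assert ((inner >= -1e-9) & (inner <= 1 + 1e-9)).all().all()
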