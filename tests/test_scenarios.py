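"""Scenario operators, life tables and LE calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import healthmarkov as hm
from healthmarkov.scenarios import (
    ScenarioModel,
    ScenarioSpec,
    TargetUnreachableError,
    apply_compression,
    apply_dynamic,
    apply_expansion,
    compound_factor,
    initial_profile,
    scenario_catalog,
)

BASE_POOR = np.array([0.00, 0.04, 0.81, 0.15])


class TestCompoundFactor:
    @pytest.mark.parametrize(
        "x,year,expected",
        [(0.0, 2035, 1.0), (0.02, 2011, 0.98), (0.02, 2050, 0.98 ** 40)],
    )
    def test_values(self, x, year, expected):
        assert compound_factor(x, year) == pytest.approx(expected, rel=1e-12)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            compound_factor(1.0, 2020)
        with pytest.raises(ValueError):
            compound_factor(0.1, 2005)


class TestOperators:
    def test_expansion_conserves_mass_example(self):
        row = np.array([0.80, 0.10, 0.06, 0.04])
        out = apply_expansion(row, 0, 0.5)
        np.testing.assert_allclose(out, [0.82, 0.10, 0.06, 0.02], atol=1e-12)

    def test_expansion_identity(self, ref_row):
        np.testing.assert_allclose(apply_expansion(ref_row, 0, 1.0), ref_row)

    def test_expansion_poor_row_anchor(self):
        """Baseline poor row with a 0.6 survival multiplier: death 0.09,
        own state 0.87 (the printed scenario row 0.88/0.09 reflects rounding
        of the underlying multiplier)."""
        out = apply_expansion(BASE_POOR, 2, 0.6)
        assert out[3] == pytest.approx(0.09, abs=1e-12)
        assert out[2] == pytest.approx(0.87, abs=1e-12)

    def test_expansion_touches_only_death_and_diagonal(self, ref_row):
        out = apply_expansion(ref_row, 0, 0.7)
        assert out[1] == ref_row[1] and out[2] == ref_row[2]
        assert out.sum() == pytest.approx(1.0, abs=1e-15)

    def test_compression_good_row(self, ref_row):
        out = apply_compression(ref_row, 0, 0.5)
        np.testing.assert_allclose(out, [0.935, 0.035, 0.02, 0.01], atol=1e-12)

    def test_compression_poor_row_unchanged(self):
        out = apply_compression(BASE_POOR, 2, 0.5)
        np.testing.assert_array_equal(out, BASE_POOR)

    def test_compression_identity(self, ref_row):
        np.testing.assert_allclose(apply_compression(ref_row, 0, 1.0), ref_row)

    def test_dynamic_good_row_anchor(self, ref_row):
        out = apply_dynamic(ref_row, 0, 0.5, 1.0)
        np.testing.assert_allclose(out, [0.87, 0.10, 0.02, 0.01], atol=1e-12)

    def test_dynamic_poor_row_anchor(self):
        out = apply_dynamic(BASE_POOR, 2, 1.0, 0.8)
        np.testing.assert_allclose(out, [0.00, 0.04, 0.84, 0.12], atol=1e-12)

    def test_dynamic_identity(self, ref_row):
        np.testing.assert_allclose(apply_dynamic(ref_row, 0, 1.0, 1.0), ref_row)

    def test_non_stochastic_row_rejected(self):
        with pytest.raises(ValueError, match="stochastic"):
            apply_expansion(np.array([0.5, 0.2, 0.1, 0.1]), 0, 0.5)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        probs=st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
        mult=st.floats(0.05, 1.0),
        origin=st.integers(0, 2),
    )
    def test_operators_preserve_stochasticity(self, probs, mult, origin):
        row = np.asarray(probs) / np.sum(probs)
        for out in (
            apply_expansion(row, origin, mult),
            apply_compression(row, origin, mult),
            apply_dynamic(row, origin, mult, mult),
        ):
            assert abs(out.sum() - 1.0) < 1e-12
            assert np.all(out >= -1e-15)
            assert out[-1] <= row[-1] + 1e-15  # death never increases


class TestInitialProfile:
    def test_2010_returns_baseline(self, truth):
        base = hm.baseline_profile_at_65(truth, 0)
        for sid in ("baseline", "2+", "3++"):
            spec = scenario_catalog()[sid]
            np.testing.assert_allclose(initial_profile(spec, 2010, 0, base), base)

    def test_compression_ramp_reaches_full_good_health(self, truth):
        base = hm.baseline_profile_at_65(truth, 0)
        for sid in ("2+", "2++"):
            out = initial_profile(scenario_catalog()[sid], 2050, 0, base)
            assert out[0] == 1.0
            assert out[1] == 0.0 and out[2] == 0.0

    def test_dynamic_ramp_reaches_45_percent_moderate(self, truth):
        base = hm.baseline_profile_at_65(truth, 0)
        for sid in ("3+", "3++"):
            out = initial_profile(scenario_catalog()[sid], 2050, 0, base)
            assert out[1] == 0.45
            assert out.sum() == pytest.approx(1.0, abs=1e-12)
            # remaining mass split proportionally
            np.testing.assert_allclose(out[0] / out[2], base[0] / base[2], rtol=1e-9)

    def test_no_ramp_scenarios_unchanged(self, truth):
        base = hm.baseline_profile_at_65(truth, 1)
        for sid in ("1o", "1++", "2o", "3o"):
            np.testing.assert_allclose(
                initial_profile(scenario_catalog()[sid], 2040, 1, base), base
            )

    def test_unnormalised_profile_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            initial_profile(scenario_catalog()["2+"], 2030, 0, np.array([0.5, 0.3, 0.1]))


class TestScenarioModel:
    def test_2010_reproduces_baseline_exactly(self, truth, calibrated_specs):
        for sid, spec in calibrated_specs.items():
            model = ScenarioModel(truth, spec)
            P0 = model.baseline_matrix(0, 75)
            np.testing.assert_array_equal(model.transition_matrix(0, 75, 2010), P0)

    def test_baseline_scenario_constant_over_years(self, truth):
        model = ScenarioModel(truth, scenario_catalog()["baseline"])
        P0 = model.transition_matrix(1, 80, 2010)
        np.testing.assert_array_equal(model.transition_matrix(1, 80, 2045), P0)

    def test_rows_stochastic_everywhere(self, truth, calibrated_specs):
        for sid, spec in calibrated_specs.items():
            model = ScenarioModel(truth, spec)
            for year in (2010, 2030, 2050):
                for age in (65, 85, 105):
                    P = model.transition_matrix(0, age, year)
                    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
                    assert np.all(P >= -1e-15)
                    assert P[3, 3] == 1.0

    def test_expansion_death_probability_monotone_in_year(self, truth, calibrated_specs):
        model = ScenarioModel(truth, calibrated_specs["1o"])
        deaths = [model.transition_matrix(0, 75, y)[0, 3] for y in range(2010, 2051)]
        assert np.all(np.diff(deaths) < 0)


class TestLifeTable:
    def test_certain_death_half_year(self, truth):
        p = truth.copy()
        p.trans_coef[:, -1, 0] = 80.0
        model = ScenarioModel(p, scenario_catalog()["baseline"])
        lt = model.life_table(0, 2010)
        assert lt.total == pytest.approx(0.5, abs=1e-9)

    def test_no_mortality_reaches_cap(self, truth):
        p = truth.copy()
        for l in range(3):
            for m in range(4):
                if m != l:
                    p.trans_coef[l, m, :] = 0.0
                    p.trans_coef[l, m, 0] = -80.0
        model = ScenarioModel(p, scenario_catalog()["baseline"])
        lt = model.life_table(0, 2010)
        assert lt.total == pytest.approx(110 - 65, abs=1e-9)

    def test_fundamental_matrix_closed_form(self, truth):
        """A 3-living-state chain with age-invariant rows: the life table
        matches (I - Q)^-1 occupancy up to the half-year death credit."""
        p = truth.copy()
        p.trans_coef[:, :, 1:] = 0.0  # no covariate effects: constant rows
        model = ScenarioModel(p, scenario_catalog()["baseline"], age_cap=100000)
        # closed form with the same start profile
        x = p.covariates.trans_vector(0, 1, 75, 0)
        P = p.transition_matrix(x)
        Q = P[:3, :3]
        start = hm.baseline_profile_at_65(p, 0)
        N = np.linalg.inv(np.eye(3) - Q)
        occupancy = start @ N                       # expected person-years per state
        deaths_per_state = occupancy * P[:3, 3]     # each dying year counted half
        expected = occupancy - 0.5 * deaths_per_state
        model.age_cap = 65 + 2000  # effectively unbounded horizon
        lt = model.life_table(0, 2010)
        np.testing.assert_allclose(lt.by_state, expected, rtol=1e-9)

    def test_components_sum_to_total(self, truth, calibrated_specs):
        model = ScenarioModel(truth, calibrated_specs["3o"])
        lt = model.life_table(1, 2050)
        assert lt.by_state.sum() == pytest.approx(lt.total, rel=1e-12)
        assert np.all(lt.by_state >= 0)


class TestCalibration:
    def test_fixed_point_at_baseline_le(self, truth):
        base = ScenarioModel(truth, scenario_catalog()["baseline"]).life_table(0, 2050)
        spec = scenario_catalog()["1o"]
        spec.le_targets[0] = base.total
        out, rep = hm.calibrate(truth, spec, 0)
        assert out.rates[0] == pytest.approx(0.0, abs=1e-6)

    def test_expansion_reaches_baseline_plus_two_years(self, truth):
        base = ScenarioModel(truth, scenario_catalog()["baseline"]).life_table(0, 2050)
        spec = scenario_catalog()["1o"]
        spec.le_targets[0] = base.total + 2.0
        out, rep = hm.calibrate(truth, spec, 0)
        achieved = ScenarioModel(truth, out).life_table(0, 2050).total
        assert abs(achieved - (base.total + 2.0)) < 0.005

    def test_le_increasing_in_expansion_rate(self, truth):
        spec = scenario_catalog()["1o"]
        les = []
        for x in (0.0, 0.01, 0.02, 0.04, 0.08):
            s = ScenarioSpec("1o", "expansion", le_targets={0: 21.1}, rates={0: x})
            les.append(ScenarioModel(truth, s).life_table(0, 2050).total)
        assert np.all(np.diff(les) > 0)

    def test_dynamic_holds_poor_years(self, truth, calibrated_specs):
        base = ScenarioModel(truth, calibrated_specs["baseline"])
        for sid in ("3o", "3+", "3++"):
            model = ScenarioModel(truth, calibrated_specs[sid])
            for sex in (0, 1):
                b = base.life_table(sex, 2050).by_state[2]
                d = model.life_table(sex, 2050).by_state[2]
                assert abs(d - b) < 0.005

    def test_unreachable_target_reports_range(self, truth):
        spec = scenario_catalog()["1o"]
        spec.le_targets[0] = 5.0  # below the baseline LE
        with pytest.raises(TargetUnreachableError, match="below"):
            hm.calibrate(truth, spec, 0)

    def test_baseline_not_calibrated(self, truth):
        with pytest.raises(ValueError, match="baseline"):
            hm.calibrate(truth, scenario_catalog()["baseline"], 0)
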