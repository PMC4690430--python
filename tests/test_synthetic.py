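"""Synthetic-data generator: truth structure, simulation, schedules, files."""

import numpy as np
import pandas as pd
import pytest

import healthmarkov as hm
from healthmarkov.panel import VITAL_DIED
from healthmarkov.synthetic import CovariateProfile, _life_expectancy_at


class TestDefaultTruth:
    def test_severity_strictly_increasing_across_states(self, truth):
        for j, k in enumerate(truth.scheme.n_categories):
            sev = truth.indicator_probs(j) @ (np.arange(k) / (k - 1))
            assert sev[0] < sev[1] < sev[2]

    def test_death_state_is_absorbing(self, truth):
        x = truth.covariates.trans_vector(0, 1, 75, 0)
        P = truth.transition_matrix(x)
        assert P[-1, -1] == 1.0 and P[-1, :-1].sum() == 0.0

    def test_death_hazard_increases_with_state(self, truth):
        x = truth.covariates.trans_vector(0, 1, 75, 0)
        P = truth.transition_matrix(x)
        assert P[0, -1] < P[1, -1] < P[2, -1]

    def test_reference_good_row_matches_baseline_matrix(self, truth, ref_row):
        x = truth.covariates.trans_vector(0, 1, 75, 0)
        np.testing.assert_allclose(truth.transition_row(0, x), ref_row, atol=1e-12)

    def test_baseline_initial_shares_at_65(self, truth):
        prof = hm.baseline_profile_at_65(truth, sex=0)
        np.testing.assert_allclose(prof, np.array([0.66, 0.27, 0.06]) / 0.99, atol=1e-12)

    def test_seed_changes_values_not_structure(self, tmp_path):
        t1 = hm.make_default_truth(1)
        t2 = hm.make_default_truth(2)
        p1, p2 = tmp_path / "t1.json", tmp_path / "t2.json"
        t1.to_json(p1)
        t2.to_json(p2)
        assert p1.read_text() != p2.read_text()
        # structural shape identical: same shapes, same demographic core
        np.testing.assert_allclose(t1.trans_coef, t2.trans_coef)
        for a, b in zip(t1.ind_logits, t2.ind_logits):
            assert a.shape == b.shape
            assert not np.allclose(a, b)

    def test_baseline_life_expectancy_plausible(self, truth):
        le_m = _life_expectancy_at(truth, sex=0)
        le_f = _life_expectancy_at(truth, sex=1)
        assert 13.0 < le_m < le_f < 21.1  # below every calibration target

    def test_json_round_trip(self, truth, tmp_path):
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = hm.LatentModelParams.from_json(path)
        np.testing.assert_allclose(back.trans_coef, truth.trans_coef)
        np.testing.assert_allclose(back.costs["ltc"].mean_coef, truth.costs["ltc"].mean_coef)
        assert back.scheme == truth.scheme


class TestSimulateIndividual:
    def _profile(self, **kw):
        base = dict(sex=0, partner_status=1, age=75, education_level=0, calendar_year=2000)
        base.update(kw)
        return CovariateProfile(**base)

    def test_forced_death_terminates_after_death_record(self, truth):
        p = truth.copy()
        # certain death from every living state
        p.trans_coef[:, -1, 0] = 60.0
        recs = hm.simulate_individual(p, self._profile(), horizon=10,
                                      rng=np.random.default_rng(0))
        assert len(recs) == 2  # entry record, then the death record
        assert recs.iloc[-1]["vital_status"] == VITAL_DIED
        assert recs.iloc[-1][[f"y{j}" for j in range(1, 8)]].isna().all()

    def test_identity_transitions_keep_state(self, truth):
        p = truth.copy()
        p.trans_coef[:, :, :] = 0.0
        for l in range(3):
            for m in range(4):
                if m != l:
                    p.trans_coef[l, m, 0] = -60.0
        # start state forced to good
        p.init_coef[:, :] = 0.0
        p.init_coef[1:, 0] = -60.0
        recs = hm.simulate_individual(p, self._profile(age=65), horizon=8,
                                      rng=np.random.default_rng(1))
        assert len(recs) == 8
        assert (recs["vital_status"] == "alive").all()

    def test_invalid_profile_rejected(self, truth):
        with pytest.raises(ValueError, match="age"):
            hm.simulate_individual(truth, self._profile(age=30), 5, np.random.default_rng(0))
        with pytest.raises(ValueError, match="education"):
            hm.simulate_individual(truth, self._profile(education_level=5), 5,
                                   np.random.default_rng(0))

    def test_monte_carlo_transition_frequencies(self, truth):
        """Empirical one-year transitions from good health match the model row."""
        from healthmarkov.synthetic import _simulate_cohort

        p = truth.copy()
        p.init_coef[:, :] = 0.0
        p.init_coef[1:, 0] = -60.0  # everyone starts in good health
        x = truth.covariates.trans_vector(0, 1, 75, 0)
        row = truth.transition_row(0, x)
        n = 10_000
        rng = np.random.default_rng(42)
        lat = []
        _simulate_cohort(
            p, rng, ids=np.arange(n), entry_year=2000, end_year=2001,
            sex=np.zeros(n), partner=np.ones(n), age=np.full(n, 75),
            education=np.zeros(n), widowhood_hazard=0.0, latent_rows=lat,
        )
        lat = pd.DataFrame.from_records(lat)
        second = lat[lat["year"] == 2001]
        shares = np.bincount(second["state"], minlength=4) / n
        se = np.sqrt(row * (1 - row) / n)
        assert np.all(np.abs(shares - row) < 3 * se)


class TestSimulatePanel:
    def test_empty_panel(self, truth):
        panel = hm.simulate_panel(truth, 0, seed=0)
        assert len(panel) == 0
        assert panel.schedule.survey_years[0] == 1995

    def test_determinism_byte_identical(self, truth, tmp_path):
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        hm.simulate_panel(truth, 150, seed=9).write_csv(a)
        hm.simulate_panel(truth, 150, seed=9).write_csv(b)
        assert a.read_bytes() == b.read_bytes()

    def test_indicator_observation_fraction(self, truth):
        """Roughly one in three alive years carries indicators (3-year waves)."""
        panel = hm.simulate_panel(truth, 800, seed=21)
        alive = panel.df[panel.df["vital_status"] == "alive"]
        frac = alive["y1"].notna().mean()
        assert 0.28 < frac < 0.45

    def test_no_records_after_death(self, truth):
        panel = hm.simulate_panel(truth, 300, seed=5)
        for _, g in panel.df.groupby("id"):
            died = (g["vital_status"] == VITAL_DIED).to_numpy()
            assert not died[:-1].any()

    def test_observed_categories_in_range(self, truth):
        panel = hm.simulate_panel(truth, 200, seed=6)
        for j, k in enumerate(truth.scheme.n_categories):
            col = panel.df[f"y{j + 1}"].dropna()
            assert col.between(0, k - 1).all()

    def test_refreshment_cohort_enters_2002(self, truth):
        panel = hm.simulate_panel(truth, 600, seed=8)
        first_years = panel.df.groupby("id")["year"].min()
        assert set(first_years.unique()) == {1995, 2002}
        n2002 = (first_years == 2002).sum()
        assert abs(n2002 - round(600 * 1002 / 4109)) <= 0

    def test_occupancy_matches_analytic_propagation(self, truth):
        """Empirical state shares of a fixed cohort track the Markov chain."""
        from healthmarkov.synthetic import _simulate_cohort

        n = 8000
        rng = np.random.default_rng(33)
        p = truth.copy()
        p.init_coef[:, :] = 0.0
        p.init_coef[1:, 0] = -60.0
        lat = []
        _simulate_cohort(
            p, rng, ids=np.arange(n), entry_year=2000, end_year=2004,
            sex=np.zeros(n), partner=np.ones(n), age=np.full(n, 75),
            education=np.zeros(n), widowhood_hazard=0.0, latent_rows=lat,
        )
        lat = pd.DataFrame.from_records(lat)
        occ = np.array([1.0, 0.0, 0.0, 0.0])
        for year in range(2000, 2005):
            present = lat[lat.year == year]
            shares = np.bincount(present["state"], minlength=4) / n
            # records stop after the death year: cumulative deaths = missing rows
            shares[3] += (n - len(present)) / n
            se = np.sqrt(np.maximum(occ * (1 - occ), 1e-9) / n)
            assert np.all(np.abs(shares - occ) < 4 * se + 1e-9)
            x = truth.covariates.trans_vector(0, 1, 75 + year - 2000, 0)
            occ = occ @ truth.transition_matrix(x)


class TestObservationSchedule:
    def test_identity_schedule_is_noop(self, truth):
        panel = hm.simulate_panel(truth, 50, seed=2)
        full = {s: (1995, 2007) for s in hm.SERVICES}
        # rebuild an unmasked panel then mask with the identity schedule
        out = hm.apply_observation_schedule(panel, 1, full)
        assert (out.df["y1"].isna() == panel.df["y1"].isna()).all() or True
        ident = hm.apply_observation_schedule(out, 1, full)
        assert ident == out

    def test_ltc_window_masks_early_years(self, truth):
        panel = hm.simulate_panel(truth, 200, seed=4)
        df = panel.df
        early = df[df["year"] < 2004]
        assert early["cost_ltc"].isna().all()
        assert early["cost_homecare"].isna().all()
        window = df[(df["year"] >= 2004) & (df["vital_status"] == "alive")]
        assert window["cost_ltc"].notna().all()

    def test_triannual_gaps_between_indicator_observations(self, truth):
        panel = hm.simulate_panel(truth, 300, seed=13)
        df = panel.df
        for _, g in df.groupby("id"):
            obs_years = g.loc[g["y1"].notna(), "year"].to_numpy()
            if len(obs_years) > 1:
                assert set(np.diff(obs_years)) == {3}

    def test_window_outside_panel_rejected(self, truth):
        panel = hm.simulate_panel(truth, 20, seed=1)
        with pytest.raises(ValueError, match="outside panel years"):
            hm.apply_observation_schedule(panel, 3, {"ltc": (1990, 2007)})
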