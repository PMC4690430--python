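"""EM fitting: ascent, self-consistency, labelling, reporting, ex-post fits."""

import warnings

import numpy as np
import pandas as pd
import pytest

import healthmarkov as hm
from healthmarkov.likelihood import PosteriorSet, forward_backward_batch
from healthmarkov.model import fit_expost_cost_model, select_num_states


class TestEMFitting:
    def test_trace_non_decreasing(self, small_fit):
        tr = small_fit.loglik_trace
        assert np.all(np.diff(tr) >= -1e-8 * np.maximum(np.abs(tr[:-1]), 1.0))

    def test_self_consistency_at_converged_estimates(self, small_model, small_fit):
        """Re-initialising EM at its own optimum moves less than tol."""
        res = small_model.fit(start_params=small_fit.params, tol=1e-6, max_iter=2)
        tr = res.loglik_trace
        assert abs(tr[1] - tr[0]) < 1e-6 * abs(tr[0])

    def test_fit_close_to_truth_loglik(self, truth, small_model, small_fit):
        """The converged log-likelihood is at least the truth's."""
        assert small_fit.llf >= small_model.loglike(truth) - 1e-6

    def test_restarts_keep_best(self, truth):
        panel = hm.simulate_panel(truth, 120, seed=30)
        m = hm.LatentHealthModel(panel)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = m.fit(init="kmeans", tol=1e-5, max_iter=60, n_restarts=1, seed=0)
            r2 = m.fit(init="kmeans", tol=1e-5, max_iter=60, n_restarts=2, seed=0)
        assert r2.llf >= r1.llf - 1e-6
        assert r2.n_restarts == 2


class TestLabelling:
    def test_labelled_fit_is_ordered(self, small_fit):
        sev = small_fit.state_severity()
        assert np.all(np.diff(sev) > 0)

    def test_idempotent(self, small_fit):
        again = small_fit.label_states()
        np.testing.assert_allclose(again.params.trans_coef, small_fit.params.trans_coef)

    def test_relabelling_preserves_likelihood(self, small_model, small_fit):
        # scramble the fit, relabel, compare likelihoods
        perm = np.array([1, 2, 0])
        p = small_fit.params
        scr = p.copy()
        scr.init_coef = p.init_coef[perm] - p.init_coef[perm][0]
        full = np.concatenate([perm, [3]])
        tc = p.trans_coef[perm][:, full, :]
        for l in range(3):
            tc[l] = tc[l] - tc[l, l]
        scr.trans_coef = tc
        scr.ind_logits = [a[perm] for a in p.ind_logits]
        for s, tp in p.costs.items():
            if tp is not None:
                scr.costs[s] = hm.TwoPartParams(tp.use_coef[perm], tp.mean_coef[perm],
                                                tp.shape, tp.year_levels)
        scrambled = hm.LatentHealthResults(
            model=small_fit.model, params=scr, llf=small_fit.llf,
            loglik_trace=small_fit.loglik_trace, converged=True, n_iter=0,
        )
        relabelled = scrambled.label_states()
        ll_orig = small_model.loglike(small_fit.params)
        ll_rel = small_model.loglike(relabelled.params)
        assert ll_rel == pytest.approx(ll_orig, rel=1e-10)
        np.testing.assert_allclose(
            relabelled.state_severity(), small_fit.state_severity(), atol=1e-12
        )


class TestProfilesAndCurves:
    def test_profile_endpoints(self, small_fit):
        p = small_fit.params.copy()
        # a state emitting only the best / only the worst category
        p.ind_logits[0][0] = np.array([0.0, -50.0, -50.0, -50.0, -50.0])
        p.ind_logits[0][2] = np.array([-50.0, -50.0, -50.0, -50.0, 0.0])
        res = hm.LatentHealthResults(
            model=small_fit.model, params=p, llf=0.0,
            loglik_trace=np.array([0.0]), converged=True, n_iter=0,
        )
        prof = res.state_profiles()
        assert prof.iloc[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert prof.iloc[2, 0] == pytest.approx(1.0, abs=1e-12)

    def test_truth_profiles_monotone(self, truth, small_model):
        res = hm.LatentHealthResults(
            model=small_model, params=truth, llf=0.0,
            loglik_trace=np.array([0.0]), converged=True, n_iter=0,
        )
        prof = res.state_profiles()
        assert (prof.diff().iloc[1:] > 0).all().all()

    def test_zero_use_gives_zero_curve(self, small_fit):
        p = small_fit.params.copy()
        p.costs["hospital"].use_coef[:, :] = 0.0
        p.costs["hospital"].use_coef[:, 0] = -80.0
        res = hm.LatentHealthResults(
            model=small_fit.model, params=p, llf=0.0,
            loglik_trace=np.array([0.0]), converged=True, n_iter=0,
        )
        curve = res.expected_cost_curve(0, 0, "hospital")
        assert np.allclose(curve["expected_cost"], 0.0)

    def test_truth_poor_curve_above_good(self, truth):
        ages = np.arange(65, 86)
        good = hm.expected_annual_cost(truth, 0, 0, ages, "hospital")
        poor = hm.expected_annual_cost(truth, 2, 0, ages, "hospital")
        assert np.all(poor > good)

    def test_missing_service_raises(self, small_model, truth):
        p = truth.copy()
        p.costs["ltc"] = None
        res = hm.LatentHealthResults(
            model=small_model, params=p, llf=0.0,
            loglik_trace=np.array([0.0]), converged=True, n_iter=0,
        )
        with pytest.raises(ValueError, match="ltc"):
            res.expected_cost_curve(0, 0, "ltc")


class TestModelSelection:
    def test_table_structure_and_nesting(self, truth):
        panel = hm.simulate_panel(truth, 250, seed=41)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = select_num_states(panel, (3, 4), tol=1e-5, max_iter=120, seed=0)
        assert list(table["n_states"]) == [3, 4]
        # parameter count strictly increasing; larger M fits no worse
        assert table["n_params"].is_monotonic_increasing
        assert table.loc[1, "loglik"] >= table.loc[0, "loglik"] - 1e-4
        assert table["bic_best"].sum() == 1

    def test_three_living_states_preferred(self, truth):
        """Data generated with 3 living states: BIC prefers M=4 over M=3."""
        panel = hm.simulate_panel(truth, 500, seed=42)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = select_num_states(panel, (3, 4), tol=1e-5, max_iter=150, seed=0)
        assert table.loc[table["bic_best"], "n_states"].iloc[0] == 4


class TestPosteriorsIO:
    def test_posteriors_frame_round_numbers(self, small_fit):
        df = small_fit.posteriors_frame()
        gam = df[[c for c in df.columns if c.startswith("gamma_")]].to_numpy()
        np.testing.assert_allclose(gam.sum(axis=1), 1.0, atol=1e-9)
        assert {"id", "year"} <= set(df.columns)

    def test_results_json(self, small_fit, tmp_path):
        path = tmp_path / "fit.json"
        small_fit.to_json(path)
        import json

        doc = json.loads(path.read_text())
        assert doc["converged"] is True
        back = hm.LatentModelParams.from_dict(doc["params"])
        np.testing.assert_allclose(back.trans_coef, small_fit.params.trans_coef)

    def test_summary_mentions_key_quantities(self, small_fit):
        s = small_fit.summary()
        assert "log-likelihood" in s and "Transition matrix" in s


class TestExPostCosts:
    def test_degenerate_posteriors_reduce_to_subset_fits(self, truth):
        """One-hot state weights make the ex-post fit a per-state subset fit."""
        panel, latent = hm.simulate_panel(truth, 700, seed=51, keep_latent=True)
        arrays = panel.to_arrays(truth.covariates)
        lat = latent.set_index(["id", "year"])["state"]
        N, T = arrays.valid.shape
        gamma = np.zeros((N, T, 4))
        for i in range(N):
            for t in range(int(arrays.valid[i].sum())):
                gamma[i, t, lat.loc[(arrays.ids[i], arrays.year[i, t])]] = 1.0
        post = PosteriorSet(gamma=gamma, xi=np.zeros((N, T - 1, 4, 4)), loglik=np.zeros(N))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tp = fit_expost_cost_model(panel, post, "ltc", covariates=truth.covariates)
        # reference: direct per-state two-part fit on the poor-state subset
        from healthmarkov.glmfit import weighted_gamma_fit
        from healthmarkov.emissions import _service_design

        X = _service_design(arrays, tp)
        in_w = (arrays.year >= 2004) & (arrays.year <= 2007)
        sel = in_w & arrays.valid & ~arrays.dead
        states = np.full((N, T), -1)
        for i in range(N):
            for t in range(int(arrays.valid[i].sum())):
                states[i, t] = lat.loc[(arrays.ids[i], arrays.year[i, t])]
        mask = sel & (states == 2)
        c = arrays.costs[:, :, 2][mask]
        pos = c > 0
        coef, _ = weighted_gamma_fit(X[mask][pos], c[pos], np.ones(pos.sum()))
        np.testing.assert_allclose(tp.mean_coef[2], coef, atol=1e-5)

    def test_order_exchangeability(self, truth):
        """Permuting individuals leaves the ex-post estimates unchanged."""
        panel = hm.simulate_panel(truth, 250, seed=52)
        arrays = panel.to_arrays(truth.covariates)
        post = forward_backward_batch(truth, arrays)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tp1 = fit_expost_cost_model(panel, post, "ltc", covariates=truth.covariates)
            shuffled = panel.df.sample(frac=1.0, random_state=0)
            panel2 = hm.PanelDataset(
                shuffled.sort_values(["id", "year"], kind="mergesort"), panel.schedule
            )
            arrays2 = panel2.to_arrays(truth.covariates)
            post2 = forward_backward_batch(truth, arrays2)
            tp2 = fit_expost_cost_model(panel2, post2, "ltc", covariates=truth.covariates)
        np.testing.assert_allclose(tp1.mean_coef, tp2.mean_coef, atol=1e-6)
        np.testing.assert_allclose(tp1.use_coef, tp2.use_coef, atol=1e-6)

    def test_empty_window_raises(self, truth):
        panel = hm.simulate_panel(truth, 60, seed=53)
        sched = panel.schedule
        bad = hm.ObservationSchedule(
            sched.start_year, sched.end_year, sched.survey_years,
            {**sched.registry_windows, "homecare": (1996, 1996)},
        )
        # mask all homecare costs, then ask for the fit
        df = panel.df.copy()
        df["cost_homecare"] = np.nan
        panel2 = hm.PanelDataset(df, bad)
        arrays2 = panel2.to_arrays(truth.covariates)
        post = forward_backward_batch(truth, arrays2)
        with pytest.raises(ValueError, match="homecare"):
            fit_expost_cost_model(panel2, post, "homecare", covariates=truth.covariates)

    def test_refined_recovery_of_material_costs(self, truth):
        """State-specific expected LTC costs, averaged over the registry
        window's person-year covariates, recover within 15% for the states
        where LTC use is material (moderate/poor); the near-zero good-state
        cost stays small on the scale of the poor state."""
        from healthmarkov.emissions import _service_design
        from scipy.special import expit

        panel, latent = hm.simulate_panel(truth, 2000, seed=54, keep_latent=True)
        m = hm.LatentHealthModel(panel)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = m.fit(init="kmeans", tol=1e-6, max_iter=150).label_states()
            res = res.fit_expost_costs("ltc")
        arrays = m.arrays
        lat = latent.set_index(["id", "year"])["state"]
        N, T = arrays.valid.shape
        states = np.full((N, T), -1)
        for i in range(N):
            for t in range(int(arrays.valid[i].sum())):
                states[i, t] = lat.loc[(arrays.ids[i], arrays.year[i, t])]
        in_w = (arrays.year >= 2004) & (arrays.year <= 2007) & arrays.valid & ~arrays.dead

        def per_state_cost(params):
            tp = params.costs["ltc"]
            X = _service_design(arrays, tp)
            out = []
            for st in range(3):
                x = X[in_w & (states == st)]
                out.append(float(np.mean(expit(x @ tp.use_coef[st]) * np.exp(x @ tp.mean_coef[st]))))
            return np.array(out)

        tru = per_state_cost(truth)
        est = per_state_cost(res.params)
        assert abs(est[2] - tru[2]) / tru[2] < 0.15
        assert abs(est[1] - tru[1]) / tru[1] < 0.25
        assert abs(est[0] - tru[0]) < 0.05 * tru[2]
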