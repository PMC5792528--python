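"""Cox partial-likelihood machinery: oracle agreement, truncation, averaging."""

import numpy as np
import pandas as pd
import pytest

import socbond as sb
from socbond import survival, _cox
from socbond.survival import standardize, model_average, quadratic_group_size_model


def _simulated(n=400, beta=(0.5, -0.8, 0.3), rate=0.3, seed=0, round_to=None):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, len(beta)))
    entry = rng.uniform(0, 2, n)
    t = entry + rng.exponential(1.0 / (rate * np.exp(x @ np.asarray(beta))))
    cens = entry + rng.uniform(0.5, 6, n)
    stop = np.minimum(t, cens)
    if round_to is not None:
        stop = np.maximum(np.round(stop, round_to), entry + 1e-6)
    return entry, stop, (t <= cens).astype(int), x


class TestSolverAgainstLifelines:
    """Dual-route check: the in-house Newton solver against lifelines."""

    def test_left_truncated_fit_matches_coxphfitter(self):
        from lifelines import CoxPHFitter

        entry, stop, event, x = _simulated()
        fit = _cox.cox_fit(entry, stop, event, x)
        df = pd.DataFrame(x, columns=["a", "b", "c"])
        df["stop"], df["event"], df["entry"] = stop, event, entry
        ref = CoxPHFitter().fit(df, duration_col="stop", event_col="event",
                                entry_col="entry")
        assert np.allclose(fit.beta, ref.params_.to_numpy(), atol=1e-4)
        assert np.allclose(np.sqrt(np.diag(fit.cov)),
                           ref.standard_errors_.to_numpy(), atol=1e-4)
        assert fit.loglik == pytest.approx(ref.log_likelihood_, abs=1e-5)

    def test_efron_tie_handling_matches_lifelines(self):
        from lifelines import CoxPHFitter

        entry, stop, event, x = _simulated(round_to=1)
        fit = _cox.cox_fit(entry, stop, event, x)
        df = pd.DataFrame(x, columns=["a", "b", "c"])
        df["stop"], df["event"], df["entry"] = stop, event, entry
        ref = CoxPHFitter().fit(df, duration_col="stop", event_col="event",
                                entry_col="entry")
        assert np.allclose(fit.beta, ref.params_.to_numpy(), atol=1e-4)
        assert fit.loglik == pytest.approx(ref.log_likelihood_, abs=1e-5)

    def test_counting_process_fit_matches_timevarying_fitter(self):
        from lifelines import CoxTimeVaryingFitter

        entry, stop, event, x = _simulated(n=200, seed=3)
        # split each spell into two intervals with identical covariates
        mid = (entry + stop) / 2
        rows = []
        for i in range(len(stop)):
            rows.append((i, entry[i], mid[i], 0, *x[i]))
            rows.append((i, mid[i], stop[i], event[i], *x[i]))
        df = pd.DataFrame(rows, columns=["id", "start", "stop", "event", "a", "b", "c"])
        fit = _cox.cox_fit(df.start.to_numpy(), df.stop.to_numpy(),
                           df.event.to_numpy(), df[["a", "b", "c"]].to_numpy())
        ref = CoxTimeVaryingFitter().fit(df, id_col="id", start_col="start",
                                         stop_col="stop", event_col="event")
        assert np.allclose(fit.beta, ref.params_.to_numpy(), atol=1e-4)


class TestRiskSetCorrectness:
    def test_interval_splitting_leaves_fit_unchanged(self):
        entry, stop, event, x = _simulated(n=150, seed=5)
        whole = _cox.cox_fit(entry, stop, event, x)
        mid = (entry + stop) / 2
        e2 = np.concatenate([entry, mid])
        s2 = np.concatenate([mid, stop])
        ev2 = np.concatenate([np.zeros_like(event), event])
        x2 = np.vstack([x, x])
        split = _cox.cox_fit(e2, s2, ev2, x2)
        assert np.allclose(whole.beta, split.beta, atol=1e-8)

    def test_event_free_pre_entry_exposure_leaves_fit_unchanged(self):
        """Extra at-risk intervals placed strictly before the earliest event
        change no risk set, so coefficients are invariant to 1e-8."""
        entry, stop, event, x = _simulated(n=150, seed=6)
        base = _cox.cox_fit(entry, stop, event, x)
        t_min = stop[event == 1].min()
        add = entry > t_min  # give some subjects exposure before any event
        e2 = np.concatenate([entry, np.full(add.sum(), t_min - 1.5)])
        s2 = np.concatenate([stop, np.full(add.sum(), t_min - 0.5)])
        ev2 = np.concatenate([event, np.zeros(add.sum(), dtype=int)])
        x2 = np.vstack([x, x[add]])
        aug = _cox.cox_fit(e2, s2, ev2, x2)
        assert np.allclose(base.beta, aug.beta, atol=1e-8)

    def test_single_interval_per_subject_equals_fixed_fit(self):
        rng = np.random.default_rng(11)
        rec = sb.simulate_survival(300, sb.GeneratorParams(), rng=rng)
        rec["cov"] = rng.normal(size=len(rec))
        fixed = survival.fit_cox_fixed(rec, covariates=["cov"],
                                       class_col="latent_class", reference=3)
        td = rec.rename(columns={"entry_age": "start_age", "exit_age": "stop_age"})
        tv = survival.fit_cox_timedep(td, covariates=["cov"],
                                      class_col="latent_class", reference=3)
        assert np.allclose(fixed.params.to_numpy(), tv.params.to_numpy(), atol=1e-8)


class TestResultContracts:
    def test_hazard_ratio_and_ci_identities(self):
        rng = np.random.default_rng(1)
        rec = sb.simulate_survival(400, sb.GeneratorParams(), rng=rng)
        res = survival.fit_cox_fixed(rec, covariates=(),
                                     class_col="latent_class", reference=3)
        assert np.allclose(res.hazard_ratios, np.exp(res.params))
        ci = res.conf_int()
        assert np.allclose(ci["lower"], res.params - 1.96 * res.bse)
        assert np.allclose(ci["upper"], res.params + 1.96 * res.bse)
        sig = (ci["lower"] > 0) | (ci["upper"] < 0)
        assert (res.significant == sig).all()

    def test_all_censored_is_an_error(self):
        df = pd.DataFrame(
            {"entry_age": [1.0, 2.0], "exit_age": [3.0, 4.0], "event": [0, 0],
             "cov": [0.1, 0.5]}
        )
        with pytest.raises(ValueError, match="no events"):
            survival.fit_cox_fixed(df, covariates=["cov"], class_col=None)

    def test_complete_separation_raises(self):
        df = pd.DataFrame(
            {
                "entry_age": np.zeros(20),
                "exit_age": np.concatenate([np.arange(1, 11), np.arange(20, 30)]),
                "event": np.concatenate([np.ones(10), np.zeros(10)]).astype(int),
                "cov": np.concatenate([np.ones(10), np.zeros(10)]),
            }
        )
        with pytest.raises(survival.SeparationError):
            survival.fit_cox_fixed(df, covariates=["cov"], class_col=None,
                                   standardize_cols=[])

    def test_overlapping_intervals_rejected_naming_subject(self):
        df = pd.DataFrame(
            {
                "female_id": ["F1", "F1", "F2"],
                "start_age": [1.0, 1.5, 1.0],
                "stop_age": [2.0, 2.5, 2.0],
                "event": [0, 1, 0],
                "cov": [0.0, 1.0, 0.5],
            }
        )
        with pytest.raises(ValueError, match="F1"):
            survival.fit_cox_timedep(df, covariates=["cov"], class_col=None)


class TestStandardize:
    def test_zero_mean_unit_sd(self):
        z = standardize(np.random.default_rng(0).normal(3, 5, 100), "v")
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_location_scale_invariance(self):
        x = np.random.default_rng(1).normal(size=50)
        assert np.allclose(standardize(x, "v"), standardize(4 * x + 7, "v"))

    def test_two_point_covariate_symmetric(self):
        z = standardize(np.array([0.0, 0.0, 1.0, 1.0]), "v")
        assert np.allclose(sorted(set(np.round(z, 12))), [-np.sqrt(3) / 2, np.sqrt(3) / 2])

    def test_zero_variance_names_covariate(self):
        with pytest.raises(ValueError, match="flat_cov"):
            standardize(np.ones(10), "flat_cov")


class TestModelAverage:
    def _two_fits(self):
        rng = np.random.default_rng(4)
        rec = sb.simulate_survival(500, sb.GeneratorParams(), rng=rng)
        rec["c1"] = rng.normal(size=len(rec))
        rec["c2"] = rng.normal(size=len(rec))
        a = survival.fit_cox_fixed(rec, covariates=["c1"],
                                   class_col="latent_class", reference=3)
        b = survival.fit_cox_fixed(rec, covariates=["c2"],
                                   class_col="latent_class", reference=3)
        return a, b

    def test_weights_follow_aicc_differences(self):
        a, b = self._two_fits()
        avg = model_average(a, b)
        w = avg.attrs["akaike_weights"]
        delta = np.array([a.aicc, b.aicc]) - min(a.aicc, b.aicc)
        expect = np.exp(-delta / 2) / np.exp(-delta / 2).sum()
        assert np.allclose(w, expect)
        # equal-evidence special case: delta = 0 -> equal weights, plain mean
        avg_same = model_average(a, a)
        assert np.allclose(avg_same.attrs["akaike_weights"], [0.5, 0.5])
        shared = [t for t in a.names]
        assert np.allclose(avg_same.loc[shared, "coef"], a.params[shared])

    def test_delta_aicc_of_two_gives_known_weights(self):
        # w1 = 1 / (1 + exp(-1)) when AICc differs by exactly 2
        w1 = 1 / (1 + np.exp(-1.0))
        delta = np.array([0.0, 2.0])
        w = np.exp(-delta / 2) / np.exp(-delta / 2).sum()
        assert w[0] == pytest.approx(w1, abs=1e-12)
        assert w[0] == pytest.approx(0.731, abs=5e-4)

    def test_unconditional_se_exceeds_within_model_se_when_models_disagree(self):
        a, b = self._two_fits()
        avg = model_average(a, b)
        term = "latent_class[4]"
        assert avg.loc[term, "se(coef)"] >= min(a.bse[term], b.bse[term]) - 1e-12
        assert avg.loc[term, "hazard_ratio"] == pytest.approx(
            np.exp(avg.loc[term, "coef"])
        )

    def test_mismatched_event_sets_rejected(self):
        a, _ = self._two_fits()
        rng = np.random.default_rng(9)
        rec = sb.simulate_survival(200, sb.GeneratorParams(), rng=rng)
        c = survival.fit_cox_fixed(rec, covariates=(),
                                   class_col="latent_class", reference=3)
        with pytest.raises(ValueError):
            model_average(a, c)


class TestProportionalHazardsCheck:
    def test_matches_r_survival_cox_zph(self):
        """Frozen oracle: R survival::cox.zph (v3.8-3, transform='km') on the
        same simulated data; the average-information approximation agrees
        with R's exact solve to within a few percent."""
        rng = np.random.default_rng(42)
        n = 250
        x = rng.normal(size=(n, 2))
        entry = rng.uniform(0, 1, n)
        t = entry + rng.exponential(1 / (0.4 * np.exp(x @ [0.6, -0.4])))
        stop = np.minimum(t, entry + 5)
        event = (t <= entry + 5).astype(int)
        fit = _cox.cox_fit(entry, stop, event, x)
        assert np.allclose(fit.beta, [0.5849224, -0.2805652], atol=1e-4)
        z = _cox.zph_test(fit, "km")
        r_chi = np.array([5.017255, 6.525874])      # R per-term chisq
        r_global = 9.813443                          # R global chisq, df=2
        assert np.all(np.abs(z["term_chi2"] - r_chi) / r_chi < 0.15)
        assert abs(z["global_chi2"] - r_global) / r_global < 0.10
        assert z["df"] == 2

    def test_single_covariate_global_equals_per_term(self):
        entry, stop, event, x = _simulated(n=200, beta=(0.5,), seed=8)
        fit = _cox.cox_fit(entry, stop, event, x)
        z = _cox.zph_test(fit)
        assert z["global_chi2"] == pytest.approx(z["term_chi2"][0])

    def test_too_few_events_rejected(self):
        entry = np.array([0.0, 0.0, 0.0])
        stop = np.array([1.0, 2.0, 3.0])
        event = np.array([1, 0, 0])
        fit = _cox.cox_fit(entry, stop, event, np.array([[0.2], [0.1], [0.3]]))
        with pytest.raises(ValueError):
            _cox.zph_test(fit)

    def test_false_positive_rate_near_nominal_under_proportional_hazards(self):
        rng = np.random.default_rng(13)
        reject = 0
        n_rep = 60
        for rep in range(n_rep):
            x = rng.normal(size=(250, 2))
            entry = rng.uniform(0, 1, 250)
            t = entry + rng.exponential(1 / (0.4 * np.exp(x @ [0.5, -0.5])))
            stop = np.minimum(t, entry + 4)
            event = (t <= entry + 4).astype(int)
            fit = _cox.cox_fit(entry, stop, event, x)
            reject += _cox.zph_test(fit)["global_p"] < 0.05
        assert reject / n_rep < 0.15

    def test_detects_strongly_time_varying_effect(self):
        """A covariate whose effect reverses with age should trip the
        per-term Schoenfeld test."""
        rng = np.random.default_rng(14)
        n = 500
        x = rng.normal(size=(n, 1))
        entry = np.zeros(n)
        # piecewise hazard: effect +1 before t=1, -1 after
        stop, event = [], []
        for xi in x[:, 0]:
            t1 = rng.exponential(1 / (0.5 * np.exp(+1.2 * xi)))
            if t1 < 1.0:
                stop.append(t1); event.append(1)
                continue
            t2 = 1.0 + rng.exponential(1 / (0.5 * np.exp(-1.2 * xi)))
            stop.append(min(t2, 4.0)); event.append(int(t2 < 4.0))
        fit = _cox.cox_fit(entry, np.array(stop), np.array(event), x)
        z = _cox.zph_test(fit)
        assert z["term_p"][0] < 0.01


class TestCoverageAndRecovery:
    def test_null_coefficient_within_two_se_at_nominal_rate(self):
        rng = np.random.default_rng(7)
        p = sb.GeneratorParams(class_log_hr={1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0},
                               baseline_hazard=0.1)
        inside = 0
        n_rep = 200
        for _ in range(n_rep):
            rec = sb.simulate_survival(300, p, rng=rng, class_probs=(0.5, 0, 0.5, 0))
            res = survival.fit_cox_fixed(rec, covariates=(),
                                         class_col="latent_class", reference=3)
            inside += abs(res.params.iloc[0]) <= 2 * res.bse.iloc[0]
        assert 0.93 <= inside / n_rep <= 0.99

    def test_quadratic_group_size_recovery_and_null_calibration(self):
        rng = np.random.default_rng(15)
        n = 800
        g = rng.uniform(3, 21, n)
        gz = (g - g.mean()) / g.std(ddof=1)
        entry = rng.uniform(7, 15, n)
        # hazard lowest at intermediate size: positive quadratic log-hazard
        lam = 0.08 * np.exp(0.8 * gz**2)
        t = entry + rng.exponential(1 / lam)
        rec = pd.DataFrame(
            {
                "entry_age": entry,
                "exit_age": np.minimum(t, entry + 8),
                "event": (t < entry + 8).astype(int),
                "mean_groupmates": g,
                "age_first_birth": rng.normal(7.2, 0.7, n),
            }
        )
        res = quadratic_group_size_model(rec, class_col=None)
        b = res.params["group_size_z2"]
        assert b > 0
        assert res.conf_int().loc["group_size_z2", "lower"] > 0
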