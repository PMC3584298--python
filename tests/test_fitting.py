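"""Simultaneous curve fitting, rr fitting, goodness of fit, lifetimes."""

import numpy as np
import pandas as pd
import pytest

import memchain as mc


def make_two_group_dataset(params, lam, times, trials=None, seed=None):
    """Exact (or binomially sampled) control + lesioned retention dataset."""
    lesion = mc.pathology_profile("korsakoff", lam=lam)
    rows = []
    rng = np.random.default_rng(seed) if seed is not None else None
    for grp, p in (("control", np.asarray(mc.recall_probability(params, times))),
                   ("lesioned", mc.ribot_gradient(params, lesion, times))):
        for t, pp in zip(times, p):
            row = {"group": grp, "time": float(t)}
            if trials is None:
                row["proportion"] = pp
            else:
                row["successes"] = int(rng.binomial(trials, pp))
                row["trials"] = trials
            rows.append(row)
    return mc.RetentionDataset(pd.DataFrame(rows))


CHO = dict(mu1=1.50, a1=0.103, mu2=0.00325)
CHO_TIMES = np.geomspace(3.5, 56, 4)


def cho_spec(**kw):
    return mc.two_store_spec(lesions={"lesioned": {"lam1": mc.ParamSpec.fixed(1.0)}},
                             **kw)


class TestFit:
    def test_noiseless_self_consistency(self):
        truth = mc.two_store(**CHO)
        ds = make_two_group_dataset(truth, 1.0, CHO_TIMES)
        res = mc.fit(ds, cho_spec(multistart=16))
        for name, val in CHO.items():
            assert res.params[name] == pytest.approx(val, rel=1e-4)
        assert res.sse == pytest.approx(0.0, abs=1e-12)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert res.success

    def test_partial_lesion_recovery(self):
        truth = mc.two_store(2.0, 0.3, 0.1)
        times = np.array([0.5, 2.0, 5.0, 10.0, 20.0])
        ds = make_two_group_dataset(truth, 0.6, times)
        spec = mc.two_store_spec(
            lesions={"lesioned": {"lam1": mc.ParamSpec.free(0.0, 1.0)}},
            multistart=16)
        res = mc.fit(ds, spec)
        assert res.params["lesioned:lam1"] == pytest.approx(0.6, abs=1e-4)
        assert res.params["a1"] == pytest.approx(0.3, rel=1e-3)

    def test_deterministic_given_seed(self):
        truth = mc.two_store(**CHO)
        ds = make_two_group_dataset(truth, 1.0, CHO_TIMES, trials=30, seed=7)
        r1 = mc.fit(ds, cho_spec(multistart=8, seed=11))
        r2 = mc.fit(ds, cho_spec(multistart=8, seed=11))
        assert r1.params == r2.params
        assert r1.sse == r2.sse

    def test_flat_data_flagged_as_degenerate(self):
        # no temporal signal: the perfect fit is the degenerate balanced ridge
        # mu2 = a1 (consolidation exactly offsets decline), flagged as such
        ds = mc.RetentionDataset(pd.DataFrame({
            "group": "only", "time": [1.0, 5.0, 10.0, 20.0], "proportion": 0.5}))
        spec = mc.two_store_spec(free=("mu1", "mu2"), fixed={"a1": 0.3, "a2": 0.0})
        with pytest.warns(UserWarning, match="signal"):
            res = mc.fit(ds, spec)
        assert "degenerate" in res.message
        assert res.sse == pytest.approx(0.0, abs=1e-10)
        assert res.params["mu2"] == pytest.approx(0.3, abs=1e-4)
        assert res.params["mu1"] == pytest.approx(-np.log(0.5), rel=1e-3)

    def test_under_identified_rejected(self):
        ds = mc.RetentionDataset(pd.DataFrame({
            "group": "only", "time": [1.0, 5.0], "proportion": [0.7, 0.5]}))
        spec = mc.two_store_spec(free=("mu1", "a1", "mu2"))
        with pytest.raises(ValueError, match="under-identified"):
            mc.fit(ds, spec)

    def test_binomial_loss_needs_counts(self):
        ds = mc.RetentionDataset(pd.DataFrame({
            "group": "only", "time": [1.0, 3.0, 5.0, 9.0],
            "proportion": [0.8, 0.6, 0.5, 0.4]}))
        spec = mc.two_store_spec(free=("mu1", "a1"), fixed={"mu2": 0.0},
                                 loss="binom")
        with pytest.raises(ValueError, match="counts"):
            mc.fit(ds, spec)

    def test_binomial_loss_recovers_parameters(self):
        truth = mc.two_store(**CHO)
        ds = make_two_group_dataset(truth, 1.0, CHO_TIMES, trials=2000, seed=3)
        res = mc.fit(ds, cho_spec(loss="binom", multistart=8))
        assert res.params["a1"] == pytest.approx(CHO["a1"], rel=0.15)
        assert res.params["mu1"] == pytest.approx(CHO["mu1"], rel=0.15)

    def test_extra_free_parameter_never_hurts(self):
        truth = mc.two_store(2.0, 0.3, 0.1)
        times = np.array([0.5, 2.0, 5.0, 10.0, 20.0])
        ds = make_two_group_dataset(truth, 0.6, times, trials=40, seed=5)
        fixed = mc.two_store_spec(
            lesions={"lesioned": {"lam1": mc.ParamSpec.fixed(0.5)}}, multistart=12)
        free = mc.two_store_spec(
            lesions={"lesioned": {"lam1": mc.ParamSpec.free(0.0, 1.0)}},
            multistart=12)
        assert mc.fit(ds, free).sse <= mc.fit(ds, fixed).sse + 1e-9

    def test_recovery_improves_with_trials(self):
        # estimator consistency: error shrinks as binomial noise vanishes
        truth = mc.two_store(2.0, 0.3, 0.1)
        times = np.array([0.5, 2.0, 5.0, 10.0, 20.0])
        med_err = {}
        for n in (20, 1000):
            errs = []
            for rep in range(20):
                ds = make_two_group_dataset(truth, 1.0, times, trials=n,
                                            seed=1000 * n + rep)
                res = mc.fit(ds, cho_spec(multistart=6))
                errs.append(abs(res.params["a1"] - 0.3) / 0.3)
            med_err[n] = float(np.median(errs))
        assert med_err[1000] < med_err[20]
        assert med_err[1000] < 0.10


class TestFitRR:
    def test_self_consistency_on_exact_curve(self):
        # generating values from a published Korsakoff famous-faces fit
        truth = dict(a1=0.108, mu2=0.001, lam=0.779)
        params = mc.two_store(1.0, truth["a1"], truth["mu2"])
        lesion = mc.pathology_profile("korsakoff", lam=truth["lam"])
        t = np.array([2.5, 7.5, 15.0, 25.0, 35.0, 45.0])
        curve = mc.rr_model(params, lesion, t)
        res = mc.fit_rr(mc.RRCurve(t, curve.rr, "data"), multistart=16)
        assert res.params["a1"] == pytest.approx(truth["a1"], rel=1e-4)
        assert res.params["mu2"] == pytest.approx(truth["mu2"], rel=1e-4)
        assert res.params["lam1"] == pytest.approx(truth["lam"], rel=1e-4)

    def test_full_lesion_recovered_intercept(self):
        params = mc.two_store(1.0, 0.2, 0.01)
        lesion = mc.pathology_profile("korsakoff", lam=1.0)
        t = np.array([1.0, 5.0, 12.0, 25.0, 40.0])
        curve = mc.rr_model(params, lesion, t)
        res = mc.fit_rr(mc.RRCurve(t, curve.rr, "data"), multistart=16)
        assert mc.rr_intercept(res.lesion_profile("")) <= 0.05 or \
            (1.0 - res.params["lam1"]) <= 0.05

    def test_flat_curve_flagged(self):
        t = np.array([1.0, 5.0, 12.0, 25.0])
        with pytest.warns(UserWarning, match="flat"):
            res = mc.fit_rr(mc.RRCurve(t, np.full(4, 0.6), "data"), multistart=8)
        assert "flat" in res.message
        assert res.params["lam1"] == pytest.approx(0.4, abs=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="four"):
            mc.fit_rr(mc.RRCurve([1.0, 2.0, 3.0], [0.5, 0.6, 0.7], "data"))

    def test_mu1_and_q_not_fittable(self):
        t = np.array([1.0, 5.0, 12.0, 25.0, 40.0])
        curve = mc.RRCurve(t, np.linspace(0.2, 0.8, 5), "data")
        with pytest.raises(ValueError, match="cancel"):
            mc.fit_rr(curve, spec={"mu1": mc.ParamSpec.free(0, 10)})


class TestLifetimeAndGoodness:
    @pytest.mark.parametrize("a1,expected", [(0.103, 9.7), (0.286, 3.5), (1.0, 1.0)])
    def test_mtl_lifetime(self, a1, expected):
        assert round(mc.mtl_lifetime(a1), 1) == expected

    def test_lifetime_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError):
            mc.mtl_lifetime(0.0)

    def test_perfect_fit(self):
        o = np.array([0.6, 0.4])
        gof = mc.goodness(o, o, [10, 10])
        assert gof.sse == 0.0 and gof.r2 == 1.0 and gof.chisq == 0.0

    def test_hand_computed_toy(self):
        gof = mc.goodness([0.6, 0.4], [0.5, 0.5], [10, 10], n_free=0)
        assert gof.sse == pytest.approx(0.02)
        assert gof.chisq == pytest.approx(0.8)
        assert 0 < gof.chisq_p < 1

    def test_mean_predictor_has_zero_r2(self):
        o = np.array([0.2, 0.5, 0.8])
        gof = mc.goodness(o, np.full(3, o.mean()), [10, 10, 10])
        assert gof.r2 == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_prediction_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            gof = mc.goodness([0.5], [1.0], [10])
        assert np.isnan(gof.chisq)


class TestRetentionDataset:
    def test_invalid_rows_all_reported(self):
        df = pd.DataFrame({
            "group": ["a", "a", "a", "a"],
            "time": [1.0, 2.0, 2.0, -1.0],
            "successes": [5, 12, 3, 2],
            "trials": [10, 10, 10, 10],
        })
        with pytest.raises(ValueError) as err:
            mc.RetentionDataset(df)
        msg = str(err.value)
        assert "successes 12" in msg and "invalid time" in msg and "duplicate" in msg

    def test_proportion_computed_from_counts(self):
        ds = mc.RetentionDataset.from_counts(["a", "a"], [1.0, 2.0], [5, 2], [10, 10])
        np.testing.assert_allclose(ds.group("a")["proportion"], [0.5, 0.2])
        assert ds.has_counts
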