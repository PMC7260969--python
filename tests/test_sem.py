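import numpy as np
import pandas as pd
import pytest

from conftest import make_chain_data

from acttime.sem import (PathModel, acttime_inputs, fit_path_model,
                         hypothesized_model, permute_rois, prepare_series,
                         regress_out_acttime_model, reverse_model)
from acttime.synth import ROI_LABELS

CIRCUIT_W = {("ACC", "BF"): 0.4, ("BF", "SN"): 0.5, ("PPN", "SN"): 0.3,
             ("HB", "SN"): 0.3, ("SN", "CN"): 0.5, ("SN", "NAc"): 0.5}


class TestPathModel:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            PathModel(nodes=("a", "b"), edges=(("a", "b"), ("b", "a")))

    def test_duplicate_edge_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PathModel(nodes=("a", "b"), edges=(("a", "b"), ("a", "b")))

    def test_free_parameter_count(self):
        m = hypothesized_model()
        # 6 paths + 7 variances
        assert m.n_free == 13
        assert reverse_model(m).n_free == 13


class TestReverseModel:
    def test_hypothesized_circuit_reverses_to_expected_edges(self):
        rev = reverse_model(hypothesized_model())
        assert set(rev.edges) == {("BF", "ACC"), ("SN", "BF"), ("SN", "PPN"),
                                  ("SN", "HB"), ("CN", "SN"), ("NAc", "SN")}

    def test_involution(self):
        m = hypothesized_model()
        assert reverse_model(reverse_model(m)) == m

    def test_single_edge(self):
        m = PathModel(nodes=("x", "y"), edges=(("x", "y"),))
        assert reverse_model(m).edges == (("y", "x"),)


class TestFitPathModel:
    def test_saturated_truth_limit(self):
        df = make_chain_data(CIRCUIT_W, 20_000, 1.0, seed=1, labels=ROI_LABELS)
        fit = fit_path_model(hypothesized_model(), df)
        assert fit.fml < 0.01
        assert fit.srmr < 0.02
        assert fit.gfi > 0.99
        assert fit.rmsea < 0.05
        assert fit.df == 15

    def test_parameter_recovery_within_2se(self):
        df = make_chain_data(CIRCUIT_W, 4000, 1.0, seed=2, labels=ROI_LABELS)
        fit = fit_path_model(hypothesized_model(), df)
        for e, w in CIRCUIT_W.items():
            assert abs(fit.path_coefficients[e] - w) <= 2 * fit.path_se[e], e

    def test_three_node_chain_matches_path_tracing_oracle(self):
        # x -a-> y -b-> z with unit innovations: Wright's rules give
        # var(x)=1, var(y)=a^2+1, var(z)=b^2(a^2+1)+1,
        # cov(x,y)=a, cov(x,z)=ab, cov(y,z)=b(a^2+1)
        a, b = 0.7, -0.4
        s = np.array([
            [1.0, a, a * b],
            [a, a ** 2 + 1.0, b * (a ** 2 + 1.0)],
            [a * b, b * (a ** 2 + 1.0), b ** 2 * (a ** 2 + 1.0) + 1.0],
        ])
        rng = np.random.default_rng(3)
        chol = np.linalg.cholesky(s)
        # synthesize data whose sample covariance is exactly s
        raw = rng.normal(size=(5000, 3))
        raw = raw - raw.mean(0)
        white = np.linalg.cholesky(np.cov(raw, rowvar=False, ddof=1))
        x = raw @ np.linalg.inv(white).T @ chol.T
        df = pd.DataFrame(x, columns=["x", "y", "z"])
        m = PathModel(nodes=("x", "y", "z"), edges=(("x", "y"), ("y", "z")))
        fit = fit_path_model(m, df)
        assert fit.fml == pytest.approx(0.0, abs=1e-8)
        assert fit.path_coefficients[("x", "y")] == pytest.approx(a, abs=1e-6)
        assert fit.path_coefficients[("y", "z")] == pytest.approx(b, abs=1e-6)
        assert np.allclose(fit.residual_variances.to_numpy(), 1.0, atol=1e-5)

    def test_singular_covariance_rejected(self):
        rng = np.random.default_rng(4)
        col = rng.normal(size=200)
        df = pd.DataFrame({"x": col, "y": 2 * col, "z": rng.normal(size=200)})
        m = PathModel(nodes=("x", "y", "z"), edges=(("x", "y"),))
        with pytest.raises(ValueError, match="singular"):
            fit_path_model(m, df)

    def test_aic_differences_invariant_to_common_rescaling(self):
        df = make_chain_data(CIRCUIT_W, 1500, 1.0, seed=5, labels=ROI_LABELS)
        m = hypothesized_model()
        d1 = fit_path_model(m, df).aic - fit_path_model(reverse_model(m), df).aic
        df2 = df * 7.3
        d2 = fit_path_model(m, df2).aic - fit_path_model(reverse_model(m), df2).aic
        assert d1 == pytest.approx(d2, abs=0.5)

    def test_hypothesized_direction_beats_reversal(self):
        df = make_chain_data(CIRCUIT_W, 2000, 1.0, seed=6, labels=ROI_LABELS)
        m = hypothesized_model()
        fit_h = fit_path_model(m, df)
        fit_r = fit_path_model(reverse_model(m), df)
        assert fit_h.aic < fit_r.aic
        assert fit_h.n_free == fit_r.n_free


class TestRegressOutActtime:
    def _session(self, n=40, seed=7):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "acttime": rng.uniform(4, 16, n),
            "trial_onset_in_run": np.arange(n) * 34.0,
        })

    def test_inputs_have_two_columns_on_run_grid(self):
        ins = acttime_inputs(self._session(), 1400, 1.0)
        assert list(ins.columns) == ["resp_main", "resp_acttime"]
        assert len(ins) == 1400

    def test_constant_acttime_drops_parametric_input(self):
        session = self._session()
        session["acttime"] = 9.0
        with pytest.warns(UserWarning, match="constant"):
            ins = acttime_inputs(session, 1400, 1.0)
        assert "resp_acttime" not in ins.columns

    def test_residual_variance_drops_when_bold_is_acttime_locked(self):
        session = self._session(60, seed=8)
        rng = np.random.default_rng(9)
        n = int(session["trial_onset_in_run"].iloc[-1] + 30)
        ins = acttime_inputs(session, n, 1.0)
        nodes = ("x", "y")
        df = pd.DataFrame({
            "x": 1.0 * ins["resp_main"] + 0.8 * ins["resp_acttime"]
                 + 0.3 * rng.normal(size=n),
            "y": 0.7 * ins["resp_main"] + 0.3 * rng.normal(size=n),
        })
        base = PathModel(nodes=nodes, edges=(("x", "y"),))
        fit0 = fit_path_model(base, df)
        aug = regress_out_acttime_model(base)
        fit1 = fit_path_model(aug, pd.concat([df, ins], axis=1))
        assert (fit1.residual_variances[list(nodes)]
                < fit0.residual_variances[list(nodes)]).all()

    def test_acttime_driven_coupling_shrinks_after_regression(self):
        # two nodes whose only shared signal is the actTime-locked input:
        # the apparent x->y path collapses once the inputs are modelled
        session = self._session(80, seed=10)
        rng = np.random.default_rng(11)
        n = int(session["trial_onset_in_run"].iloc[-1] + 30)
        ins = acttime_inputs(session, n, 1.0)
        common = ins["resp_main"] + 0.6 * ins["resp_acttime"]
        df = pd.DataFrame({
            "x": common + 0.3 * rng.normal(size=n),
            "y": common + 0.3 * rng.normal(size=n),
        })
        base = PathModel(nodes=("x", "y"), edges=(("x", "y"),))
        fit0 = fit_path_model(base, df)
        aug = regress_out_acttime_model(base)
        fit1 = fit_path_model(aug, pd.concat([df, ins], axis=1))
        assert abs(fit1.path_coefficients[("x", "y")]) \
            < 0.5 * abs(fit0.path_coefficients[("x", "y")])


class TestPermuteRois:
    def test_three_node_chain_has_six_assignments(self):
        w = {("x", "y"): 0.6, ("y", "z"): 0.5}
        df = make_chain_data(w, 800, 1.0, seed=12)
        m = PathModel(nodes=("x", "y", "z"), edges=(("x", "y"), ("y", "z")))
        ens = permute_rois(m, df)
        assert len(ens.aics) == 6
        assert ens.n_failed == 0

    def test_identity_assignment_reproduces_reference_aic(self):
        w = {("x", "y"): 0.6, ("y", "z"): 0.5}
        df = make_chain_data(w, 800, 1.0, seed=13)
        m = PathModel(nodes=("x", "y", "z"), edges=(("x", "y"), ("y", "z")))
        ens = permute_rois(m, df)
        i = ens.assignments.index(("x", "y", "z"))
        assert ens.aics[i] == ens.reference_aic

    def test_true_topology_ranks_low_in_its_ensemble(self):
        w = {("x", "y"): 0.7, ("y", "z"): 0.7}
        df = make_chain_data(w, 2000, 1.0, seed=14)
        m = PathModel(nodes=("x", "y", "z"), edges=(("x", "y"), ("y", "z")))
        ens = permute_rois(m, df)
        # the reversed chain is Markov-equivalent, so the minimum is shared
        assert ens.reference_aic <= ens.aics.min() + 1e-6


class TestPrepareSeries:
    def test_demeans_each_participant(self):
        rng = np.random.default_rng(15)
        frames = {p: pd.DataFrame({"a": rng.normal(5, 1, 50),
                                   "b": rng.normal(-2, 1, 50)})
                  for p in ("s1", "s2")}
        out = prepare_series(frames)
        assert len(out) == 100
        assert np.allclose(out.iloc[:50].mean(), 0.0, atol=1e-12)
        assert np.allclose(out.iloc[50:].mean(), 0.0, atol=1e-12)
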