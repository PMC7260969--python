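import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from acttime.hrf import HrfSpec, hrf_kernel
from acttime.tsglm import (EpochedMatrix, GlmSpec, RoiTimeSeries, build_ppi_spec,
                           epoch, fit_timecourse_glm, glm_deterministic,
                           loo_peak_test, loo_peak_tests, preprocess)


def make_epoched(data, dt=0.5, window=(-9.0, 6.0)):
    times = np.arange(window[0], window[1] + dt / 2, dt)
    assert data.shape[1] == len(times)
    return EpochedMatrix(data=data, epoch_times=times,
                         trial_index=np.arange(data.shape[0]))


def fake_session(n, rng):
    att = rng.uniform(3.0, 18.0, n)
    return pd.DataFrame({
        "acttime": att,
        "trial_onset_in_run": np.arange(n) * 34.0,
        "prev_acttime": rng.uniform(3.0, 18.0, n),
    })


class TestPreprocess:
    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            preprocess(np.ones(50), 1.0)

    def test_nan_input_reported_with_indices(self):
        x = np.ones(20) + np.arange(20.0)
        x[7] = np.nan
        with pytest.raises(ValueError, match="7"):
            preprocess(x, 1.0)

    def test_no_resampling_needed_leaves_zscores(self):
        rng = np.random.default_rng(0)
        x = rng.normal(2.0, 3.0, 100)
        out = preprocess(x, 0.5, 0.5)
        assert np.allclose(out.values, (x - x.mean()) / x.std())

    def test_upsampling_matches_manual_linear_interpolation(self):
        t = np.arange(0, 30, 1.0)
        x = np.sin(2 * np.pi * t / 10)
        out = preprocess(x, 1.0, 0.5)
        z = (x - x.mean()) / x.std()
        # manual interpolation oracle at half-integer times
        mid = 0.5 * (z[:-1] + z[1:])
        assert np.allclose(out.values[1::2], mid)
        assert np.allclose(out.values[0::2], z)


class TestEpoch:
    def test_31_columns_at_half_second_grid(self):
        series = RoiTimeSeries(np.random.default_rng(1).normal(size=400), 0.5)
        ep = epoch(series, [50.0, 90.0], (-9.0, 6.0))
        assert ep.data.shape == (2, 31)
        assert ep.epoch_times[0] == -9.0 and ep.epoch_times[-1] == 6.0

    def test_event_near_run_edge_dropped_and_counted(self):
        series = RoiTimeSeries(np.random.default_rng(2).normal(size=100), 0.5)
        ep = epoch(series, [5.0, 30.0], (-9.0, 6.0))  # first event: window < 0
        assert ep.data.shape[0] == 1
        assert ep.n_dropped == 1
        assert ep.trial_index.tolist() == [1]

    def test_all_trials_dropped_raises(self):
        series = RoiTimeSeries(np.zeros(20), 0.5)
        with pytest.raises(ValueError, match="dropped"):
            epoch(series, [1.0], (-9.0, 6.0))


class TestFitTimecourseGlm:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        n, k, t = 40, 4, 7
        y = rng.normal(size=(n, t))
        cols = {f"x{i}": rng.normal(size=n) for i in range(k - 1)}
        cols["constant"] = np.ones(n)
        ep = EpochedMatrix(y, np.linspace(-9, 6, t), np.arange(n))
        betas = fit_timecourse_glm(ep, GlmSpec(columns=cols))
        x = np.column_stack(list(cols.values()))
        oracle = np.linalg.solve(x.T @ x, x.T @ y)  # normal equations
        assert np.allclose(betas.to_numpy(), oracle.T, atol=1e-10)

    def test_exact_recovery_of_modulation_weight(self):
        # noise-free BOLD built as w * modulator x kernel: per-timestep OLS
        # must return exactly w * kernel(tau)
        rng = np.random.default_rng(3)
        n = 50
        w = 0.37
        kernel = hrf_kernel(HrfSpec(), 0.5)[:31]
        mod = rng.normal(size=n)
        modz = (mod - mod.mean()) / mod.std()
        data = w * np.outer(modz, kernel) + 1.5
        ep = make_epoched(data)
        spec = GlmSpec(columns={"mod": modz, "constant": np.ones(n)})
        betas = fit_timecourse_glm(ep, spec)
        assert np.allclose(betas["mod"].to_numpy(), w * kernel, atol=1e-6)

    def test_rank_deficient_design_names_collinear_pair(self):
        rng = np.random.default_rng(4)
        n = 30
        a = rng.normal(size=n)
        cols = {"a": a, "b": 2.0 * a, "constant": np.ones(n)}
        ep = make_epoched(rng.normal(size=(n, 31)))
        with pytest.raises(ValueError, match="'a' vs 'b'|'b' vs 'a'"):
            fit_timecourse_glm(ep, GlmSpec(columns=cols))

    def test_too_few_trials_rejected(self):
        ep = make_epoched(np.random.default_rng(5).normal(size=(6, 31)))
        cols = {f"x{i}": np.random.default_rng(i).normal(size=6) for i in range(3)}
        with pytest.raises(ValueError, match="few trials"):
            fit_timecourse_glm(ep, GlmSpec(columns=cols))

    def test_deterministic_beta_invariant_to_observed_acttime_leakage(self):
        # adding any multiple of the observed-actTime regressor to the BOLD
        # must not move the deterministic-actTime beta (partialling)
        rng = np.random.default_rng(6)
        n = 80
        session = fake_session(n, rng)
        det = pd.DataFrame({"det_present_past": rng.uniform(5, 15, n)})
        spec = glm_deterministic(session, det)
        y = rng.normal(size=(n, 31))
        obs = spec.columns["observed_actTime"]
        ep1 = make_epoched(y)
        ep2 = make_epoched(y + 3.7 * obs[:, None])
        b1 = fit_timecourse_glm(ep1, spec)["deterministic_actTime"]
        b2 = fit_timecourse_glm(ep2, spec)["deterministic_actTime"]
        assert np.allclose(b1, b2, atol=1e-10)

    def test_sign_and_phase_of_generative_peaks_recovered(self):
        # an SN-like ROI with positive early modulation and a BF-like ROI
        # with negative late modulation must peak with the right sign and
        # in the right phase window
        rng = np.random.default_rng(7)
        n = 120
        kernel = hrf_kernel(HrfSpec(), 0.5)
        tau = np.arange(-9, 6.01, 0.5)
        early = np.interp(tau, np.arange(len(kernel)) * 0.5 - 7.0, kernel,
                          left=0, right=0)   # peaks near -1 s
        late = np.interp(tau, np.arange(len(kernel)) * 0.5 - 1.0, kernel,
                         left=0, right=0)    # peaks near +5 s
        mod = rng.normal(size=n)
        modz = (mod - mod.mean()) / mod.std()
        sn = 0.5 * np.outer(modz, early) + 0.05 * rng.normal(size=(n, len(tau)))
        bf = -0.5 * np.outer(modz, late) + 0.05 * rng.normal(size=(n, len(tau)))
        spec = GlmSpec(columns={"mod": modz, "constant": np.ones(n)})
        b_sn = fit_timecourse_glm(make_epoched(sn), spec)["mod"]
        b_bf = fit_timecourse_glm(make_epoched(bf), spec)["mod"]
        t_sn = b_sn.abs().idxmax()
        t_bf = b_bf.abs().idxmax()
        assert -2.0 <= t_sn <= 0.5 and b_sn[t_sn] > 0
        assert 4.0 <= t_bf <= 6.0 and b_bf[t_bf] < 0


class TestPpi:
    def _ppi_setup(self, n, b_inter, seed, noise=0.2):
        rng = np.random.default_rng(seed)
        session = fake_session(n, rng)
        det = pd.DataFrame({"det_present_past": rng.uniform(5, 15, n)})
        seed_bold = rng.normal(size=(n, 31))
        psych = det["det_present_past"].to_numpy()
        psych_z = (psych - psych.mean()) / psych.std()
        gain = 0.8 + b_inter * psych_z
        target = gain[:, None] * seed_bold + noise * rng.normal(size=(n, 31))
        return session, det, make_epoched(seed_bold), make_epoched(target)

    def test_constant_coupling_gives_null_interaction(self):
        session, det, seed_ep, target_ep = self._ppi_setup(300, 0.0, seed=8)
        spec = build_ppi_spec(seed_ep, session, det)
        betas = fit_timecourse_glm(target_ep, spec)
        se = 0.2 / np.sqrt(300)
        assert np.abs(betas["PPI"].to_numpy()).max() < 5 * se

    def test_interaction_weight_recovered_within_2se(self):
        b = 0.3
        session, det, seed_ep, target_ep = self._ppi_setup(300, b, seed=9)
        spec = build_ppi_spec(seed_ep, session, det)
        betas = fit_timecourse_glm(target_ep, spec)["PPI"].to_numpy()
        # rough SE: residual sd / (sqrt(n) * sd of the PPI column) per timestep
        ppi_col = np.asarray(spec.columns["PPI"])
        se = 0.2 / (np.sqrt(300) * ppi_col.std(axis=0).mean())
        assert abs(betas.mean() - b) < 2 * se

    def test_constant_psychological_factor_rejected(self):
        rng = np.random.default_rng(10)
        session = fake_session(50, rng)
        det = pd.DataFrame({"det_present_past": np.full(50, 9.0)})
        with pytest.raises(ValueError, match="constant"):
            build_ppi_spec(make_epoched(rng.normal(size=(50, 31))), session, det)

    def test_misaligned_seed_rejected(self):
        rng = np.random.default_rng(11)
        session = fake_session(40, rng)
        det = pd.DataFrame({"det_present_past": rng.uniform(5, 15, 40)})
        with pytest.raises(ValueError, match="misaligned"):
            build_ppi_spec(make_epoched(rng.normal(size=(41, 31))), session, det)


class TestLooPeak:
    def test_shared_peak_found_in_every_fold(self):
        rng = np.random.default_rng(12)
        tau = np.arange(-9, 6.01, 0.5)
        bump = np.exp(-0.5 * ((tau - 2.0) / 0.8) ** 2)
        betas = 0.8 * bump + 0.05 * rng.normal(size=(12, len(tau)))
        r = loo_peak_test(betas, tau, "full")
        assert np.allclose(r["peak_times"], 2.0, atol=0.5)
        assert r["p_raw"] < 1e-6 and r["t"] > 0

    def test_peak_times_confined_to_phase_window(self):
        rng = np.random.default_rng(13)
        tau = np.arange(-9, 6.01, 0.5)
        betas = rng.normal(size=(8, len(tau)))
        for phase, (lo, hi) in (("early", (-2, 0)), ("late", (4, 6))):
            r = loo_peak_test(betas, tau, phase)
            assert np.all((r["peak_times"] >= lo) & (r["peak_times"] <= hi))

    def test_negative_peak_detected_with_sign(self):
        rng = np.random.default_rng(14)
        tau = np.arange(-9, 6.01, 0.5)
        bump = np.exp(-0.5 * ((tau + 1.0) / 0.8) ** 2)
        betas = -0.8 * bump + 0.05 * rng.normal(size=(10, len(tau)))
        r = loo_peak_test(betas, tau, "full")
        assert r["t"] < 0 and np.allclose(r["mean_peak_time"], -1.0, atol=0.5)

    def test_family_correction_is_monotone_and_conservative(self):
        rng = np.random.default_rng(15)
        tau = np.arange(-9, 6.01, 0.5)
        fam = {f"roi{i}": rng.normal(size=(10, len(tau))) for i in range(9)}
        out = loo_peak_tests(fam, tau, "full")
        assert (out["p_holm"] >= out["p_raw"] - 1e-15).all()
        ordered = out.sort_values("p_raw")
        assert ordered["p_holm"].is_monotonic_increasing
        # Holm's smallest adjusted p equals Bonferroni on the smallest raw p
        assert ordered["p_holm"].iloc[0] == pytest.approx(
            min(1.0, ordered["p_raw"].iloc[0] * 9))

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError, match="participants"):
            loo_peak_test(np.zeros((3, 31)), np.arange(-9, 6.01, 0.5))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_holm_never_rejects_more_than_uncorrected(self, seed):
        rng = np.random.default_rng(seed)
        tau = np.arange(-9, 6.01, 0.5)
        fam = {f"r{i}": rng.normal(size=(6, len(tau))) for i in range(5)}
        out = loo_peak_tests(fam, tau, "full")
        assert out["significant"].sum() <= (out["p_raw"] < 0.05).sum()
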