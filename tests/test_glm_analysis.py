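import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from discrw.glm_analysis import (
    DEFAULT_OVERSAMPLING,
    TASK_COLUMNS,
    bh_fdr,
    build_design_matrix,
    compare_models,
    fit_glm,
    highpass_basis,
    hrf_curve,
    hrf_kernel,
)
from discrw.rw_models import ModelParams, run_model
from discrw.synthetic_data import (
    GroundTruth,
    SubjectProfile,
    simulate_judgments,
    synthesize_bold,
)


@pytest.fixture
def trace(exp_design):
    trials = simulate_judgments(exp_design, SubjectProfile(subject_id=1), seed=3)
    return run_model(trials, ModelParams("WITH", 0.05))


@pytest.fixture
def design_matrix(exp_design, trace):
    return build_design_matrix(exp_design, trace)


class TestHrfKernel:
    def test_peak_near_five_seconds(self):
        # oracle: numerically locate the mode of the double-gamma mixture
        res = optimize.minimize_scalar(
            lambda t: -hrf_curve(t), bounds=(1.0, 10.0), method="bounded"
        )
        assert res.x == pytest.approx(5.0, abs=0.05)
        t_fine = np.arange(0, 32, 0.01)
        k = hrf_curve(t_fine)
        assert t_fine[np.argmax(k)] == pytest.approx(res.x, abs=0.02)

    def test_zero_at_time_zero(self):
        assert hrf_kernel(2.1)[0] == 0.0

    def test_length_is_ceil_32_over_tr(self):
        for tr in (1.0, 2.1, 3.0):
            assert len(hrf_kernel(tr)) == int(np.ceil(32.0 / tr))

    def test_normalized_to_unit_peak(self):
        k = hrf_kernel(0.5)
        assert k.max() == pytest.approx(1.0, abs=1e-3)

    def test_invalid_tr(self):
        with pytest.raises(ValueError):
            hrf_kernel(0.0)


class TestHighpassBasis:
    def test_column_count_formula(self):
        # oracle: floor(2 * N * TR / cutoff)
        assert highpass_basis(250, 2.1, 128.0).shape == (250, 8)
        for n, tr, cutoff in ((100, 2.0, 100.0), (64, 3.0, 90.0), (250, 2.1, 300.0)):
            expected = int(np.floor(2.0 * n * tr / cutoff))
            assert highpass_basis(n, tr, cutoff).shape == (n, expected)

    def test_orthonormal(self):
        b = highpass_basis(250, 2.1, 128.0)
        np.testing.assert_allclose(b.T @ b, np.eye(b.shape[1]), atol=1e-10)

    def test_slow_cosine_energy_captured(self):
        n, tr = 250, 2.1
        t = np.arange(n) * tr
        sig = np.cos(2 * np.pi * t / 300.0)
        sig = sig - sig.mean()
        b = highpass_basis(n, tr, 128.0)
        proj = b @ (b.T @ sig)
        assert (proj @ proj) / (sig @ sig) >= 0.99

    def test_cutoff_shorter_than_two_tr_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            highpass_basis(250, 2.1, 3.0)

    def test_too_few_volumes_rejected(self):
        with pytest.raises(ValueError, match="n_volumes"):
            highpass_basis(3, 2.1)


class TestBuildDesignMatrix:
    def test_five_task_columns(self, design_matrix):
        task_names = [c for c in design_matrix.column_names if not
                      (c.startswith("highpass_") or c == "intercept")]
        assert tuple(task_names) == TASK_COLUMNS
        assert len(task_names) == 5

    def test_single_intercept_and_no_allzero_columns(self, design_matrix):
        assert design_matrix.column_names.count("intercept") == 1
        assert np.all(np.abs(design_matrix.values).max(axis=0) > 1e-12)

    def test_constant_modulator_rejected(self, exp_design, trace):
        degenerate = trace
        degenerate.delta[:] = 0.42
        with pytest.raises(ValueError, match="delta_modulator"):
            build_design_matrix(exp_design, degenerate)

    def test_length_mismatch_rejected(self, exp_design, trace):
        short = trace.for_session(1)
        short.delta = short.delta[:10]
        short.v = short.v[:10]
        short.r = short.r[:10]
        short.session_index = short.session_index[:10]
        with pytest.raises(ValueError, match="per-session slice"):
            build_design_matrix(exp_design, short)

    def test_superposition_oracle(self, exp_design, trace):
        # brute force: sum of per-trial shifted kernels
        dm = build_design_matrix(exp_design, trace, centering_policy="center")
        dt = exp_design.tr / DEFAULT_OVERSAMPLING
        t_kernel = np.arange(0.0, 32.0, dt)
        kernel = hrf_curve(t_kernel)
        kernel = kernel / kernel.max()
        n_fine = exp_design.n_volumes * DEFAULT_OVERSAMPLING
        expected = np.zeros(n_fine)
        heights = trace.delta - trace.delta.mean()
        for trial, h in zip(exp_design.trials, heights):
            idx = int(round(trial.delivery_onset / dt))
            end = min(n_fine, idx + len(kernel))
            expected[idx:end] += h * kernel[: end - idx]
        np.testing.assert_allclose(
            dm.column("delta_modulator"),
            expected[::DEFAULT_OVERSAMPLING],
            atol=1e-10,
        )

    def test_modulators_centered_and_scaled(self, exp_design, trace):
        dm = build_design_matrix(exp_design, trace, centering_policy="center_scale")
        # reconstruct impulse heights: delta scaled to unit SD
        h = (trace.delta - trace.delta.mean()) / (trace.delta - trace.delta.mean()).std()
        assert h.std() == pytest.approx(1.0)
        # the convolved column integrates the scaled impulses; compare peak scale
        dm_centered = build_design_matrix(exp_design, trace, centering_policy="center")
        ratio = dm.column("delta_modulator") / np.where(
            np.abs(dm_centered.column("delta_modulator")) > 1e-9,
            dm_centered.column("delta_modulator"),
            np.nan,
        )
        sd = (trace.delta - trace.delta.mean()).std()
        finite = np.isfinite(ratio)
        np.testing.assert_allclose(ratio[finite], 1.0 / sd, rtol=1e-6)

    def test_orthogonalize_makes_modulators_orthogonal_to_events(self, exp_design, trace):
        dm = build_design_matrix(exp_design, trace, orthogonalize=True)
        for mod in ("v_modulator", "delta_modulator", "reward_modulator"):
            for ev in ("stimulus_event", "delivery_event"):
                assert abs(dm.column(mod) @ dm.column(ev)) < 1e-8
        assert abs(dm.column("delta_modulator") @ dm.column("v_modulator")) < 1e-8


class TestFitGlm:
    def test_noiseless_recovery_exact(self, design_matrix):
        beta_true = (1.2, -0.5, 0.8, 2.0, 0.3)
        ts = synthesize_bold(
            design_matrix, GroundTruth(beta_true=beta_true, noise_sd=0, drift_amplitude=0), 0
        )
        res = fit_glm(ts, design_matrix)
        np.testing.assert_allclose(res.betas[:5], beta_true, atol=1e-8)

    def test_ols_matches_normal_equations_oracle(self, design_matrix):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(design_matrix.n_volumes)
        res = fit_glm(y, design_matrix, prewhiten=False)
        x = design_matrix.values
        expected = np.linalg.solve(x.T @ x, x.T @ y)
        np.testing.assert_allclose(res.betas, expected, atol=1e-10)

    def test_ar1_estimate_recovers_generating_coefficient(self, design_matrix):
        truth = GroundTruth(beta_true=(0,) * 5, noise_sd=1.0, ar1_coef=0.3, drift_amplitude=0)
        rhos = [
            fit_glm(synthesize_bold(design_matrix, truth, seed=s), design_matrix).ar1_estimate
            for s in range(30)
        ]
        assert np.mean(rhos) == pytest.approx(0.3, abs=0.05)

    def test_type_one_error_sane(self, design_matrix):
        rng = np.random.default_rng(99)
        hits = sum(
            abs(fit_glm(rng.standard_normal(250), design_matrix).t_stat("delta_modulator")) > 1.96
            for _ in range(300)
        )
        assert 0.02 < hits / 300 < 0.09

    def test_drift_in_filter_nullspace_changes_no_beta(self, design_matrix):
        beta_true = (1.0, 1.0, 0.5, 1.0, 0.5)
        clean = synthesize_bold(
            design_matrix, GroundTruth(beta_true=beta_true, noise_sd=0, drift_amplitude=0), 1
        )
        drifty = synthesize_bold(
            design_matrix, GroundTruth(beta_true=beta_true, noise_sd=0, drift_amplitude=5.0), 1
        )
        b0 = fit_glm(clean, design_matrix).betas[:5]
        b1 = fit_glm(drifty, design_matrix).betas[:5]
        np.testing.assert_allclose(b0, b1, atol=1e-6)

    def test_rank_deficiency_names_columns(self, design_matrix):
        x = design_matrix
        x.values[:, x.column_names.index("v_modulator")] = x.column("stimulus_event")
        with pytest.raises(ValueError, match="collinear"):
            fit_glm(np.zeros(x.n_volumes), x)

    def test_df_error(self, design_matrix):
        import dataclasses

        small = dataclasses.replace(
            design_matrix,
            values=design_matrix.values[:10],
            n_volumes=10,
        )
        with pytest.raises(ValueError, match="not enough volumes"):
            fit_glm(np.zeros(10), small)

    def test_length_mismatch(self, design_matrix):
        with pytest.raises(ValueError, match="length"):
            fit_glm(np.zeros(100), design_matrix)


class TestCompareModels:
    @staticmethod
    def _effects_frame(rows):
        return pd.DataFrame(
            rows, columns=["subject", "session", "alpha", "variant", "effect_size"]
        )

    def test_identical_effects_give_t_zero_p_one(self):
        rows = [
            (s, sess, 0.05, var, 1.0)
            for s in (1, 2, 3)
            for sess in (1, 2, 3)
            for var in ("WITH", "WITHOUT")
        ]
        comp = compare_models(self._effects_frame(rows), alpha_values=[0.05])
        assert comp.per_alpha.t.iloc[0] == 0.0
        assert comp.per_alpha.p.iloc[0] == 1.0

    def test_three_subject_closed_form_oracle(self):
        w = np.array([1.3, 0.9, 1.1])
        wo = np.array([1.0, 0.8, 0.7])
        rows = []
        for i, (a, b) in enumerate(zip(w, wo), start=1):
            rows.append((i, 1, 0.05, "WITH", a))
            rows.append((i, 1, 0.05, "WITHOUT", b))
        comp = compare_models(self._effects_frame(rows), sessions=(1,), alpha_values=[0.05])
        d = w - wo
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert comp.per_alpha.t.iloc[0] == pytest.approx(t_expected, rel=1e-12)
        assert comp.per_alpha.df.iloc[0] == 2

    def test_missing_variant_raises_pairing_error(self):
        rows = [(1, 1, 0.05, "WITH", 1.0), (2, 1, 0.05, "WITH", 1.0),
                (1, 1, 0.05, "WITHOUT", 0.5)]
        with pytest.raises(ValueError, match="missing WITHOUT"):
            compare_models(self._effects_frame(rows), sessions=(1,), alpha_values=[0.05])

    def test_single_subject_rejected(self):
        rows = [(1, 1, 0.05, "WITH", 1.0), (1, 1, 0.05, "WITHOUT", 0.5)]
        with pytest.raises(ValueError, match="at least 2 subjects"):
            compare_models(self._effects_frame(rows), sessions=(1,), alpha_values=[0.05])

    def test_sessions_restriction_applied(self):
        rows = []
        for s in (1, 2):
            rows += [(s, 1, 0.05, "WITH", 2.0), (s, 1, 0.05, "WITHOUT", 1.0)]
            rows += [(s, 4, 0.05, "WITH", -50.0), (s, 4, 0.05, "WITHOUT", 50.0)]
        comp = compare_models(self._effects_frame(rows), sessions=(1,), alpha_values=[0.05])
        assert comp.per_alpha.mean_diff.iloc[0] == pytest.approx(1.0)


class TestBhFdr:
    def test_all_zero_p_all_rejected(self):
        assert bh_fdr([0.0, 0.0, 0.0], 0.05).all()

    def test_enumerated_example(self):
        flags = bh_fdr([0.01, 0.02, 0.2, 0.9], 0.05)
        assert list(flags) == [True, True, False, False]

    def test_matches_bruteforce_stepup(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 30))
            q = 0.1
            flags = bh_fdr(p, q)
            # brute force: largest k with p_(k) <= k q / m
            m = len(p)
            sp = np.sort(p)
            k_star = 0
            for k in range(1, m + 1):
                if sp[k - 1] <= k * q / m:
                    k_star = k
            expected = p <= (sp[k_star - 1] if k_star else -1)
            assert np.array_equal(flags, expected)

    def test_null_uniform_controls_fdr(self):
        rng = np.random.default_rng(42)
        m, q, reps = 20, 0.05, 1000
        fdp = []
        for _ in range(reps):
            p = rng.uniform(size=m)
            rejected = bh_fdr(p, q).sum()
            fdp.append(rejected > 0)  # all nulls: any rejection is a false discovery
        assert np.mean(fdp) <= q + 3 * np.sqrt(q * (1 - q) / reps)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bh_fdr([], 0.05)
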