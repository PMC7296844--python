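"""Design matrices, HRF, OLS, group correlation, cluster thresholds, ROI PCA."""

import numpy as np
import pandas as pd
import pytest

from rewardconn import glm, io, rl, synth
from rewardconn.glm import (
    DesignSpec,
    build_design,
    conjunction,
    contrast_estimate,
    fit_first_level,
    hrf_kernel,
    mc_cluster_threshold,
    roi_first_pc,
    second_level_correlation,
)


@pytest.fixture(scope="module")
def design_spec():
    return DesignSpec(tr=1.56, n_scans=840)


@pytest.fixture(scope="module")
def events(session_trials, task_config):
    return io.trials_to_events(session_trials, task_config)


class TestHRF:
    def test_peak_near_five_seconds(self):
        dt = 0.1
        h = hrf_kernel(dt)
        assert 4.0 < np.argmax(h) * dt < 6.0

    def test_decays_by_32s(self):
        h = hrf_kernel(0.1)
        assert abs(h[-1]) < 1e-3 * h.max()
        assert np.all(np.isfinite(h))

    def test_matches_reference_implementation(self):
        """Double-gamma kernel agrees with nilearn's canonical HRF."""
        nilearn = pytest.importorskip("nilearn.glm.first_level")
        dt = 1.56 / 16
        ours = hrf_kernel(dt)
        ref = nilearn.spm_hrf(1.56, oversampling=16, time_length=32.0 + dt)
        n = min(ours.size, ref.size)
        c = np.corrcoef(ours[:n] / ours.max(), ref[:n] / ref.max())[0, 1]
        assert c > 0.999


class TestBuildDesign:
    def test_single_event_is_hrf_impulse(self):
        spec = DesignSpec(tr=1.56, n_scans=64)
        ev = pd.DataFrame(
            [
                dict(onset=0.0, duration=spec.dt, trial_type="cue_choice",
                     condition="choice", action="high", outcome=1, missed=0)
            ]
        )
        X = build_design(ev, variant="categorical", spec=spec)
        col = X["cue_choice"].to_numpy()
        h = hrf_kernel(spec.dt)[:: spec.micro_per_tr]
        n = min(col.size, h.size)
        np.testing.assert_allclose(col[:n], h[:n], atol=1e-12)

    def test_column_counts_both_variants(self, schedule, model3, params3, task_config, design_spec):
        # a session with misses so the nuisance regressor is populated
        trials = synth.simulate_agent(
            schedule, model3, params3, task_config, seed=5, miss_rate=0.1
        )
        events = io.trials_to_events(trials, task_config)
        n_out = int((~events[events["trial_type"].str.startswith("outcome")].empty)
                    and events["trial_type"].str.startswith("outcome").sum())
        rng = np.random.default_rng(0)
        motion = rng.standard_normal((design_spec.n_scans, 6))
        Xc = build_design(events, "categorical", motion=motion, spec=design_spec)
        Xm = build_design(
            events, "modulated", modulator_values=np.arange(n_out, dtype=float),
            motion=motion, spec=design_spec,
        )
        # 2 cue + 4 outcome + 2 response + 1 nuisance + 6 motion (+ constant)
        assert Xc.shape[1] == 15 + 1
        # 2 cue + outcome + modulator + 2 response + 1 nuisance + 6 motion (+ constant)
        assert Xm.shape[1] == 13 + 1

    def test_constant_modulator_column_vanishes(self, events, design_spec):
        X = build_design(
            events, "modulated", modulator_values=np.full(66, 3.7), spec=design_spec
        )
        np.testing.assert_allclose(X["outcome_modulator"], 0.0, atol=1e-12)

    def test_event_outside_window_rejected(self, design_spec):
        ev = pd.DataFrame(
            [
                dict(onset=1e6, duration=1.0, trial_type="cue_choice",
                     condition="choice", action="high", outcome=1, missed=0)
            ]
        )
        with pytest.raises(ValueError):
            build_design(ev, "categorical", spec=design_spec)

    def test_outcome_subspace_shared_with_binary_modulator(self, events, design_spec):
        """The 4-outcome categorical columns span the single-outcome +
        binary-win-modulator columns (same events, re-partitioned)."""
        out_ev = events[events["trial_type"].str.startswith("outcome")].sort_values("onset")
        wins = (out_ev["trial_type"] == "outcome_win").to_numpy(dtype=float)
        Xc = build_design(events, "categorical", spec=design_spec)
        Xm = build_design(events, "modulated", modulator_values=wins, spec=design_spec)
        A = Xc[
            ["outcome_win_choice", "outcome_nowin_choice",
             "outcome_win_nochoice", "outcome_nowin_nochoice"]
        ].to_numpy()
        for col in ("outcome_all", "outcome_modulator"):
            b, res, *_ = np.linalg.lstsq(A, Xm[col].to_numpy(), rcond=None)
            resid = Xm[col].to_numpy() - A @ b
            assert np.abs(resid).max() < 1e-8

    def test_categorical_and_modulated_contrasts_agree(self, task_config):
        """reward > no-reward contrast and the binary modulator estimate give
        the same effect (same sign, correlated) on planted data."""
        rng = np.random.default_rng(4)
        spec = DesignSpec(tr=1.56, n_scans=840)
        model = rl.MODELS[3]
        betas_c, betas_m = [], []
        from rewardconn.task import generate_schedule

        for s in range(8):
            schedule = generate_schedule(task_config, seed=100 + s)
            params = rl.RLParams(0.4, 0.2, 3.0, 3.0)
            trials = synth.simulate_agent(schedule, model, params, task_config, seed=s)
            events = io.trials_to_events(trials, task_config)
            out_ev = events[events["trial_type"].str.startswith("outcome")].sort_values("onset")
            wins = (out_ev["trial_type"] == "outcome_win").to_numpy(dtype=float)
            amplitude = rng.uniform(0.5, 1.5)
            Xc = build_design(events, "categorical", spec=spec)
            Xm = build_design(events, "modulated", modulator_values=wins, spec=spec)
            win_cols = Xc["outcome_win_choice"] + Xc["outcome_win_nochoice"]
            y = amplitude * win_cols.to_numpy() + 0.3 * rng.standard_normal(spec.n_scans)
            bc, _ = fit_first_level(y, Xc)
            c = np.zeros(Xc.shape[1])
            for name, w in (
                ("outcome_win_choice", 0.5), ("outcome_win_nochoice", 0.5),
                ("outcome_nowin_choice", -0.5), ("outcome_nowin_nochoice", -0.5),
            ):
                c[list(Xc.columns).index(name)] = w
            betas_c.append(contrast_estimate(bc, c))
            bm, _ = fit_first_level(y, Xm)
            betas_m.append(bm[list(Xm.columns).index("outcome_modulator")])
        betas_c, betas_m = np.asarray(betas_c), np.asarray(betas_m)
        assert np.all(np.sign(betas_c) == np.sign(betas_m))
        assert np.corrcoef(betas_c, betas_m)[0, 1] > 0.8


class TestFirstLevel:
    def test_noiseless_exact_recovery(self, events, design_spec):
        X = build_design(events, "categorical", spec=design_spec)
        rng = np.random.default_rng(0)
        beta_true = rng.standard_normal(X.shape[1])
        y = X.to_numpy() @ beta_true
        beta, rv = fit_first_level(y, X)
        np.testing.assert_allclose(beta, beta_true, atol=1e-8)
        assert rv == pytest.approx(0.0, abs=1e-12)

    def test_rank_deficiency_names_columns(self, events, design_spec):
        X = build_design(events, "categorical", spec=design_spec)
        X["dup"] = X["cue_choice"]
        with pytest.raises(np.linalg.LinAlgError, match="dup|cue_choice"):
            fit_first_level(np.zeros(design_spec.n_scans), X)

    def test_modulator_coverage(self):
        """Planted modulator amplitude recovered within its CI in ~95% of
        noisy simulations."""
        from scipy import stats as st

        spec = DesignSpec(tr=1.56, n_scans=500)
        rng = np.random.default_rng(9)
        onsets = np.arange(40) * 18.0 + 5.0
        ev = pd.DataFrame(
            [
                dict(onset=o, duration=1.5, trial_type="outcome_win",
                     condition="choice", action="high", outcome=1, missed=0)
                for o in onsets
            ]
        )
        mod = rng.standard_normal(40)
        X = build_design(ev, "modulated", modulator_values=mod, spec=spec)
        Xm = X.to_numpy()
        j = list(X.columns).index("outcome_modulator")
        XtXinv = np.linalg.inv(Xm.T @ Xm)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            y = 1.0 * Xm[:, j] + 1.0 * rng.standard_normal(spec.n_scans)
            beta, rv = fit_first_level(y, X)
            se = np.sqrt(rv * XtXinv[j, j])
            crit = st.t.ppf(0.975, spec.n_scans - Xm.shape[1])
            hits += abs(beta[j] - 1.0) <= crit * se
        assert hits / n_sim >= 0.90

    def test_null_orthogonal_contrast(self, events, design_spec):
        X = build_design(events, "categorical", spec=design_spec)
        rng = np.random.default_rng(2)
        y = rng.standard_normal(design_spec.n_scans)
        beta, _ = fit_first_level(y, X)
        assert abs(beta[list(X.columns).index("cue_choice")]) < 2.0


class TestSecondLevel:
    def test_reduces_to_spearman(self):
        from rewardconn.behavior import spearman

        rng = np.random.default_rng(1)
        cv = rng.standard_normal(30)
        scores = rng.standard_normal(30)
        assert second_level_correlation(cv, scores) == spearman(cv, scores)

    def test_planted_negative_dependence_recovered(self):
        rng = np.random.default_rng(3)
        qids = rng.integers(0, 20, size=60).astype(float)
        amplitude = 1.0 - 0.08 * qids + 0.2 * rng.standard_normal(60)
        rho, p = second_level_correlation(amplitude, qids)
        assert rho < -0.5
        assert p < 1e-3

    def test_permuted_scores_null(self):
        rng = np.random.default_rng(4)
        qids = rng.integers(0, 20, size=80).astype(float)
        amplitude = 1.0 - 0.08 * qids + 0.2 * rng.standard_normal(80)
        rho, _ = second_level_correlation(amplitude, rng.permutation(qids))
        assert abs(rho) < 0.25


class TestClusterThreshold:
    def test_reproducible_and_monotone_in_fwhm(self):
        k1a = mc_cluster_threshold((16, 16, 8), 3.4, 6.8, n_sims=150, seed=5)
        k1b = mc_cluster_threshold((16, 16, 8), 3.4, 6.8, n_sims=150, seed=5)
        k2 = mc_cluster_threshold((16, 16, 8), 3.4, 10.2, n_sims=150, seed=5)
        assert k1a == k1b
        assert k2 >= k1a

    def test_unsmoothed_matches_independent_oracle(self):
        """No smoothing on a 10x10x1 grid: extent matches a brute-force
        Bernoulli-field + flood-fill oracle."""
        from scipy import stats as st

        k = mc_cluster_threshold((10, 10, 1), 3.0, 3.0, voxel_p=0.05,
                                 fwe_p=0.01, n_sims=3000, seed=8)
        rng = np.random.default_rng(12345)
        p_vox = 2 * st.norm.sf(st.norm.ppf(1 - 0.025))

        def flood_max(mask):
            seen = np.zeros_like(mask, dtype=bool)
            best = 0
            for i in range(10):
                for j in range(10):
                    if mask[i, j] and not seen[i, j]:
                        stack, size = [(i, j)], 0
                        seen[i, j] = True
                        while stack:
                            a, b = stack.pop()
                            size += 1
                            for da in (-1, 0, 1):
                                for db in (-1, 0, 1):
                                    x, y = a + da, b + db
                                    if 0 <= x < 10 and 0 <= y < 10 and mask[x, y] and not seen[x, y]:
                                        seen[x, y] = True
                                        stack.append((x, y))
                        best = max(best, size)
            return best

        maxima = [
            flood_max(rng.uniform(size=(10, 10)) < p_vox) for _ in range(3000)
        ]
        oracle = int(np.ceil(np.quantile(maxima, 0.99)))
        assert abs(k - oracle) <= 1

    def test_small_sim_count_warns(self):
        with pytest.warns(UserWarning):
            mc_cluster_threshold((8, 8, 4), 3.0, 3.0, n_sims=50, seed=0)

    def test_fwhm_below_voxel_rejected(self):
        with pytest.raises(ValueError):
            mc_cluster_threshold((8, 8, 4), 3.0, 1.0, n_sims=100)


class TestConjunction:
    def test_disjoint_empty_and_identity(self):
        a = np.array([[1, 0], [0, -1]])
        b = np.array([[0, 1], [1, 0]])
        assert conjunction(a, b).sum() == 0
        np.testing.assert_array_equal(conjunction(a, a), a)

    def test_planted_overlap_size(self):
        rng = np.random.default_rng(0)
        a = np.zeros((6, 6, 6), dtype=int)
        b = np.zeros((6, 6, 6), dtype=int)
        a[:3] = 1
        b[2:4] = 1
        b[5, 5, 5] = -1
        a[5, 5, 5] = -1
        out = conjunction(a, b)
        assert (out == 1).sum() == 36  # the z-slab overlap
        assert out[5, 5, 5] == -1

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            conjunction(np.zeros((2, 2)), np.zeros((3, 3)))


class TestRoiFirstPC:
    def test_identical_voxels_return_standardized_series(self):
        t = np.linspace(0, 10, 200)
        s = np.sin(t)
        block = np.tile(s, (5, 1))
        pc = roi_first_pc(block)
        z = (s - s.mean()) / (s - s.mean()).std()
        np.testing.assert_allclose(pc, z, atol=1e-8)

    def test_dominant_group_sets_sign(self):
        """With anti-correlated voxel groups, PC1 follows the majority."""
        rng = np.random.default_rng(6)
        s = rng.standard_normal(300)
        block = np.vstack([np.tile(s, (7, 1)), np.tile(-s, (2, 1))])
        block += 0.01 * rng.standard_normal(block.shape)
        pc = roi_first_pc(block)
        z = (s - s.mean()) / s.std()
        assert np.corrcoef(pc, z)[0, 1] > 0.99

    def test_pc1_dominates_variance(self):
        rng = np.random.default_rng(7)
        block = rng.standard_normal((12, 400))
        pc = roi_first_pc(block)
        Bc = block - block.mean(axis=1, keepdims=True)
        s = np.linalg.svd(Bc, compute_uv=False)
        assert s[0] >= s[1]

    def test_constant_block_rejected(self):
        with pytest.raises(ValueError):
            roi_first_pc(np.ones((4, 100)))
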