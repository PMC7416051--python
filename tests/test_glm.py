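"""Design-matrix construction, OLS, contrasts, eigenvariate, sign-flip test."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gamma as gamma_dist
from scipy.stats import kstest

from meridian import glm, synthetic
from meridian.constants import CONDITIONS, NODES


@pytest.fixture(scope="module")
def desk_events(desk_design_pair):
    return pd.concat(desk_design_pair, ignore_index=True)


@pytest.fixture(scope="module")
def desk_design(desk_events, desk_spec):
    return glm.build_design_matrix(
        desk_events, n_volumes=desk_spec.volumes_per_run, tr=desk_spec.tr_seconds
    )


def spm_hrf_dense(t):
    """Direct double-gamma canonical HRF on a dense grid (peak 6, undershoot 16)."""
    h = gamma_dist.pdf(t, 6) - gamma_dist.pdf(t, 16) / 6.0
    return h


class TestDesignMatrix:
    def test_eight_condition_regressors_across_runs(self, desk_design):
        assert desk_design.condition_columns == list(CONDITIONS)

    def test_single_run_column_count(self, desk_design_pair, desk_spec):
        seq_h = desk_design_pair[0]
        dm = glm.build_design_matrix(
            seq_h, n_volumes=desk_spec.volumes_per_run, tr=desk_spec.tr_seconds
        )
        # 4 horizontal conditions + drift set + constant
        n_drift = len(
            [c for c in dm.columns if c.startswith("drift")]
        )
        assert len(dm.columns) == 4 + n_drift + 1
        assert n_drift >= 1

    def test_hrf_peak_near_dense_convolution_oracle(self, desk_spec):
        events = pd.DataFrame(
            {"run": ["horizontal"], "onset": [0.0], "trial_type": ["vL"], "cueing": ["valid"]}
        )
        dm = glm.build_design_matrix(events, n_volumes=40, tr=desk_spec.tr_seconds)
        reg = dm.frame["vL"].to_numpy()
        t_dense = np.arange(0, 40 * 2.2, 0.01)
        oracle_peak = t_dense[np.argmax(spm_hrf_dense(t_dense))]
        sample_peak = np.argmax(reg) * desk_spec.tr_seconds
        assert abs(sample_peak - oracle_peak) <= desk_spec.tr_seconds

    def test_superposition_of_identical_events(self):
        one = pd.DataFrame(
            {"run": ["horizontal"], "onset": [11.0], "trial_type": ["iL"]}
        )
        two = pd.concat([one, one], ignore_index=True)
        d1 = glm.build_design_matrix(one, n_volumes=40, tr=2.2)
        d2 = glm.build_design_matrix(two, n_volumes=40, tr=2.2)
        assert np.allclose(d2.frame["iL"], 2 * d1.frame["iL"], atol=1e-10)

    def test_drift_columns_orthonormal_within_run(self, desk_design):
        drifts = [c for c in desk_design.columns if c.startswith("drift")]
        h_cols = [c for c in drifts if c.endswith("_h")]
        M = desk_design.frame[h_cols].to_numpy()
        M = M[: len(M) // 2]  # horizontal run rows
        gram = M.T @ M
        assert np.allclose(gram, np.eye(len(h_cols)), atol=1e-8)

    def test_event_beyond_scan_end_raises(self):
        events = pd.DataFrame(
            {"run": ["horizontal"], "onset": [500.0], "trial_type": ["vL"]}
        )
        with pytest.raises(ValueError, match="beyond"):
            glm.build_design_matrix(events, n_volumes=40, tr=2.2)


class TestFitGlm:
    def test_exact_regression_on_design_column(self, desk_design):
        X = desk_design.frame
        ts = np.tile(X["iL"].to_numpy()[:, None], (1, 6))
        res = glm.fit_glm(ts, desk_design)
        assert np.allclose(res.betas["iL"], 1.0, atol=1e-8)
        other = [c for c in CONDITIONS if c != "iL"]
        assert np.allclose(res.betas[other], 0.0, atol=1e-8)

    def test_constant_shift_moves_only_intercepts(self, desk_design, rng):
        ts = rng.normal(size=(len(desk_design.frame), 6))
        r1 = glm.fit_glm(ts, desk_design)
        r2 = glm.fit_glm(ts + 5.0, desk_design)
        const_cols = [c for c in desk_design.columns if c.startswith("constant")]
        var_cols = [c for c in desk_design.columns if c not in const_cols]
        assert np.allclose(r1.betas[var_cols], r2.betas[var_cols], atol=1e-8)
        assert not np.allclose(r1.betas[const_cols], r2.betas[const_cols])

    def test_betas_track_injected_condition_amplitudes(self, desk_design_pair, desk_spec):
        """Noiseless BOLD from the generator: invalid-condition betas exceed
        valid ones in modulated nodes, and betas correlate with the
        injected input weights across conditions."""
        truth = synthetic.default_ground_truth(snr=None, noise_sd=0.0)
        bold, _ = synthetic.generate_bold(
            desk_design_pair, truth, spec=desk_spec, seed=0
        )
        events = pd.concat(desk_design_pair, ignore_index=True)
        design = glm.build_design_matrix(
            events, n_volumes=desk_spec.volumes_per_run, tr=desk_spec.tr_seconds
        )
        res = glm.fit_glm(bold, design)
        # all conditions driven equally; invalid trials additionally amplified
        # through B1/B3 at IPS_L (the modulated target node)
        ips_l = res.betas.loc["IPS_L"]
        assert ips_l[["iL", "iR"]].mean() > ips_l[["vL", "vR"]].mean()
        assert (res.betas[list(CONDITIONS)].to_numpy() > 0).all()

    def test_rank_deficiency_warns_and_uses_pinv(self, desk_design, caplog):
        X = desk_design.frame.copy()
        X["dup"] = X["iL"]
        design2 = glm.DesignMatrix(
            frame=X, condition_columns=desk_design.condition_columns,
            run_columns=desk_design.run_columns,
        )
        with caplog.at_level("WARNING"):
            res = glm.fit_glm(np.zeros((len(X), 6)), design2)
        assert res.rank_deficient
        assert "rank deficient" in caplog.text


class TestContrasts:
    def test_equal_betas_zero_difference_contrasts(self):
        betas = pd.DataFrame(1.0, index=list(NODES), columns=list(CONDITIONS))
        for name in ("main_cueing", "horiz_reorient", "vert_reorient",
                     "main_direction", "interaction"):
            assert np.allclose(glm.apply_contrast(betas, name), 0.0)

    def test_main_cueing_weight_sum(self):
        betas = pd.DataFrame(0.0, index=list(NODES), columns=list(CONDITIONS))
        betas[["iL", "iR", "iD", "iU"]] = 1.0
        assert np.allclose(glm.apply_contrast(betas, "main_cueing"), 4.0)

    def test_main_effect_is_sum_of_run_contrasts(self, rng):
        betas = pd.DataFrame(
            rng.normal(size=(6, 8)), index=list(NODES), columns=list(CONDITIONS)
        )
        total = glm.apply_contrast(betas, "main_cueing")
        parts = glm.apply_contrast(betas, "horiz_reorient") + glm.apply_contrast(
            betas, "vert_reorient"
        )
        assert np.allclose(total, parts)

    def test_cueing_effect_localizes_to_modulated_nodes(self, rng):
        betas = pd.DataFrame(1.0, index=list(NODES), columns=list(CONDITIONS))
        betas.loc["TPJ_L", ["iL", "iR", "iD", "iU"]] += 2.0
        betas.loc["TPJ_R", ["iL", "iR", "iD", "iU"]] += 2.0
        con = glm.apply_contrast(betas, "main_cueing")
        assert set(con.nlargest(2).index) == {"TPJ_L", "TPJ_R"}


class TestCollapse:
    def test_simple_average(self):
        betas = pd.DataFrame({"iL": [2.0], "iR": [4.0], "vL": [1.0], "vR": [1.0],
                              "iD": [0.0], "iU": [0.0], "vD": [0.0], "vU": [0.0]})
        out = glm.collapse_betas(betas)
        assert np.isclose(out["invalid_horizontal"].iloc[0], 3.0)

    def test_idempotent(self, rng):
        betas = pd.DataFrame(
            rng.normal(size=(6, 8)), index=list(NODES), columns=list(CONDITIONS)
        )
        once = glm.collapse_betas(betas)
        twice = glm.collapse_betas(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_collapse_commutes_with_contrast(self, rng):
        betas = pd.DataFrame(
            rng.normal(size=(6, 8)), index=list(NODES), columns=list(CONDITIONS)
        )
        coll = glm.collapse_betas(betas)
        lhs = (coll["invalid_horizontal"] + coll["invalid_vertical"]) - (
            coll["valid_horizontal"] + coll["valid_vertical"]
        )
        rhs = glm.apply_contrast(betas, "main_cueing") / 2.0
        assert np.allclose(lhs, rhs)


class TestEigenvariate:
    def test_identical_voxels_recover_common_series(self, rng):
        series = rng.normal(size=200)
        roi = np.tile(series, (15, 1))
        out = glm.eigenvariate(roi)
        c = np.corrcoef(out, series)[0, 1]
        assert c > 0.999999
        assert np.isclose(out.std(), roi.std(axis=1).mean())

    def test_dominant_group_wins_svd_oracle(self, rng):
        base = rng.normal(size=300)
        big = np.array([base + 0.05 * rng.normal(size=300) for _ in range(12)])
        small = np.array([-base + 0.05 * rng.normal(size=300) for _ in range(3)])
        roi = np.concatenate([big, small])
        out = glm.eigenvariate(roi)
        # svd oracle: first right singular vector of the centered matrix
        centered = roi - roi.mean(axis=1, keepdims=True)
        v = np.linalg.svd(centered, full_matrices=False)[2][0]
        assert abs(np.corrcoef(out, v)[0, 1]) > 0.999
        # sign aligned with the dominant (positive-loading) group
        assert np.corrcoef(out, base)[0, 1] > 0.99

    def test_orthogonal_noise_voxels_leave_component(self, rng):
        base = rng.normal(size=400)
        roi = np.array([base * w for w in (1.0, 0.9, 1.1, 1.0)])
        noise = rng.normal(size=(4, 400)) * 0.5
        noise -= noise @ base[:, None] * base[None] / (base @ base)  # orthogonalize
        out1 = glm.eigenvariate(roi)
        out2 = glm.eigenvariate(np.concatenate([roi, noise]))
        assert abs(np.corrcoef(out1, out2)[0, 1]) > 0.98


class TestSignFlip:
    def test_full_enumeration_exact_p(self):
        p = glm.signflip_ttest(np.full(10, 0.7), n_permutations=25_000)
        assert np.isclose(p, 2 / 2**10)

    def test_p_bounds(self, rng):
        for _ in range(5):
            v = rng.normal(size=25)
            p = glm.signflip_ttest(v, n_permutations=400, seed=3)
            assert 1 / 401 <= p <= 1.0

    def test_calibration_under_symmetric_null(self):
        """p-values are approximately uniform for symmetric zero-mean data."""
        rng = np.random.default_rng(77)
        ps = [
            glm.signflip_ttest(rng.normal(size=30), n_permutations=250, seed=k)
            for k in range(200)
        ]
        assert kstest(ps, "uniform").pvalue > 0.01
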