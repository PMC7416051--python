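"""Design, behavior and BOLD generators: counts, invariants, oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meridian import dcm, synthetic
from meridian.constants import HORIZONTAL, NODES, VERTICAL


class TestDesign:
    def test_block_counts_and_validity(self):
        spec = synthetic.DesignSpec(seed=4)
        seq = synthetic.generate_design(spec, HORIZONTAL)
        per_block = seq.groupby("block")["cueing"].apply(lambda s: (s == "invalid").sum())
        assert (per_block == 8).all()
        assert (seq.groupby("block").size() == 40).all()
        assert np.isclose((seq["cueing"] == "valid").mean(), 0.80)
        assert len(seq) == 200

    def test_condition_labels_partition_trials(self):
        seq = synthetic.generate_design(synthetic.DesignSpec(seed=0), HORIZONTAL)
        counts = seq["trial_type"].value_counts()
        assert set(counts.index) == {"iL", "iR", "vL", "vR"}
        assert counts.sum() == 200

    def test_positions_match_run(self):
        spec = synthetic.DesignSpec(seed=1)
        assert set(synthetic.generate_design(spec, HORIZONTAL)["position"]) == {"L", "R"}
        assert set(synthetic.generate_design(spec, VERTICAL)["position"]) == {"D", "U"}

    def test_target_property_cells_balanced_within_block(self):
        seq = synthetic.generate_design(synthetic.DesignSpec(seed=2), VERTICAL)
        for _, block in seq.groupby("block"):
            cells = block.groupby(["position", "finger", "soa_ms"]).size()
            assert len(cells) == 8
            assert (cells == 5).all()

    def test_onsets_strictly_increasing_and_fit_run(self):
        spec = synthetic.DesignSpec(seed=9)
        seq = synthetic.generate_design(spec, HORIZONTAL)
        assert (np.diff(seq["onset"]) > 0).all()
        assert seq["onset"].iloc[-1] + 0.25 + seq["iti_s"].iloc[-1] <= spec.run_duration

    def test_degenerate_single_invalid_block(self):
        spec = synthetic.DesignSpec(
            blocks_per_run=1, valid_per_block=0, invalid_per_block=8, seed=0
        )
        seq = synthetic.generate_design(spec, HORIZONTAL)
        assert len(seq) == 8
        assert (seq["cueing"] == "invalid").all()
        assert (np.diff(seq["onset"]) > 0).all()

    def test_infeasible_timing_raises(self):
        spec = synthetic.DesignSpec(volumes_per_run=30, seed=0)
        with pytest.raises(ValueError, match="infeasible"):
            synthetic.generate_design(spec, HORIZONTAL)

    def test_deterministic_given_seed(self):
        spec = synthetic.DesignSpec(seed=7)
        a = synthetic.generate_design(spec, HORIZONTAL)
        b = synthetic.generate_design(spec, HORIZONTAL)
        pd.testing.assert_frame_equal(a, b)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_counts_exact_for_every_seed(self, seed):
        seq = synthetic.generate_design(synthetic.DESK_SPEC, VERTICAL, seed=seed)
        assert (seq["cueing"] == "valid").mean() == 0.8
        assert (np.diff(seq["onset"]) > 0).all()

    def test_events_tsv_roundtrip(self, tmp_path, behavior_record):
        path = tmp_path / "events.tsv"
        synthetic.write_events(behavior_record, path)
        back = synthetic.read_events(path)
        assert len(back) == len(behavior_record)
        assert np.allclose(back["onset"], behavior_record["onset"])


class TestBehavior:
    def _many_trials(self, n_blocks, **kwargs):
        spec = synthetic.DesignSpec(
            volumes_per_run=60 * n_blocks, blocks_per_run=n_blocks, seed=0
        )
        # timing feasibility is irrelevant here; build trials directly
        rows = []
        for b in range(n_blocks):
            for k in range(40):
                rows.append(
                    {
                        "run": HORIZONTAL,
                        "block": b,
                        "onset": b * 300 + k * 6.0,
                        "cueing": "invalid" if k % 5 == 0 else "valid",
                        "position": "L" if k % 2 else "R",
                        "finger": k % 2,
                        "trial_type": "iL",
                    }
                )
        return pd.DataFrame(rows)

    def test_invalidity_cost_recovered(self):
        seq = self._many_trials(250)  # 10,000 trials
        params = synthetic.BehaviorParams(
            invalidity_cost_ms=50.0, error_prob=0.0, miss_prob=0.0, seed=42
        )
        rec = synthetic.generate_behavior(seq, params)
        med = rec.groupby("cueing")["rt_ms"].median()
        assert abs((med["invalid"] - med["valid"]) - 50.0) < 5.0

    def test_null_generator_has_no_cueing_effect(self):
        seq = self._many_trials(250)
        params = synthetic.BehaviorParams(
            invalidity_cost_ms=0.0, error_prob=0.0, miss_prob=0.0, seed=7
        )
        rec = synthetic.generate_behavior(seq, params)
        med = rec.groupby("cueing")["rt_ms"].median()
        assert abs(med["invalid"] - med["valid"]) < 6.0

    def test_error_rate_binomial(self):
        seq = self._many_trials(250)
        params = synthetic.BehaviorParams(error_prob=0.05, miss_prob=0.0, seed=3)
        rec = synthetic.generate_behavior(seq, params)
        rate = 1.0 - rec["correct"].mean()
        assert 0.04 < rate < 0.06

    def test_rts_positive_and_missed_nan(self, behavior_record):
        ok = behavior_record["rt_ms"].dropna()
        assert (ok > 0).all()
        assert behavior_record.loc[behavior_record["missed"], "rt_ms"].isna().all()

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError, match="empty"):
            synthetic.generate_behavior(pd.DataFrame(), synthetic.BehaviorParams())


class TestBold:
    def test_zero_input_zero_noise_gives_zero(self, desk_design_pair, desk_spec):
        truth = synthetic.default_ground_truth(
            b_strength=0.0, snr=None, noise_sd=0.0, driving_weight=0.0
        )
        bold, _ = synthetic.generate_bold(desk_design_pair, truth, spec=desk_spec, seed=0)
        assert np.allclose(bold.to_numpy(), 0.0, atol=1e-12)

    def test_noiseless_matches_simulator(self, desk_design_pair, desk_spec):
        truth = synthetic.default_ground_truth(snr=None, noise_sd=0.0)
        bold, inputs = synthetic.generate_bold(desk_design_pair, truth, spec=desk_spec, seed=0)
        direct = dcm.simulate_bold(truth.model, inputs, sampling_offset=truth.sampling_offset)
        assert np.allclose(bold.to_numpy(), direct, atol=1e-14)

    def test_doubling_noise_sd_doubles_residual_sd(self, desk_design_pair, desk_spec):
        t0 = synthetic.default_ground_truth(snr=None, noise_sd=0.0)
        clean, _ = synthetic.generate_bold(desk_design_pair, t0, spec=desk_spec, seed=0)
        sds = []
        for sd in (0.01, 0.02):
            t = synthetic.default_ground_truth(snr=None, noise_sd=sd)
            noisy, _ = synthetic.generate_bold(desk_design_pair, t, spec=desk_spec, seed=5)
            sds.append((noisy.to_numpy() - clean.to_numpy()).std())
        ratio = sds[1] / sds[0]
        assert abs(ratio - 2.0) < 0.2

    def test_voxel_expansion_mean_recovers_node_signal(self, desk_design_pair, desk_spec):
        truth = synthetic.default_ground_truth(snr=None, noise_sd=0.0)
        truth.voxels_per_node = 60
        truth.voxel_noise_sd = 0.01
        bold, _, voxels = synthetic.generate_bold(
            desk_design_pair, truth, spec=desk_spec, seed=2, return_voxels=True
        )
        for node in NODES:
            mean_series = voxels[node].mean(axis=0)
            resid = mean_series - bold[node].to_numpy()
            # mean of independent voxel noise shrinks as 1/sqrt(V)
            assert resid.std() < 2.5 * 0.01 / np.sqrt(60)

    def test_unstable_truth_raises_naming_eigenvalue(self, desk_design_pair, desk_spec):
        truth = synthetic.default_ground_truth(snr=None)
        truth.model.a[0, 0] = 1.0  # positive self-connection -> unstable
        with pytest.raises(ValueError, match="eigenvalue"):
            synthetic.generate_bold(desk_design_pair, truth, spec=desk_spec, seed=0)

    def test_timeseries_tsv_roundtrip(self, tmp_path, desk_bold):
        bold, _ = desk_bold
        path = tmp_path / "bold.tsv"
        synthetic.write_timeseries(bold, path)
        back = synthetic.read_timeseries(path)
        assert list(back.columns) == list(NODES)
        assert np.allclose(back.to_numpy(), bold.to_numpy())
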