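"""High-pass filtering, nuisance regression, scrubbing, and LS2 estimation."""

import numpy as np
import pytest

from seqpos import bold, design, glm
from seqpos.bold import EffectConfig, NoiseSpec, sample_patterns, simulate_run
from seqpos.design import CombinationScheme, EventOccurrence, combine_occurrences
from seqpos.glm import (
    GLMConfig,
    ScrubConfig,
    build_event_regressor,
    build_nuisance_matrix,
    dct_highpass_basis,
    estimate_betas_ls2,
    flag_exclusion,
    flag_scans,
    highpass_filter,
)

SILENT = NoiseSpec(thermal_sd=0.0, ar1_coefficient=0.0, drift_amplitude=0.0,
                   cardiac_amplitude=0.0, respiratory_amplitude=0.0,
                   motion_spike_rate=0.0, motion_walk_sd_mm=0.0)


# ---------------------------------------------------------------------------
# discrete-cosine high-pass
# ---------------------------------------------------------------------------

class TestHighpass:
    def test_basis_size_follows_cutoff(self):
        B = dct_highpass_basis(n_frames=756, tr_s=1.75, cutoff_s=128.0)
        assert B.shape == (756, int(np.floor(2 * 756 * 1.75 / 128.0)))

    def test_basis_orthonormal(self):
        B = dct_highpass_basis(400, 1.75, 128.0)
        assert np.allclose(B.T @ B, np.eye(B.shape[1]), atol=1e-10)

    def test_filter_is_projection(self):
        rng = np.random.default_rng(0)
        B = dct_highpass_basis(300, 1.75, 128.0)
        X = rng.standard_normal((300, 5))
        once = highpass_filter(X, B)
        assert np.allclose(highpass_filter(once, B), once, atol=1e-10)

    def test_removes_drift_span_and_passes_task_frequencies(self):
        B = dct_highpass_basis(600, 1.75, 128.0)
        rng = np.random.default_rng(1)
        in_span = B @ rng.standard_normal((B.shape[1], 3))
        assert np.abs(highpass_filter(in_span, B)).max() < 1e-10
        t = np.arange(600) * 1.75
        fast = np.sin(2 * np.pi * t / 20.0)[:, None]  # 20-s task-band signal
        kept = highpass_filter(fast, B)
        assert np.linalg.norm(kept) / np.linalg.norm(fast) > 0.95

    def test_cutoff_must_exceed_two_tr(self):
        with pytest.raises(ValueError):
            GLMConfig(highpass_cutoff_s=3.0).validate(tr_s=1.75)


# ---------------------------------------------------------------------------
# scrubbing and nuisance matrix
# ---------------------------------------------------------------------------

def _still_run(geometry, n_frames=750):
    """A structurally valid run with constant data and zero motion."""
    data = np.zeros(geometry.shape + (n_frames,))
    data[geometry.mask] = 100.0
    ts = np.arange(0, n_frames * 1.75 + 1, 0.05)
    trace = np.column_stack([ts, np.sin(ts)])
    return bold.BOLDRun(
        data=data, geometry=geometry, tr_s=1.75,
        motion_params=np.zeros((n_frames, 6)),
        cardiac_trace=trace.copy(), respiratory_trace=trace.copy(),
        truth=None)


class TestScrubbing:
    def test_no_exceedance_gives_motion_plus_physio_only(self, small_geometry):
        run = _still_run(small_geometry)
        N, names = build_nuisance_matrix(run)
        assert N.shape == (750, 8)
        assert sum(n.startswith("spike") for n in names) == 0

    def test_spike_columns_are_one_hot_and_orthogonal(self, small_geometry):
        run = _still_run(small_geometry)
        for t in (100, 200, 300):
            run.motion_params[t:, 0] += 1.0  # 1-mm jumps
        N, names = build_nuisance_matrix(run)
        spikes = N[:, [i for i, n in enumerate(names) if n.startswith("spike")]]
        assert spikes.shape[1] == 3
        assert np.all(spikes.sum(axis=0) == 1.0)
        assert np.allclose(spikes.T @ spikes, np.eye(3))

    def test_image_diff_criterion(self, small_geometry):
        run = _still_run(small_geometry)
        run.data[small_geometry.mask, 400] += 25.0  # gross image artifact
        flags = flag_scans(run)
        assert flags[400] and flags[401]
        assert flags.sum() == 2

    def test_exclusion_rule_boundaries(self, small_geometry):
        run = _still_run(small_geometry, n_frames=750)
        assert flag_exclusion(run) == ("keep", 0.0)
        # 76 flagged of 750 = 10.13% -> exclude (each persistent 1-mm jump
        # produces exactly one inter-scan exceedance)
        for t in range(10, 10 + 3 * 76, 3):
            run.motion_params[t:, 1] += 1.0
        decision, frac = flag_exclusion(run)
        assert frac == pytest.approx(76 / 750)
        assert decision == "exclude"

    def test_exactly_ten_percent_is_kept(self, small_geometry):
        run = _still_run(small_geometry, n_frames=750)
        for t in range(10, 10 + 3 * 75, 3):
            run.motion_params[t:, 1] += 1.0
        decision, frac = flag_exclusion(run)
        assert frac == pytest.approx(0.10)
        assert decision == "keep"

    def test_constant_motion_logged(self, small_geometry, caplog):
        run = _still_run(small_geometry)
        with caplog.at_level("WARNING"):
            build_nuisance_matrix(run)
        assert any("constant" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# event regressors
# ---------------------------------------------------------------------------

def _occ(onset):
    return EventOccurrence(trial_index=0, phase="presentation",
                           stimulus_set="houses", identity="A", position=1,
                           onset_s=onset, valid=True)


class TestEventRegressor:
    def test_empty_occurrences_give_zero_column(self):
        ft = np.arange(100) * 1.75
        assert not build_event_regressor([], ft).any()

    def test_linearity_over_occurrences(self):
        ft = np.arange(200) * 1.75
        singles = sum(build_event_regressor([_occ(t)], ft)
                      for t in (20.0, 120.0, 250.0))
        combined = build_event_regressor([_occ(20.0), _occ(120.0), _occ(250.0)], ft)
        assert np.allclose(combined, singles, atol=1e-12)

    def test_onset_beyond_run_rejected(self):
        ft = np.arange(100) * 1.75
        with pytest.raises(ValueError):
            build_event_regressor([_occ(500.0)], ft)


# ---------------------------------------------------------------------------
# LS2 estimation
# ---------------------------------------------------------------------------

def _spaced_regressor_set(n_events=5, spacing=80.0):
    """Events with disjoint HRF supports: one single-occurrence regressor each."""
    occs = []
    for i in range(n_events):
        occs.append(EventOccurrence(
            trial_index=i, phase="presentation", stimulus_set="houses",
            identity="ABC"[i % 3], position=i % 3 + 1,
            onset_s=30.0 + i * spacing, valid=True))
    return combine_occurrences(occs, CombinationScheme(n_per_regressor=1), seed=0)


def _run_from_signal(geometry, Y_masked, tr=1.75):
    data = np.zeros(geometry.shape + (Y_masked.shape[0],))
    data[geometry.mask] = Y_masked.T
    T = Y_masked.shape[0]
    ts = np.arange(0, T * tr + 1, 0.05)
    trace = np.column_stack([ts, np.zeros_like(ts)])
    return bold.BOLDRun(data=data, geometry=geometry, tr_s=tr,
                        motion_params=np.zeros((T, 6)),
                        cardiac_trace=trace.copy(),
                        respiratory_trace=trace.copy(), truth=None)


class TestLS2:
    def test_ls2_matches_joint_glm_under_orthogonality(self, small_geometry):
        """With disjoint-support events sharing a per-voxel amplitude and zero
        noise, the separate-GLM betas equal the joint-GLM betas exactly.

        The joint fit is recomputed here by brute force (direct lstsq on the
        full design) as an independent oracle."""
        rs = _spaced_regressor_set()
        T = 300
        ft = np.arange(T) * 1.75
        E = np.column_stack([
            build_event_regressor(r.occurrences, ft) for r in rs.regressors])
        rng = np.random.default_rng(0)
        V = small_geometry.n_mask_voxels
        amp = rng.uniform(0.5, 2.0, size=V)          # one amplitude per voxel
        Y = np.outer(E.sum(axis=1), amp) + 7.0       # + constant baseline
        run = _run_from_signal(small_geometry, Y)

        cfg = GLMConfig(include_motion=False, include_physio=False,
                        include_spikes=False)
        ls2 = estimate_betas_ls2(run, rs, cfg, enforce_exclusion=False)

        B = dct_highpass_basis(T, 1.75, cfg.highpass_cutoff_s)
        X = np.column_stack([highpass_filter(E, B), np.ones((T, 1))])
        joint = np.linalg.lstsq(X, highpass_filter(Y, B), rcond=None)[0][:5]
        assert np.allclose(ls2.betas, joint, rtol=1e-8, atol=1e-10)
        assert np.allclose(ls2.betas, amp[None, :], rtol=1e-6)

    def test_replicated_design_yields_69_beta_rows(self, shared_betas):
        assert shared_betas.n_regressors == 69
        counts = shared_betas.labels["phase"].value_counts().to_dict()
        assert counts == {"presentation": 42, "recognition": 27}

    def test_all_zero_data_gives_zero_betas(self, small_geometry):
        rs = _spaced_regressor_set()
        run = _run_from_signal(small_geometry,
                               np.zeros((300, small_geometry.n_mask_voxels)))
        cfg = GLMConfig(include_motion=False, include_physio=False,
                        include_spikes=False)
        betas = estimate_betas_ls2(run, rs, cfg, enforce_exclusion=False)
        assert np.allclose(betas.betas, 0.0, atol=1e-12)

    def test_noiseless_pattern_recovery_sparse_design(self, small_geometry):
        """With well-separated events and zero noise, every beta map
        correlates > 0.99 with its event's injected composite pattern."""
        d = design.generate_design(seed=2, n_trials=30,
                                   length_distribution={1: 1.0},
                                   probed_fraction=0.0, n_changed_probes=0,
                                   rest_range_s=(20.0, 30.0))
        rs = combine_occurrences(design.enumerate_occurrences(d), seed=2)
        eff = EffectConfig(sharing_mode="shared", position_amplitude=1.0,
                           identity_amplitude=0.5)
        truth = sample_patterns(small_geometry, eff, seed=3)
        run = simulate_run(d, small_geometry, truth, SILENT, seed=0)
        betas = estimate_betas_ls2(run, rs, enforce_exclusion=False)
        rid = small_geometry.region_ids[0]
        rows = small_geometry.region_rows(rid)
        for r_idx in range(betas.n_regressors):
            lbl = betas.labels.iloc[r_idx]
            expected = (truth.position_patterns[(rid, lbl.position, lbl.phase)]
                        + 0.5 * truth.identity_patterns[(rid, lbl.identity)])
            got = betas.betas[r_idx, rows]
            assert np.corrcoef(got, expected)[0, 1] > 0.99

    def test_noiseless_recovery_rapid_design(self, small_geometry,
                                             preset_design, preset_regressors):
        """On the rapid replicated design the separate-GLM pooling leaves some
        cross-talk between temporally adjacent events; class-mean beta maps
        still track the injected positional patterns strongly."""
        eff = EffectConfig(sharing_mode="shared", position_amplitude=1.0,
                           identity_amplitude=0.5)
        truth = sample_patterns(small_geometry, eff, seed=3)
        run = simulate_run(preset_design, small_geometry, truth, SILENT, seed=0)
        betas = estimate_betas_ls2(run, preset_regressors,
                                   enforce_exclusion=False)
        rid = small_geometry.region_ids[0]
        rows = small_geometry.region_rows(rid)
        lab = betas.labels
        for phase in ("presentation", "recognition"):
            for pos in (1, 2, 3):
                sel = ((lab["phase"] == phase)
                       & (lab["position"] == pos)).to_numpy()
                mean_beta = betas.betas[sel][:, rows].mean(axis=0)
                expected = truth.position_patterns[(rid, pos, phase)]
                assert np.corrcoef(mean_beta, expected)[0, 1] > 0.8

    def test_excluded_participant_rejected(self, small_geometry):
        rs = _spaced_regressor_set()
        run = _run_from_signal(small_geometry,
                               np.zeros((300, small_geometry.n_mask_voxels)))
        run.motion_params[::5, 0] = np.arange(60)  # wild motion
        with pytest.raises(ValueError, match="excluded"):
            estimate_betas_ls2(run, rs)

    def test_rank_deficiency_reported(self, small_geometry):
        # two identical regressors make every LS2 design singular
        occs = [_occ(30.0), _occ(30.0)]
        rs = combine_occurrences(occs, CombinationScheme(n_per_regressor=1),
                                 seed=0)
        run = _run_from_signal(small_geometry,
                               np.zeros((200, small_geometry.n_mask_voxels)))
        cfg = GLMConfig(include_motion=False, include_physio=False,
                        include_spikes=False)
        with pytest.raises(np.linalg.LinAlgError, match="rank-deficient"):
            estimate_betas_ls2(run, rs, cfg, enforce_exclusion=False)
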