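"""Searchlights, pattern normalization, and position classification."""

import numpy as np
import pytest

from seqpos import bold
from seqpos.mvpa import (
    MVPAConfig,
    OneVsOneSVM,
    build_searchlights,
    classify_cross_phase,
    classify_within_phase,
    run_searchlight,
    sphere_offsets,
    zscore_patterns,
)


# ---------------------------------------------------------------------------
# searchlight geometry
# ---------------------------------------------------------------------------

def brute_force_members(center, radius_mm, voxel_size, shape, mask):
    """Independent oracle: exhaustive scan of the whole lattice."""
    out = []
    vs = np.asarray(voxel_size)
    for idx in np.ndindex(*shape):
        if not mask[idx]:
            continue
        d2 = (((np.array(idx) - center) * vs) ** 2).sum()
        if d2 <= radius_mm ** 2 + 1e-9:
            out.append(idx)
    return sorted(out)


class TestSearchlights:
    def test_full_grid_membership_matches_brute_force(self):
        # 6-mm sphere on a 2-mm isotropic grid, centre deep inside: the
        # lattice contains 123 points with squared voxel distance <= 9
        g = bold.make_geometry(shape=(13, 13, 13), seed=0, n_regions=0,
                               mask_fraction=1.0)
        sls = build_searchlights(g, MVPAConfig())
        centre = (6, 6, 6)
        sl = next(s for s in sls if s.center_voxel == centre)
        assert sl.n_in_mask == 123
        oracle = brute_force_members(np.array(centre), 6.0, (2, 2, 2),
                                     g.shape, g.mask)
        got = sorted(map(tuple, g.mask_coords[sl.member_rows]))
        assert got == oracle

    def test_radius_below_voxel_size_gives_singleton(self):
        g = bold.make_geometry(shape=(6, 6, 6), seed=0, n_regions=0,
                               mask_fraction=1.0)
        sls = build_searchlights(g, MVPAConfig(radius_mm=1.0, min_voxels=1))
        assert all(s.n_in_mask == 1 for s in sls)

    def test_corner_centre_is_truncated(self):
        g = bold.make_geometry(shape=(13, 13, 13), seed=0, n_regions=0,
                               mask_fraction=1.0)
        sls = build_searchlights(g, MVPAConfig())
        corner = next(s for s in sls if s.center_voxel == (0, 0, 0))
        assert corner.n_in_mask < 123

    def test_offsets_respect_anisotropic_voxels(self):
        offs = sphere_offsets(6.0, (2.0, 2.0, 4.0))
        d2 = ((offs * np.array([2.0, 2.0, 4.0])) ** 2).sum(axis=1)
        assert d2.max() <= 36.0 + 1e-9
        assert np.abs(offs[:, 2]).max() == 1

    def test_empty_mask_rejected(self):
        g = bold.make_geometry(shape=(5, 5, 5), seed=0, n_regions=0,
                               mask_fraction=1.0)
        g.mask[:] = False
        with pytest.raises(ValueError):
            build_searchlights(g)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestZScore:
    def test_column_statistics(self):
        rng = np.random.default_rng(0)
        Z = zscore_patterns(rng.standard_normal((20, 15)) * 3 + 5)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-6)
        assert np.allclose(Z.std(axis=0), 1.0, atol=1e-6)

    def test_constant_column_zeroed(self):
        X = np.random.default_rng(1).standard_normal((10, 4))
        X[:, 2] = 7.0
        Z = zscore_patterns(X, remove_uniform=False)
        assert np.allclose(Z[:, 2], 0.0)

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            zscore_patterns(np.ones((1, 5)))

    def test_uniform_per_item_signal_removed(self):
        # a per-item offset applied to all voxels vanishes entirely
        rng = np.random.default_rng(2)
        offsets = rng.standard_normal(12)
        X = np.tile(offsets[:, None], (1, 30))
        Z = zscore_patterns(X)
        assert np.allclose(Z, 0.0)


def test_pure_load_signal_classifies_at_chance():
    """A signal that scales all voxels uniformly with position (memory-load
    analogue) carries no decodable information after normalization."""
    rng = np.random.default_rng(7)
    cfg = MVPAConfig()
    y_tr = np.repeat([1, 2, 3], 12)
    y_te = np.repeat([1, 2, 3], 6)
    accs = []
    for _ in range(150):
        load_tr = y_tr[:, None] * np.ones((1, 60)) * 2.0
        load_te = y_te[:, None] * np.ones((1, 60)) * 2.0
        Xtr = load_tr + rng.standard_normal((36, 60))
        Xte = load_te + rng.standard_normal((18, 60))
        acc, _, _ = classify_cross_phase(Xtr, y_tr, Xte, y_te, cfg, seed=0)
        accs.append(acc)
    # unbiased chance for a balanced test set; generous band for 150 reps
    assert abs(np.mean(accs) - 1 / 3) < 0.04


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _clusters(rng, labels, n_voxels, sd, centroids=None):
    if centroids is None:
        centroids = {c: rng.standard_normal(n_voxels) * 3 for c in set(labels)}
    X = np.stack([centroids[c] + sd * rng.standard_normal(n_voxels)
                  for c in labels])
    return X, centroids


class TestWithinPhase:
    def test_separable_clusters_perfectly_classified(self):
        rng = np.random.default_rng(0)
        y = np.repeat([1, 2, 3], 8)
        X, _ = _clusters(rng, y, 40, sd=0.05)
        acc, y_true, y_pred = classify_within_phase(X, y, MVPAConfig(), seed=0)
        assert acc == 1.0
        assert len(y_true) == 8 * 3  # every item tested once

    def test_shuffled_labels_fall_to_chance(self):
        rng = np.random.default_rng(1)
        y = np.repeat([1, 2, 3], 8)
        X, _ = _clusters(rng, y, 40, sd=0.05)
        accs = []
        for i in range(60):
            perm = rng.permutation(y)
            acc, _, _ = classify_within_phase(X, perm, MVPAConfig(), seed=i)
            accs.append(acc)
        assert abs(np.mean(accs) - 1 / 3) < 0.05

    def test_two_items_per_class_gives_two_folds(self):
        rng = np.random.default_rng(2)
        y = np.repeat([1, 2, 3], 2)
        X, _ = _clusters(rng, y, 20, sd=0.1)
        acc, y_true, y_pred = classify_within_phase(X, y, MVPAConfig(), seed=0)
        assert len(y_true) == len(y_pred) == 6  # 2 folds x 3 classes

    def test_class_with_single_item_rejected(self):
        X = np.random.default_rng(0).standard_normal((5, 10))
        y = np.array([1, 1, 2, 2, 3])
        with pytest.raises(ValueError):
            classify_within_phase(X, y, MVPAConfig())


class TestCrossPhase:
    def test_shared_patterns_transfer_perfectly(self):
        rng = np.random.default_rng(3)
        y_tr = np.repeat([1, 2, 3], 10)
        y_te = np.repeat([1, 2, 3], 5)
        Xtr, cents = _clusters(rng, y_tr, 50, sd=0.05)
        Xte, _ = _clusters(rng, y_te, 50, sd=0.05, centroids=cents)
        acc, _, pred = classify_cross_phase(Xtr, y_tr, Xte, y_te,
                                            MVPAConfig(), seed=0)
        assert acc == 1.0

    def test_phase_specific_patterns_do_not_transfer(self):
        rng = np.random.default_rng(4)
        y_tr = np.repeat([1, 2, 3], 10)
        y_te = np.repeat([1, 2, 3], 5)
        accs = []
        for _ in range(60):
            Xtr, _ = _clusters(rng, y_tr, 50, sd=0.3)
            Xte, _ = _clusters(rng, y_te, 50, sd=0.3)  # fresh centroids
            acc, _, _ = classify_cross_phase(Xtr, y_tr, Xte, y_te,
                                             MVPAConfig(), seed=0)
            accs.append(acc)
        assert abs(np.mean(accs) - 1 / 3) < 0.06

    def test_drifted_first_position_confusion(self):
        # a drifted class-1 centroid lands on an arbitrary side of the learned
        # hyperplanes, so its recall collapses towards chance over draws while
        # the intact positions keep transferring
        rng = np.random.default_rng(5)
        y_tr = np.repeat([1, 2, 3], 10)
        y_te = np.repeat([1, 2, 3], 6)
        recalls = np.zeros(3)
        n_draws = 40
        for _ in range(n_draws):
            Xtr, cents = _clusters(rng, y_tr, 50, sd=0.1)
            drifted = dict(cents)
            drifted[1] = rng.standard_normal(50) * 3  # position 1 changed
            Xte, _ = _clusters(rng, y_te, 50, sd=0.1, centroids=drifted)
            _, y_true, y_pred = classify_cross_phase(Xtr, y_tr, Xte, y_te,
                                                     MVPAConfig(), seed=0)
            recalls += [np.mean(y_pred[y_true == c] == c) for c in (1, 2, 3)]
        recalls /= n_draws
        assert recalls[0] < 0.7
        assert recalls[1] > 0.9 and recalls[2] > 0.9

    def test_missing_class_rejected(self):
        rng = np.random.default_rng(6)
        Xtr = rng.standard_normal((20, 10))
        Xte = rng.standard_normal((10, 10))
        with pytest.raises(ValueError):
            classify_cross_phase(Xtr, np.repeat([1, 2], 10),
                                 Xte, np.repeat([1, 2, 3], [4, 3, 3]),
                                 MVPAConfig())


class TestOneVsOneSVM:
    def test_decision_distance_sign_convention(self):
        rng = np.random.default_rng(0)
        y = np.repeat([1, 2, 3], 10)
        X, cents = _clusters(rng, y, 20, sd=0.1)
        model = OneVsOneSVM(C=40).fit(X, y)
        D = model.decision_distances(X)
        # columns ordered (1,2), (1,3), (2,3); positive towards second class
        assert D[y == 2, 0].mean() > 0 > D[y == 1, 0].mean()
        assert D[y == 3, 1].mean() > 0 > D[y == 1, 1].mean()
        assert D[y == 3, 2].mean() > 0 > D[y == 2, 2].mean()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            OneVsOneSVM().fit(np.ones((4, 3)), np.ones(4))


# ---------------------------------------------------------------------------
# searchlight maps
# ---------------------------------------------------------------------------

class TestSearchlightMap:
    def test_min_voxel_rule_scores_zero(self):
        # a thin mask leaves boundary spheres with fewer than 33 voxels
        from seqpos.glm import BetaImages
        import pandas as pd

        g = bold.make_geometry(shape=(8, 8, 8), seed=0, n_regions=0,
                               mask_fraction=0.12)
        rng = np.random.default_rng(0)
        labels = pd.DataFrame({
            "stimulus_set": "houses",
            "identity": "A",
            "position": np.r_[np.repeat([1, 2, 3], 4), np.repeat([1, 2, 3], 4)],
            "phase": np.repeat(["presentation", "recognition"], 12),
            "n_occurrences": 3,
        })
        betas = BetaImages(betas=rng.standard_normal((24, g.n_mask_voxels)),
                           labels=labels, geometry=g)
        amap = run_searchlight(betas, MVPAConfig(min_voxels=33),
                               "cross_phase", seed=0)
        small = ~amap.evaluated
        assert small.any()
        assert np.all(amap.center_accuracies[small] == 0.0)
        assert amap.zero_scored.sum() == small.sum()

    def test_map_bounded(self, shared_betas):
        amap = run_searchlight(shared_betas, MVPAConfig(), "cross_phase",
                               seed=0)
        assert amap.accuracy.min() >= 0.0 and amap.accuracy.max() <= 1.0

    def test_signal_region_elevated_over_background(self, shared_betas,
                                                    small_geometry):
        amap = run_searchlight(shared_betas, MVPAConfig(), "cross_phase",
                               seed=0)
        labels = small_geometry.region_labels
        inside = np.array([labels[tuple(c)] > 0 for c in amap.centers])
        ev = amap.evaluated
        assert amap.center_accuracies[ev & inside].mean() > \
            amap.center_accuracies[ev & ~inside].mean() + 0.1

    def test_reproducibility(self, shared_betas):
        a = run_searchlight(shared_betas, MVPAConfig(), "cross_phase", seed=3)
        b = run_searchlight(shared_betas, MVPAConfig(), "cross_phase", seed=3)
        assert np.array_equal(a.center_accuracies, b.center_accuracies)
        assert np.array_equal(a.predictions, b.predictions)

    def test_within_phase_map(self, shared_betas):
        amap = run_searchlight(shared_betas, MVPAConfig(),
                               "within_presentation", seed=0)
        # 9 folds (smallest class has 9 regressors) x 3 classes tested
        assert amap.predictions.shape[1] == 27
        assert amap.analysis_kind == "within_presentation"

    def test_unknown_analysis_kind_rejected(self, shared_betas):
        with pytest.raises(ValueError):
            run_searchlight(shared_betas, MVPAConfig(), "within_probe")
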