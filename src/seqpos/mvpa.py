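"""Searchlight multivoxel pattern analysis of temporal position.

A 6-mm spherical searchlight moves through the masked grid; at each centre the
member voxels' beta patterns are normalized and a linear support-vector machine
(C=40, one-vs-one voting as in LIBSVM) performs a 3-way classification of item
position, either within one task phase (leave-one-item-per-class-out
cross-validation) or across phases (train on presentation, test on
recognition).  Spheres with fewer than 33 in-mask voxels score zero.

Normalization removes each item's uniform (searchlight-mean) component and then
z-scores every voxel across items, so signals that change a region uniformly
with position — memory load, adaptation — cannot drive classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.svm import SVC

from .bold import VolumeGeometry
from .glm import BetaImages

logger = logging.getLogger(__name__)

ANALYSIS_KINDS = ("within_presentation", "within_recognition", "cross_phase")


@dataclass
class MVPAConfig:
    radius_mm: float = 6.0
    min_voxels: int = 33
    regularization_C: float = 40.0
    balance_train: bool = True          # subsample training classes to equal size
    remove_uniform: bool = True         # per-item searchlight-mean removal
    # "joint": both phases normalized as one matrix before splitting (the
    # items-x-voxels matrix is z-scored once); "independent": each phase
    # scaled separately; "train": training statistics applied to test items.
    cross_phase_scaling: str = "joint"

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")
        if self.regularization_C <= 0:
            raise ValueError("regularization_C must be positive")
        if self.cross_phase_scaling not in ("joint", "independent", "train"):
            raise ValueError(
                "cross_phase_scaling must be 'joint', 'independent' or 'train'")


@dataclass
class SearchlightIndex:
    center_voxel: tuple[int, int, int]
    member_rows: np.ndarray  # rows into the masked-voxel ordering

    @property
    def n_in_mask(self) -> int:
        return len(self.member_rows)


@dataclass
class AccuracyMap:
    """Per-centre classification accuracies plus the raw predictions."""

    accuracy: np.ndarray          # 3D volume, 0 outside evaluated centres
    zero_scored: np.ndarray       # 3D bool volume: centres failing min_voxels
    analysis_kind: str
    centers: np.ndarray           # (n, 3) evaluated centre coordinates
    center_accuracies: np.ndarray  # (n,)
    true_labels: np.ndarray       # (m,) labels of tested items
    predictions: np.ndarray       # (n, m) predicted label per centre x item
    geometry: VolumeGeometry | None = None

    @property
    def evaluated(self) -> np.ndarray:
        """Mask over centres that were actually classified (not zero-scored)."""
        return self.predictions[:, 0] >= 0 if self.predictions.size else np.zeros(0, bool)


# ---------------------------------------------------------------------------
# searchlights
# ---------------------------------------------------------------------------

def sphere_offsets(radius_mm: float, voxel_size_mm) -> np.ndarray:
    """Integer voxel offsets whose centre-to-centre distance is <= radius."""
    vs = np.asarray(voxel_size_mm, dtype=float)
    max_off = np.floor(radius_mm / vs).astype(int)
    ranges = [np.arange(-m, m + 1) for m in max_off]
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    d2 = ((grid * vs) ** 2).sum(axis=1)
    return grid[d2 <= radius_mm ** 2 + 1e-9]


def build_searchlights(
    geometry: VolumeGeometry,
    config: MVPAConfig = MVPAConfig(),
) -> list[SearchlightIndex]:
    """One searchlight per in-mask voxel; members are in-mask voxels within
    the radius (millimetre centre-to-centre distance)."""
    if geometry.n_mask_voxels == 0:
        raise ValueError("mask is empty")
    offsets = sphere_offsets(config.radius_mm, geometry.voxel_size_mm)
    row_index = -np.ones(geometry.shape, dtype=int)
    coords = geometry.mask_coords
    row_index[tuple(coords.T)] = np.arange(len(coords))
    shape = np.array(geometry.shape)

    out: list[SearchlightIndex] = []
    for c in coords:
        pts = c + offsets
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        rows = row_index[tuple(pts[ok].T)]
        rows = rows[rows >= 0]
        out.append(SearchlightIndex(center_voxel=tuple(int(x) for x in c),
                                    member_rows=np.sort(rows)))
    return out


# ---------------------------------------------------------------------------
# pattern normalization
# ---------------------------------------------------------------------------

def zscore_patterns(matrix: np.ndarray, remove_uniform: bool = True) -> np.ndarray:
    """Normalize an items x voxels matrix.

    Each item's uniform component (its mean over the searchlight's voxels) is
    removed first, then every voxel is standardized across items.  Voxels with
    zero variance are set to zero (and logged).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 items to z-score")
    if remove_uniform:
        X = X - X.mean(axis=1, keepdims=True)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    dead = sd < 1e-12
    if dead.any():
        logger.debug("zscore_patterns: %d zero-variance voxels set to 0", dead.sum())
    sd = np.where(dead, 1.0, sd)
    Z = (X - mu) / sd
    Z[:, dead] = 0.0
    return Z


# ---------------------------------------------------------------------------
# one-vs-one linear SVM with LIBSVM-style voting
# ---------------------------------------------------------------------------

class OneVsOneSVM:
    """Linear SVMs for every class pair; prediction by vote counting with
    ties broken in favour of the lowest class label."""

    def __init__(self, C: float = 40.0):
        self.C = C
        self.classes_: np.ndarray | None = None
        self._models: dict[tuple[int, int], SVC] = {}

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OneVsOneSVM":
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self._models = {}
        for a, b in combinations(self.classes_, 2):
            sel = (y == a) | (y == b)
            svc = SVC(kernel="linear", C=self.C)
            svc.fit(X[sel], y[sel])
            self._models[(a, b)] = svc
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        votes = np.zeros((X.shape[0], len(self.classes_)), dtype=int)
        cls_index = {c: i for i, c in enumerate(self.classes_)}
        for (a, b), svc in self._models.items():
            pred = svc.predict(X)
            for c in (a, b):
                votes[:, cls_index[c]] += pred == c
        # argmax returns the first (lowest-label) class among ties
        return self.classes_[np.argmax(votes, axis=1)]

    def decision_distances(self, X: np.ndarray) -> np.ndarray:
        """Signed Euclidean distances to each pairwise separating hyperplane,
        columns ordered by class pair (a, b) with positive = towards b."""
        cols = []
        for (a, b), svc in sorted(self._models.items()):
            w = svc.coef_.ravel()
            d = (X @ w + svc.intercept_[0]) / np.linalg.norm(w)
            # SVC decision_function is positive towards classes_[1] of the pair
            if svc.classes_[1] != b:
                d = -d
            cols.append(d)
        return np.column_stack(cols)


def _balance_classes(X: np.ndarray, y: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    classes, counts = np.unique(y, return_counts=True)
    m = counts.min()
    keep = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        keep.append(rng.choice(idx, size=m, replace=False) if len(idx) > m else idx)
    keep = np.sort(np.concatenate(keep))
    return X[keep], y[keep]


# ---------------------------------------------------------------------------
# classification analyses
# ---------------------------------------------------------------------------

def classify_within_phase(
    patterns: np.ndarray,
    labels: np.ndarray,
    config: MVPAConfig = MVPAConfig(),
    seed: int = 0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Leave-one-item-per-class-out cross-validation within one phase.

    Folds pair items of equal within-class rank after a seeded shuffle; the
    fold count is the smallest class count.  Returns (mean accuracy,
    true labels of tested items, predicted labels).
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 items for within-phase CV")
    per_class = {c: rng.permutation(np.flatnonzero(labels == c)) for c in classes}
    n_folds = counts.min()

    X = zscore_patterns(patterns, config.remove_uniform)
    y_true, y_pred = [], []
    for f in range(n_folds):
        test_idx = np.array([per_class[c][f] for c in classes])
        train_mask = np.ones(len(labels), dtype=bool)
        train_mask[test_idx] = False
        Xtr, ytr = X[train_mask], labels[train_mask]
        if config.balance_train:
            Xtr, ytr = _balance_classes(Xtr, ytr, rng)
        model = OneVsOneSVM(config.regularization_C).fit(Xtr, ytr)
        pred = model.predict(X[test_idx])
        y_true.extend(labels[test_idx])
        y_pred.extend(pred)
    y_true = np.array(y_true)
    y_pred = np.array(y_pred)
    return float((y_true == y_pred).mean()), y_true, y_pred


def classify_cross_phase(
    train_patterns: np.ndarray,
    train_labels: np.ndarray,
    test_patterns: np.ndarray,
    test_labels: np.ndarray,
    config: MVPAConfig = MVPAConfig(),
    seed: int = 0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Train on presentation patterns, test on recognition patterns.

    Cross-validation is provided a priori by the two task phases.  By default
    both phases are normalized together as a single items x voxels matrix
    before splitting (so the normalization offsets cancel between phases);
    per-phase and train-statistics scaling are available as alternatives.
    Returns (accuracy, true test labels, predicted labels).
    """
    train_labels = np.asarray(train_labels)
    test_labels = np.asarray(test_labels)
    for name, lab in (("train", train_labels), ("test", test_labels)):
        if len(np.unique(lab)) < 3:
            raise ValueError(f"{name} phase is missing a position class")
    rng = np.random.default_rng(seed)
    n_train = len(train_labels)
    if config.cross_phase_scaling == "joint":
        Z = zscore_patterns(np.vstack([train_patterns, test_patterns]),
                            config.remove_uniform)
        Xtr, Xte = Z[:n_train], Z[n_train:]
    elif config.cross_phase_scaling == "independent":
        Xtr = zscore_patterns(train_patterns, config.remove_uniform)
        Xte = zscore_patterns(test_patterns, config.remove_uniform)
    else:  # apply training statistics to the test items
        R = np.asarray(train_patterns, dtype=float)
        T = np.asarray(test_patterns, dtype=float)
        if config.remove_uniform:
            R = R - R.mean(axis=1, keepdims=True)
            T = T - T.mean(axis=1, keepdims=True)
        mu, sd = R.mean(axis=0), R.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        Xtr = (R - mu) / sd
        Xte = (T - mu) / sd
    ytr = train_labels
    if config.balance_train:
        Xtr, ytr = _balance_classes(Xtr, ytr, rng)
    model = OneVsOneSVM(config.regularization_C).fit(Xtr, ytr)
    pred = model.predict(Xte)
    return float((pred == test_labels).mean()), test_labels, pred


# ---------------------------------------------------------------------------
# searchlight map
# ---------------------------------------------------------------------------

def run_searchlight(
    betas: BetaImages,
    config: MVPAConfig = MVPAConfig(),
    analysis_kind: str = "cross_phase",
    seed: int = 0,
    searchlights: list[SearchlightIndex] | None = None,
) -> AccuracyMap:
    """Classify item position in every searchlight and map the accuracies.

    Centres whose sphere holds fewer than ``config.min_voxels`` in-mask voxels
    are assigned an accuracy of exactly zero and are excluded from the stored
    predictions (prediction rows of -1).
    """
    if analysis_kind not in ANALYSIS_KINDS:
        raise ValueError(f"unknown analysis_kind {analysis_kind!r}")
    geometry = betas.geometry
    if searchlights is None:
        searchlights = build_searchlights(geometry, config)

    if analysis_kind == "cross_phase":
        tr_rows = betas.phase_rows("presentation")
        te_rows = betas.phase_rows("recognition")
        y_tr = betas.positions(tr_rows)
        y_te = betas.positions(te_rows)
        n_items = len(te_rows)
        ref_true = y_te
    else:
        phase = analysis_kind.removeprefix("within_")
        rows = betas.phase_rows(phase)
        y = betas.positions(rows)
        # tested items: one per class per fold, fold count = min class count
        _, counts = np.unique(y, return_counts=True)
        n_items = int(counts.min()) * len(np.unique(y))
        ref_true = None

    acc_vol = np.zeros(geometry.shape)
    zero_vol = np.zeros(geometry.shape, dtype=bool)
    centers, accs, preds = [], [], []
    true_out = None

    for i, sl in enumerate(searchlights):
        centers.append(sl.center_voxel)
        if sl.n_in_mask < config.min_voxels:
            zero_vol[sl.center_voxel] = True
            accs.append(0.0)
            preds.append(np.full(n_items, -1, dtype=int))
            continue
        sl_seed = seed + 7919 * i
        if analysis_kind == "cross_phase":
            acc, y_true, y_pred = classify_cross_phase(
                betas.betas[np.ix_(tr_rows, sl.member_rows)], y_tr,
                betas.betas[np.ix_(te_rows, sl.member_rows)], y_te,
                config, seed=sl_seed,
            )
        else:
            acc, y_true, y_pred = classify_within_phase(
                betas.betas[np.ix_(rows, sl.member_rows)], y,
                config, seed=sl_seed,
            )
        if true_out is None:
            true_out = y_true
        acc_vol[sl.center_voxel] = acc
        accs.append(acc)
        preds.append(y_pred)

    if true_out is None:  # every centre zero-scored
        true_out = ref_true if ref_true is not None else np.zeros(n_items, dtype=int)
    return AccuracyMap(
        accuracy=acc_vol,
        zero_scored=zero_vol,
        analysis_kind=analysis_kind,
        centers=np.array(centers, dtype=int),
        center_accuracies=np.array(accs),
        true_labels=np.asarray(true_out),
        predictions=np.vstack(preds) if preds else np.zeros((0, n_items), dtype=int),
        geometry=geometry,
    )
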