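"""Two-stage nonparametric group inference for searchlight accuracy maps.

Stage 1 (per participant): the correspondence between *test* labels and data
is permuted, giving a null distribution of mean accuracies to which the
true-labelling accuracy is appended.  Because only test labels are shuffled,
the classifier (and hence its predictions) is unchanged, so each permuted
accuracy is simply the agreement between the fixed predictions and a shuffled
label vector.

Stage 2 (group): group-level mean accuracies are resampled by drawing, with
replacement, one accuracy per participant from that participant's
distribution; the true group mean's empirical probability is its rank within
the resampled distribution, p = (1 + #{samples >= true}) / (n_samples + 1),
which is valid by construction and bounded below by 1/(n_samples + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mvpa import AccuracyMap


@dataclass
class StatsConfig:
    n_permutations: int = 100
    n_group_samples: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_permutations < 1 or self.n_group_samples < 1:
            raise ValueError("n_permutations and n_group_samples must be >= 1")


@dataclass
class GroupPMap:
    p: np.ndarray                 # (n_centers,) empirical probabilities
    centers: np.ndarray           # (n_centers, 3)
    true_group_mean: np.ndarray   # (n_centers,)
    n_group_samples: int

    @property
    def min_attainable_p(self) -> float:
        return 1.0 / (self.n_group_samples + 1)

    def volume(self, shape: tuple[int, int, int]) -> np.ndarray:
        vol = np.ones(shape)
        vol[tuple(self.centers.T)] = self.p
        return vol


def permuted_accuracies(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    n_permutations: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Null accuracies from shuffled test labels, with the true-labelling
    accuracy appended as the last element (length n_permutations + 1)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    rng = np.random.default_rng(seed)
    out = np.empty(n_permutations + 1)
    for i in range(n_permutations):
        out[i] = float((rng.permutation(y_true) == y_pred).mean())
    out[-1] = float((y_true == y_pred).mean())
    return out


def map_permutation_distributions(
    acc_map: AccuracyMap,
    config: StatsConfig = StatsConfig(),
) -> np.ndarray:
    """Per-centre permutation distributions for one participant's map.

    Returns (n_centers, n_permutations + 1); zero-scored centres carry all
    zeros (their accuracy is fixed at zero by convention).
    """
    n_centers = len(acc_map.centers)
    out = np.zeros((n_centers, config.n_permutations + 1))
    rng = np.random.default_rng(config.seed)
    y_true = acc_map.true_labels
    for i in range(n_centers):
        pred = acc_map.predictions[i]
        if pred[0] < 0:  # zero-scored centre
            continue
        out[i] = permuted_accuracies(
            y_true, pred, config.n_permutations,
            seed=int(rng.integers(2 ** 31)),
        )
    return out


def group_empirical_p(
    distributions: np.ndarray,
    config: StatsConfig = StatsConfig(),
    centers: np.ndarray | None = None,
) -> GroupPMap:
    """Group-level empirical probabilities per centre.

    ``distributions`` is (n_subjects, n_centers, n_permutations + 1) with the
    true accuracy in the last slot.  For each of ``n_group_samples`` draws one
    accuracy per participant is sampled with replacement and averaged; the
    p-value is the true group mean's rank within those samples.
    """
    distributions = np.asarray(distributions)
    if distributions.ndim == 2:  # single centre: (n_subjects, n_perm + 1)
        distributions = distributions[:, None, :]
    n_subj, n_centers, width = distributions.shape
    if n_subj < 2:
        raise ValueError("group inference needs at least 2 participants")
    if width < 2:
        raise ValueError("permutation distributions must hold at least one "
                         "permuted accuracy besides the true one")
    rng = np.random.default_rng(config.seed)
    true_mean = distributions[:, :, -1].mean(axis=0)

    n_s = config.n_group_samples
    idx = rng.integers(0, width, size=(n_s, n_subj, n_centers))
    subj_ix = np.arange(n_subj)[None, :, None]
    cent_ix = np.arange(n_centers)[None, None, :]
    sampled = distributions[subj_ix, cent_ix, idx]        # (n_s, S, C)
    group_means = sampled.mean(axis=1)                    # (n_s, C)
    p = (1.0 + (group_means >= true_mean[None, :]).sum(axis=0)) / (n_s + 1.0)
    if centers is None:
        centers = np.zeros((n_centers, 3), dtype=int)
    return GroupPMap(p=p, centers=np.asarray(centers),
                     true_group_mean=true_mean, n_group_samples=n_s)


def summarize_map(
    pmap: GroupPMap,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Centres with p < alpha (no multiplicity correction by default, matching
    the rank-based reporting convention)."""
    sel = pmap.p < alpha
    df = pd.DataFrame({
        "x": pmap.centers[sel, 0],
        "y": pmap.centers[sel, 1],
        "z": pmap.centers[sel, 2],
        "p": pmap.p[sel],
        "group_mean_accuracy": pmap.true_group_mean[sel],
    })
    return df.sort_values("p", kind="stable").reset_index(drop=True)
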