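"""Region-level representational analyses.

Given labelled beta patterns and a region's voxels, this module computes the
cross-phase confusion structure of the position classifier, 3x3 cross-phase
pattern-similarity (Pearson) matrices, the distance each position's mean
representation moves between task phases measured in the classifier's
decision-function space, a region x position ANOVA on those shift distances,
and a paired comparison of pattern dispersion between phases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats
from statsmodels.formula.api import ols

from .glm import BetaImages
from .mvpa import MVPAConfig, OneVsOneSVM, _balance_classes, zscore_patterns

POSITIONS = (1, 2, 3)


@dataclass
class ConfusionMatrix:
    proportions: np.ndarray   # 3x3, rows true position, cols predicted
    n_per_row: np.ndarray     # counts per true position
    undefined_rows: list[int]

    @property
    def accuracy(self) -> float:
        weights = self.n_per_row / self.n_per_row.sum()
        diag = np.nan_to_num(np.diag(self.proportions))
        return float((weights * diag).sum())


@dataclass
class CrossPhaseSimilarity:
    rho: np.ndarray           # 3x3: rows presentation position, cols recognition
    undefined_cells: list[tuple[int, int]]

    @property
    def diagonal_advantage(self) -> float:
        """Mean same-position minus mean different-position correlation."""
        d = np.nanmean(np.diag(self.rho))
        off = self.rho[~np.eye(3, dtype=bool)]
        return float(d - np.nanmean(off))


class VarianceComparison(NamedTuple):
    statistic: float
    df: int
    pvalue: float
    valid: bool


def confusion_from_predictions(y_true, y_pred, positions=POSITIONS) -> ConfusionMatrix:
    """Row-normalized counts of predicted vs true position."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("no predictions supplied")
    k = len(positions)
    counts = np.zeros((k, k))
    for i, t in enumerate(positions):
        for j, p in enumerate(positions):
            counts[i, j] = np.sum((y_true == t) & (y_pred == p))
    n_per_row = counts.sum(axis=1)
    undefined = [positions[i] for i in range(k) if n_per_row[i] == 0]
    props = np.full((k, k), np.nan)
    nz = n_per_row > 0
    props[nz] = counts[nz] / n_per_row[nz, None]
    return ConfusionMatrix(proportions=props, n_per_row=n_per_row.astype(int),
                           undefined_rows=undefined)


def _normalized_phases(betas: BetaImages, region_rows: np.ndarray,
                       config: MVPAConfig):
    """Region patterns per phase, normalized like the classifier input:
    both phases z-scored as one matrix (offsets cancel between phases)."""
    tr = betas.phase_rows("presentation")
    te = betas.phase_rows("recognition")
    for name, rows in (("presentation", tr), ("recognition", te)):
        if rows.size == 0:
            raise ValueError(f"no {name}-phase betas present")
    Z = zscore_patterns(betas.betas[np.ix_(np.concatenate([tr, te]), region_rows)],
                        config.remove_uniform)
    Xtr, Xte = Z[: len(tr)], Z[len(tr):]
    return Xtr, betas.positions(tr), Xte, betas.positions(te)


def _phase_position_means(betas: BetaImages, region_rows: np.ndarray,
                          config: MVPAConfig) -> dict[tuple[str, int], np.ndarray]:
    Xtr, ytr, Xte, yte = _normalized_phases(betas, region_rows, config)
    means = {}
    for phase, X, y in (("presentation", Xtr, ytr), ("recognition", Xte, yte)):
        for p in POSITIONS:
            means[(phase, p)] = X[y == p].mean(axis=0)
    return means


def cross_phase_similarity(
    betas: BetaImages,
    region_rows: np.ndarray,
    config: MVPAConfig = MVPAConfig(),
) -> CrossPhaseSimilarity:
    """Pearson correlations between mean presentation- and recognition-phase
    patterns for every pair of positions within one region."""
    if len(region_rows) < 2:
        raise ValueError("region must contain at least 2 voxels")
    means = _phase_position_means(betas, region_rows, config)
    rho = np.full((3, 3), np.nan)
    undefined = []
    for i, p_pres in enumerate(POSITIONS):
        for j, p_rec in enumerate(POSITIONS):
            a = means[("presentation", p_pres)]
            b = means[("recognition", p_rec)]
            if a.std() < 1e-12 or b.std() < 1e-12:
                undefined.append((p_pres, p_rec))
                continue
            rho[i, j] = np.corrcoef(a, b)[0, 1]
    return CrossPhaseSimilarity(rho=rho, undefined_cells=undefined)


def position_shift(
    betas: BetaImages,
    region_rows: np.ndarray,
    config: MVPAConfig = MVPAConfig(),
    seed: int = 0,
    space: str = "decision",
) -> dict[int, float]:
    """How far each position's mean pattern moves between task phases.

    With ``space='decision'`` every pattern is mapped to its 3-vector of
    signed distances to the three pairwise separating hyperplanes of a
    classifier trained on the presentation phase, and the shift is the
    Euclidean distance between the phase means of that 3-vector.  With
    ``space='voxel'`` the shift is measured directly in (normalized) voxel
    space.
    """
    rng = np.random.default_rng(seed)
    Xtr, ytr, Xte, yte = _normalized_phases(betas, region_rows, config)

    if space == "decision":
        Xfit, yfit = (Xtr, ytr)
        if config.balance_train:
            Xfit, yfit = _balance_classes(Xtr, ytr, rng)
        model = OneVsOneSVM(config.regularization_C).fit(Xfit, yfit)
        Dtr = model.decision_distances(Xtr)
        Dte = model.decision_distances(Xte)
    elif space == "voxel":
        Dtr, Dte = Xtr, Xte
    else:
        raise ValueError("space must be 'decision' or 'voxel'")

    shifts = {}
    for p in POSITIONS:
        mu_tr = Dtr[ytr == p].mean(axis=0)
        mu_te = Dte[yte == p].mean(axis=0)
        shifts[p] = float(np.linalg.norm(mu_tr - mu_te))
    return shifts


def shift_table(
    per_participant_betas: list[BetaImages],
    region_rows_by_name: dict[str, np.ndarray],
    config: MVPAConfig = MVPAConfig(),
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format table of shift distances: one row per
    (participant, region, position)."""
    rows = []
    for s, betas in enumerate(per_participant_betas):
        for region, region_rows in region_rows_by_name.items():
            shifts = position_shift(betas, region_rows, config, seed=seed + s)
            for pos, val in shifts.items():
                rows.append({"participant": betas.participant_id,
                             "region": region, "position": pos, "shift": val})
    return pd.DataFrame(rows)


def shift_anova(table: pd.DataFrame) -> pd.DataFrame:
    """Two-way (region x position) ANOVA on shift distances, participants as
    replicates.  Returns the ANOVA table with F, df and p per effect."""
    if table["region"].nunique() < 2:
        raise ValueError("need at least 2 regions")
    if table["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    cells = table.groupby(["region", "position"]).size()
    expected = table["region"].nunique() * table["position"].nunique()
    if len(cells) < expected:
        full = pd.MultiIndex.from_product(
            [table["region"].unique(), sorted(table["position"].unique())],
            names=["region", "position"])
        missing = full.difference(cells.index)
        raise ValueError(f"empty design cells: {list(missing)}")
    model = ols("shift ~ C(region) * C(position)", data=table).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    aov = aov.rename(index={
        "C(region)": "region",
        "C(position)": "position",
        "C(region):C(position)": "region:position",
        "Residual": "residual",
    })
    return aov


def pattern_dispersions(
    betas: BetaImages,
    region_rows: np.ndarray,
    config: MVPAConfig = MVPAConfig(),
) -> pd.DataFrame:
    """Per (phase, position) dispersion: mean Euclidean distance of each
    normalized pattern to its class mean."""
    Xtr, ytr, Xte, yte = _normalized_phases(betas, region_rows, config)
    rows = []
    for phase, X, pos in (("presentation", Xtr, ytr), ("recognition", Xte, yte)):
        for p in POSITIONS:
            cls = X[pos == p]
            mu = cls.mean(axis=0)
            rows.append({
                "participant": betas.participant_id, "phase": phase,
                "position": p,
                "dispersion": float(np.linalg.norm(cls - mu, axis=1).mean()),
            })
    return pd.DataFrame(rows)


def variance_comparison(dispersion_table: pd.DataFrame) -> VarianceComparison:
    """Paired two-sided test of pattern dispersion between task phases.

    For each participant the position-mean dispersion difference
    (presentation - recognition) is computed; a one-sample t-test across
    participants tests whether it departs from zero.  This is a reconstruction
    of an under-specified published comparison and is labelled as such.
    """
    participants = dispersion_table["participant"].unique()
    if len(participants) < 2:
        raise ValueError("paired comparison needs at least 2 participants")
    diffs = []
    for p in participants:
        sub = dispersion_table[dispersion_table["participant"] == p]
        pres = sub[sub["phase"] == "presentation"]["dispersion"].mean()
        rec = sub[sub["phase"] == "recognition"]["dispersion"].mean()
        diffs.append(pres - rec)
    diffs = np.asarray(diffs)
    if np.allclose(dispersion_table["dispersion"], 0):
        return VarianceComparison(np.nan, len(diffs) - 1, np.nan, valid=False)
    t, p = sstats.ttest_1samp(diffs, 0.0)
    return VarianceComparison(float(t), len(diffs) - 1, float(p), valid=True)
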