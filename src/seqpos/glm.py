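"""Single-event beta estimation with the least-squares-separate (LS2) scheme.

Each event regressor gets its own GLM containing the target regressor, one
regressor pooling all other events, nuisance columns (motion, filtered
physiological traces, spike indicators) and an intercept.  Data and design are
high-pass filtered by residualization against a discrete-cosine basis (128-s
cutoff) before fitting; no pre-whitening is applied at task frequencies, since
whitening rapid event-related data introduces artificial dissimilarities
between temporally adjacent events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bold import BOLDRun, _event_regressor
from .design import EventOccurrence, RegressorSet

logger = logging.getLogger(__name__)


@dataclass
class GLMConfig:
    highpass_cutoff_s: float = 128.0
    hrf: str = "spm"
    event_duration_s: float = 3.5
    include_motion: bool = True
    include_physio: bool = True
    include_spikes: bool = True
    pooled_other_per_phase: bool = False  # one pooled column per phase instead of global

    def validate(self, tr_s: float) -> None:
        if self.highpass_cutoff_s <= 2 * tr_s:
            raise ValueError("highpass_cutoff_s must exceed 2 x TR")


@dataclass
class ScrubConfig:
    translation_threshold_mm: float = 0.5
    rotation_threshold_deg: float = 1.33
    image_diff_threshold: float = 0.035
    exclusion_fraction: float = 0.10

    def __post_init__(self):
        for name in ("translation_threshold_mm", "rotation_threshold_deg",
                     "image_diff_threshold", "exclusion_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class BetaImages:
    """Per-regressor activity patterns: one row per event regressor."""

    betas: np.ndarray          # (R, V) over masked voxels
    labels: pd.DataFrame       # stimulus_set, identity, position, phase, n_occurrences
    geometry: "object"         # VolumeGeometry of the masked grid
    participant_id: str = "sub-01"

    def __post_init__(self):
        if self.betas.shape[0] != len(self.labels):
            raise ValueError("one label row per beta row required")

    @property
    def n_regressors(self) -> int:
        return self.betas.shape[0]

    def phase_rows(self, phase: str) -> np.ndarray:
        return np.flatnonzero((self.labels["phase"] == phase).to_numpy())

    def positions(self, rows: np.ndarray | None = None) -> np.ndarray:
        pos = self.labels["position"].to_numpy()
        return pos if rows is None else pos[rows]


# ---------------------------------------------------------------------------
# high-pass filtering
# ---------------------------------------------------------------------------

def dct_highpass_basis(n_frames: int, tr_s: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Orthonormal discrete-cosine columns spanning fluctuations slower than
    the cutoff period (SPM-style: K = floor(2 * n * TR / cutoff))."""
    K = int(np.floor(2.0 * n_frames * tr_s / cutoff_s))
    t = np.arange(n_frames)
    cols = [np.sqrt(2.0 / n_frames) * np.cos(np.pi * (2 * t + 1) * k / (2.0 * n_frames))
            for k in range(1, K + 1)]
    if not cols:
        return np.zeros((n_frames, 0))
    return np.column_stack(cols)


def highpass_filter(X: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Residualize columns of X against the drift basis (a projection)."""
    if basis.shape[1] == 0:
        return X.copy()
    return X - basis @ (basis.T @ X)


# ---------------------------------------------------------------------------
# scrubbing and nuisance regressors
# ---------------------------------------------------------------------------

def image_diff_series(run: BOLDRun) -> np.ndarray:
    """Between-image difference: squared difference of consecutive masked
    images (averaged over voxels) divided by the squared global mean; the
    first frame gets 0."""
    Y = run.masked_timeseries()  # (T, V)
    gm = float(Y.mean())
    d = np.zeros(Y.shape[0])
    if gm == 0.0:
        return d
    diffs = np.diff(Y, axis=0)
    d[1:] = (diffs ** 2).mean(axis=1) / (gm ** 2)
    return d


def flag_scans(run: BOLDRun, scrub: ScrubConfig = ScrubConfig()) -> np.ndarray:
    """Boolean flag per scan: extreme inter-scan movement or image change."""
    mp = run.motion_params
    flags = np.zeros(run.n_frames, dtype=bool)
    dtrans = np.abs(np.diff(mp[:, :3], axis=0)).max(axis=1)
    drot = np.abs(np.diff(mp[:, 3:], axis=0)).max(axis=1)
    flags[1:] |= dtrans > scrub.translation_threshold_mm
    flags[1:] |= drot > scrub.rotation_threshold_deg
    flags |= image_diff_series(run) > scrub.image_diff_threshold
    return flags


def flag_exclusion(run: BOLDRun, scrub: ScrubConfig = ScrubConfig()) -> tuple[str, float]:
    """Exclude a participant iff the flagged-scan fraction strictly exceeds
    the exclusion threshold (exactly 10% is kept)."""
    frac = float(flag_scans(run, scrub).mean())
    return ("exclude" if frac > scrub.exclusion_fraction else "keep", frac)


def resample_trace(trace: np.ndarray, frame_times: np.ndarray, tr_s: float) -> np.ndarray:
    """Low-pass filter a recorded physiological trace below the scan Nyquist
    frequency and sample it at the frame times."""
    t, v = trace[:, 0], trace[:, 1]
    if t[-1] < frame_times[-1] - 1e-9:
        raise ValueError("physiological trace shorter than the run")
    fs = 1.0 / np.median(np.diff(t))
    nyq_scan = 0.5 / tr_s
    b, a = sps.butter(4, min(0.9 * nyq_scan, 0.45 * fs) / (fs / 2.0), btype="low")
    v = sps.filtfilt(b, a, v)
    return np.interp(frame_times, t, v)


def build_nuisance_matrix(
    run: BOLDRun,
    scrub: ScrubConfig = ScrubConfig(),
    config: GLMConfig = GLMConfig(),
) -> tuple[np.ndarray, list[str]]:
    """Motion parameters + TR-resampled physiological traces + one one-hot
    spike column per flagged scan."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    ft = run.frame_times
    if config.include_motion:
        mp = run.motion_params
        if np.allclose(mp.std(axis=0), 0):
            logger.warning("motion parameters are constant; columns are "
                           "captured by the intercept")
        cols.extend(mp.T)
        names.extend([f"motion_{i}" for i in range(6)])
    if config.include_physio:
        cols.append(resample_trace(run.cardiac_trace, ft, run.tr_s))
        names.append("cardiac")
        cols.append(resample_trace(run.respiratory_trace, ft, run.tr_s))
        names.append("respiratory")
    if config.include_spikes:
        for t_idx in np.flatnonzero(flag_scans(run, scrub)):
            col = np.zeros(run.n_frames)
            col[t_idx] = 1.0
            cols.append(col)
            names.append(f"spike_{t_idx}")
    if not cols:
        return np.zeros((run.n_frames, 0)), []
    return np.column_stack(cols), names


def _drop_degenerate_columns(N: np.ndarray, names: list[str]):
    """Remove constant/zero nuisance columns (their content, if any, is
    captured by the intercept)."""
    if N.shape[1] == 0:
        return N, names
    keep = N.std(axis=0) > 1e-12
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        logger.warning("dropping degenerate nuisance columns: %s", dropped)
    return N[:, keep], [n for n, k in zip(names, keep) if k]


# ---------------------------------------------------------------------------
# event regressors and LS2 estimation
# ---------------------------------------------------------------------------

def build_event_regressor(
    occurrences: "tuple[EventOccurrence, ...] | list[EventOccurrence]",
    frame_times: np.ndarray,
    duration_s: float = 3.5,
    hrf: str = "spm",
) -> np.ndarray:
    """HRF-convolved boxcar summed over a regressor's member occurrences."""
    if hrf != "spm":
        raise ValueError("only the canonical (SPM double-gamma) HRF is supported")
    onsets = [o.onset_s for o in occurrences]
    if onsets and max(onsets) > frame_times[-1]:
        raise ValueError("event onset beyond the end of the run")
    return _event_regressor(onsets, duration_s, frame_times)


def build_design_columns(regressor_set: RegressorSet, frame_times: np.ndarray,
                         config: GLMConfig = GLMConfig()) -> np.ndarray:
    """(T, R) event-regressor matrix aligned with ``regressor_set.regressors``."""
    return np.column_stack([
        build_event_regressor(r.occurrences, frame_times,
                              config.event_duration_s, config.hrf)
        for r in regressor_set.regressors
    ]) if len(regressor_set) else np.zeros((frame_times.size, 0))


def estimate_betas_ls2(
    run: BOLDRun,
    regressor_set: RegressorSet,
    config: GLMConfig = GLMConfig(),
    scrub: ScrubConfig = ScrubConfig(),
    enforce_exclusion: bool = True,
) -> BetaImages:
    """One separate GLM per event regressor (least-squares-separate).

    Each fit contains: the target regressor; one (or, optionally, one per
    phase) regressor pooling all other events; nuisance columns; an intercept.
    Data and non-intercept design columns are high-pass filtered first.  The
    target column's coefficient per masked voxel forms one row of the output.
    """
    config.validate(run.tr_s)
    if enforce_exclusion:
        decision, frac = flag_exclusion(run, scrub)
        if decision == "exclude":
            raise ValueError(
                f"participant excluded: {frac:.1%} of volumes show extreme "
                "inter-scan movement (pass enforce_exclusion=False to override)"
            )
    if len(regressor_set) == 0:
        raise ValueError("regressor set is empty")

    ft = run.frame_times
    Y = run.masked_timeseries()
    B = dct_highpass_basis(run.n_frames, run.tr_s, config.highpass_cutoff_s)
    Yf = highpass_filter(Y, B)
    E = build_design_columns(regressor_set, ft, config)
    Ef = highpass_filter(E, B)
    N, names = build_nuisance_matrix(run, scrub, config)
    N, names = _drop_degenerate_columns(N, names)
    Nf = highpass_filter(N, B) if N.shape[1] else N
    intercept = np.ones((run.n_frames, 1))

    phases = np.array([r.phase for r in regressor_set.regressors])
    totals: dict[str, np.ndarray] = {}
    if config.pooled_other_per_phase:
        for ph in np.unique(phases):
            totals[ph] = Ef[:, phases == ph].sum(axis=1)
    total = Ef.sum(axis=1)

    R = len(regressor_set)
    betas = np.empty((R, Y.shape[1]))
    for r in range(R):
        if config.pooled_other_per_phase:
            pooled = []
            for ph in sorted(totals):
                col = totals[ph] - (Ef[:, r] if phases[r] == ph else 0.0)
                if np.any(col != 0):
                    pooled.append(col)
            pooled_cols = np.column_stack(pooled) if pooled else np.zeros((run.n_frames, 0))
        else:
            pooled_cols = (total - Ef[:, r])[:, None]
        # a regressor set with no other events leaves nothing to pool
        pooled_cols = pooled_cols[:, np.linalg.norm(pooled_cols, axis=0) > 1e-12]
        X = np.column_stack([Ef[:, r][:, None], pooled_cols, Nf, intercept])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            norms = np.linalg.norm(X, axis=0)
            bad = [f"col{j}(norm={norms[j]:.2e})" for j in np.flatnonzero(norms < 1e-10)]
            raise np.linalg.LinAlgError(
                f"rank-deficient LS2 design for regressor {r} "
                f"{regressor_set.regressors[r].label}: rank {rank} < {X.shape[1]}; "
                f"offending columns: {bad or 'collinear set'}"
            )
        coef, *_ = np.linalg.lstsq(X, Yf, rcond=None)
        betas[r] = coef[0]

    return BetaImages(
        betas=betas,
        labels=regressor_set.labels_frame(),
        geometry=run.geometry,
        participant_id=run.participant_id,
    )


def estimate_betas_joint(
    run: BOLDRun,
    regressor_set: RegressorSet,
    config: GLMConfig = GLMConfig(),
    scrub: ScrubConfig = ScrubConfig(),
) -> BetaImages:
    """Single joint GLM containing every event regressor at once.

    Provided as a reference estimator; the pipeline uses
    :func:`estimate_betas_ls2`, which is robust to overlap between temporally
    adjacent regressors.
    """
    config.validate(run.tr_s)
    ft = run.frame_times
    Y = run.masked_timeseries()
    B = dct_highpass_basis(run.n_frames, run.tr_s, config.highpass_cutoff_s)
    Yf = highpass_filter(Y, B)
    Ef = highpass_filter(build_design_columns(regressor_set, ft, config), B)
    N, names = build_nuisance_matrix(run, scrub, config)
    N, _ = _drop_degenerate_columns(N, names)
    Nf = highpass_filter(N, B) if N.shape[1] else N
    X = np.column_stack([Ef, Nf, np.ones((run.n_frames, 1))])
    coef, *_ = np.linalg.lstsq(X, Yf, rcond=None)
    return BetaImages(
        betas=coef[: len(regressor_set)],
        labels=regressor_set.labels_frame(),
        geometry=run.geometry,
        participant_id=run.participant_id,
    )
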