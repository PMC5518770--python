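"""Synthetic BOLD data with configurable ground-truth positional codes.

The simulator realizes the hypothesis space the analysis is designed to probe:
each labelled region carries multivoxel patterns for temporal position that are
either shared between task phases, phase-specific, or shared except for the
first position; item-identity patterns orthogonal to the positional ones; and
an optional univariate "load" gradient that grows monotonically with position
and is applied uniformly to a region's voxels.  Event amplitudes are convolved
with the canonical (SPM-style double-gamma) haemodynamic response and embedded
in drift + AR(1) + physiological noise with occasional motion spikes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from nilearn.glm.first_level import compute_regressor

from .design import ExperimentDesign, IDENTITIES, enumerate_occurrences

SHARING_MODES = ("shared", "phase_specific", "drifted_first_position")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass
class VolumeGeometry:
    """A small common grid with a grey-matter-analog mask and labelled regions."""

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    mask: np.ndarray            # bool volume
    region_labels: np.ndarray   # int volume, 0 = unlabelled

    def __post_init__(self):
        if self.mask.shape != tuple(self.shape):
            raise ValueError("mask shape mismatch")
        if np.any(self.region_labels[~self.mask] != 0):
            raise ValueError("labelled region outside mask")

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def mask_coords(self) -> np.ndarray:
        """(V, 3) voxel coordinates of in-mask voxels, fixed analysis order."""
        return np.argwhere(self.mask)

    @property
    def region_ids(self) -> list[int]:
        ids = np.unique(self.region_labels)
        return [int(i) for i in ids if i > 0]

    def region_rows(self, region_id: int) -> np.ndarray:
        """Rows (within the masked-voxel ordering) belonging to a region."""
        labels_in_mask = self.region_labels[self.mask]
        return np.flatnonzero(labels_in_mask == region_id)

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        return aff


def make_geometry(
    shape: tuple[int, int, int] = (16, 16, 16),
    seed: int = 0,
    n_regions: int = 4,
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
    mask_fraction: float = 0.5,
    region_voxels: int = 130,
) -> VolumeGeometry:
    """Ellipsoidal mask covering ``mask_fraction`` of the grid with
    ``n_regions`` compact, disjoint labelled blobs grown inside it."""
    shape = tuple(int(s) for s in shape)
    if any(s <= 0 for s in shape):
        raise ValueError("shape must be positive")
    if n_regions < 0 or region_voxels < 1:
        raise ValueError("n_regions and region_voxels must be non-negative/positive")

    rng = np.random.default_rng(seed)
    grid = np.indices(shape).reshape(3, -1).T.astype(float)
    center = (np.array(shape) - 1) / 2.0
    # normalized ellipsoidal radius; take the innermost fraction of voxels
    r = np.sqrt((((grid - center) / (np.array(shape) / 2.0)) ** 2).sum(axis=1))
    n_in = int(round(mask_fraction * grid.shape[0]))
    order = np.argsort(r, kind="stable")
    mask = np.zeros(int(np.prod(shape)), dtype=bool)
    mask[order[:n_in]] = True
    mask = mask.reshape(shape)

    if n_regions * region_voxels > mask.sum():
        raise ValueError(
            f"cannot fit {n_regions} regions of {region_voxels} voxels into a "
            f"{int(mask.sum())}-voxel mask"
        )

    labels = np.zeros(shape, dtype=int)
    if n_regions == 0:
        return VolumeGeometry(shape=shape, voxel_size_mm=tuple(voxel_size_mm),
                              mask=mask, region_labels=labels)
    coords = np.argwhere(mask)
    # greedy farthest-point seeds for compact, well-separated blobs
    seeds = [coords[rng.integers(len(coords))]]
    for _ in range(1, n_regions):
        d = np.min(
            [np.linalg.norm(coords - s, axis=1) for s in seeds], axis=0
        )
        seeds.append(coords[int(np.argmax(d))])

    neighbours = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                           [0, -1, 0], [0, 0, 1], [0, 0, -1]])
    for rid, start in enumerate(seeds, start=1):
        frontier = [tuple(start)]
        taken = 0
        seen = {tuple(start)}
        while frontier and taken < region_voxels:
            frontier.sort(key=lambda c: float(np.linalg.norm(np.array(c) - start)))
            c = frontier.pop(0)
            if labels[c] != 0 or not mask[c]:
                continue
            labels[c] = rid
            taken += 1
            for nb in neighbours:
                cc = tuple(np.array(c) + nb)
                if all(0 <= cc[i] < shape[i] for i in range(3)) and cc not in seen:
                    if mask[cc] and labels[cc] == 0:
                        frontier.append(cc)
                        seen.add(cc)
        if taken < region_voxels:
            raise ValueError(f"region {rid} could only grow to {taken} voxels")

    return VolumeGeometry(shape=shape, voxel_size_mm=tuple(voxel_size_mm),
                          mask=mask, region_labels=labels)


# ---------------------------------------------------------------------------
# ground-truth patterns
# ---------------------------------------------------------------------------

@dataclass
class EffectConfig:
    """Effect sizes (signal units, per voxel at unit-RMS patterns)."""

    sharing_mode: str = "shared"
    position_amplitude: float = 0.4
    identity_amplitude: float = 0.5
    load_amplitude: float = 0.0
    load_scope: str = "mask"  # load is a diffuse univariate effect; or "regions"
    n_positions: int = 3

    def __post_init__(self):
        if self.sharing_mode not in SHARING_MODES:
            raise ValueError(f"unknown sharing_mode {self.sharing_mode!r}")
        if self.load_scope not in ("mask", "regions"):
            raise ValueError("load_scope must be 'mask' or 'regions'")
        for name in ("position_amplitude", "identity_amplitude", "load_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class GroundTruthPatterns:
    """Voxel patterns injected into the simulation (analysis never sees them)."""

    effect: EffectConfig
    seed: int
    # (region_id, position, phase) -> vector over the region's voxels
    position_patterns: dict[tuple[int, int, str], np.ndarray]
    # (region_id, identity) -> vector over the region's voxels
    identity_patterns: dict[tuple[int, str], np.ndarray]
    load_gradient: dict[int, float]  # position -> scalar multiplier

    def to_json(self) -> str:
        payload = {
            "sharing_mode": self.effect.sharing_mode,
            "position_amplitude": self.effect.position_amplitude,
            "identity_amplitude": self.effect.identity_amplitude,
            "load_amplitude": self.effect.load_amplitude,
            "seed": self.seed,
            "load_gradient": self.load_gradient,
            "position_patterns": {
                f"{k[0]}|{k[1]}|{k[2]}": v.tolist()
                for k, v in self.position_patterns.items()
            },
            "identity_patterns": {
                f"{k[0]}|{k[1]}": v.tolist()
                for k, v in self.identity_patterns.items()
            },
        }
        return json.dumps(payload)


def _unit_rms(v: np.ndarray) -> np.ndarray:
    rms = np.sqrt(np.mean(v ** 2))
    if rms == 0:
        raise ValueError("degenerate zero pattern")
    return v / rms


def sample_patterns(
    geometry: VolumeGeometry,
    effect: EffectConfig = EffectConfig(),
    seed: int = 0,
) -> GroundTruthPatterns:
    """Random unit-RMS patterns per region/position/phase.

    Identity patterns are orthogonalized against the span of the region's
    position patterns so item identity cannot proxy temporal position.
    """
    rng = np.random.default_rng(seed)
    positions = range(1, effect.n_positions + 1)
    pos_patterns: dict[tuple[int, int, str], np.ndarray] = {}
    id_patterns: dict[tuple[int, str], np.ndarray] = {}

    for rid in geometry.region_ids:
        nvox = len(geometry.region_rows(rid))
        for pos in positions:
            pres = _unit_rms(rng.standard_normal(nvox))
            if effect.sharing_mode == "shared":
                rec = pres
            elif effect.sharing_mode == "phase_specific":
                rec = _unit_rms(rng.standard_normal(nvox))
            else:  # drifted_first_position
                rec = _unit_rms(rng.standard_normal(nvox)) if pos == 1 else pres
            pos_patterns[(rid, pos, "presentation")] = pres
            pos_patterns[(rid, pos, "recognition")] = rec

        basis = np.stack(
            [pos_patterns[(rid, p, ph)] for p in positions
             for ph in ("presentation", "recognition")]
        ).T
        q, _ = np.linalg.qr(basis)
        for ident in IDENTITIES:
            v = rng.standard_normal(nvox)
            v = v - q @ (q.T @ v)
            id_patterns[(rid, ident)] = _unit_rms(v)

    load = {pos: float(pos - 1) / max(effect.n_positions - 1, 1) for pos in positions}
    return GroundTruthPatterns(
        effect=effect, seed=seed,
        position_patterns=pos_patterns,
        identity_patterns=id_patterns,
        load_gradient=load,
    )


# ---------------------------------------------------------------------------
# noise and runs
# ---------------------------------------------------------------------------

@dataclass
class NoiseSpec:
    thermal_sd: float = 1.0
    ar1_coefficient: float = 0.4
    drift_amplitude: float = 2.0
    cardiac_freq_hz: float = 1.1
    respiratory_freq_hz: float = 0.3
    cardiac_amplitude: float = 0.3
    respiratory_amplitude: float = 0.3
    motion_spike_rate: float = 0.005
    motion_spike_translation_mm: float = 2.0
    motion_walk_sd_mm: float = 0.01
    trace_sampling_hz: float = 20.0

    def __post_init__(self):
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must lie in [0, 1)")


@dataclass
class BOLDRun:
    """A simulated 4D acquisition plus everything recorded alongside it."""

    data: np.ndarray                 # (x, y, z, t), signal units
    geometry: VolumeGeometry
    tr_s: float
    motion_params: np.ndarray        # (t, 6): 3 translations mm, 3 rotations deg
    cardiac_trace: np.ndarray        # (n, 2): time s, value
    respiratory_trace: np.ndarray    # (n, 2)
    truth: GroundTruthPatterns
    participant_id: str = "sub-01"

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.tr_s

    def masked_timeseries(self) -> np.ndarray:
        """(t, V) matrix over in-mask voxels in the fixed analysis order."""
        return self.data[self.geometry.mask].T


def _event_regressor(onsets: Sequence[float], duration_s: float,
                     frame_times: np.ndarray) -> np.ndarray:
    """Boxcar events convolved with the canonical double-gamma HRF."""
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        return np.zeros(frame_times.size)
    cond = (onsets, np.full(onsets.size, duration_s), np.ones(onsets.size))
    signal, _ = compute_regressor(cond, "spm", frame_times)
    return signal.ravel()


def simulate_run(
    design: ExperimentDesign,
    geometry: VolumeGeometry,
    truth: GroundTruthPatterns,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    baseline: float = 100.0,
    participant_id: str = "sub-01",
) -> BOLDRun:
    """Simulate one participant's run.

    Per-event neural amplitude = identity effect + phase-appropriate position
    pattern + load gradient, applied over the relevant region's voxels; the
    event train is HRF-convolved and sampled at the TR.  Noise = slow drift +
    AR(1)-filtered thermal noise + aliased cardiac/respiratory sinusoids +
    occasional motion spikes, which couple a step artifact into the data and
    the recorded motion parameters.
    """
    if design.n_volumes == 0 and design.n_trials > 0:
        raise ValueError("design carries no scan volumes")
    if design.trials and design.trials[-1].end_s > design.duration_s:
        raise ValueError("design is longer than the scan duration")

    rng = np.random.default_rng(seed)
    T = design.n_volumes
    frame_times = np.arange(T) * design.tr_s
    mask = geometry.mask
    V = geometry.n_mask_voxels
    Y = np.zeros((V, T))

    occurrences = enumerate_occurrences(design)
    dur = design.trials[0].item_duration_s if design.trials else 3.5
    eff = truth.effect

    # phase x position components (positional code + load gradient)
    for phase in ("presentation", "recognition"):
        for pos in range(1, eff.n_positions + 1):
            onsets = [o.onset_s for o in occurrences
                      if o.phase == phase and o.position == pos]
            if not onsets:
                continue
            x = _event_regressor(onsets, dur, frame_times)
            if eff.position_amplitude:
                for rid in geometry.region_ids:
                    rows = geometry.region_rows(rid)
                    amp = eff.position_amplitude * truth.position_patterns[(rid, pos, phase)]
                    Y[rows] += np.outer(amp, x)
            if eff.load_amplitude:
                level = eff.load_amplitude * truth.load_gradient[pos]
                if eff.load_scope == "mask":
                    Y += level * x[None, :]
                else:
                    for rid in geometry.region_ids:
                        Y[geometry.region_rows(rid)] += level * x[None, :]

    # identity components (common to both phases)
    if eff.identity_amplitude:
        for ident in IDENTITIES:
            onsets = [o.onset_s for o in occurrences if o.identity == ident]
            if not onsets:
                continue
            x = _event_regressor(onsets, dur, frame_times)
            for rid in geometry.region_ids:
                rows = geometry.region_rows(rid)
                Y[rows] += np.outer(
                    eff.identity_amplitude * truth.identity_patterns[(rid, ident)], x
                )

    # --- noise ------------------------------------------------------------
    run_len = max(T * design.tr_s, 1.0)
    if noise.drift_amplitude:
        for harmonic in (1, 2):
            shape_t = np.cos(np.pi * harmonic * frame_times / run_len)
            coef = rng.standard_normal(V) * noise.drift_amplitude / harmonic
            Y += np.outer(coef, shape_t)
    if noise.thermal_sd:
        w = rng.standard_normal((V, T)) * noise.thermal_sd
        if noise.ar1_coefficient:
            w *= np.sqrt(1 - noise.ar1_coefficient ** 2)
            from scipy.signal import lfilter
            w = lfilter([1.0], [1.0, -noise.ar1_coefficient], w, axis=1)
        Y += w
    phase_c = rng.uniform(0, 2 * np.pi)
    phase_r = rng.uniform(0, 2 * np.pi)
    if noise.cardiac_amplitude:
        Y += noise.cardiac_amplitude * np.sin(
            2 * np.pi * noise.cardiac_freq_hz * frame_times + phase_c)
    if noise.respiratory_amplitude:
        Y += noise.respiratory_amplitude * np.sin(
            2 * np.pi * noise.respiratory_freq_hz * frame_times + phase_r)

    # --- motion -----------------------------------------------------------
    motion = np.cumsum(rng.standard_normal((T, 6)) * noise.motion_walk_sd_mm, axis=0)
    spikes = rng.random(T) < noise.motion_spike_rate
    spikes[0] = False
    for t_idx in np.flatnonzero(spikes):
        axis = rng.integers(3)
        jump = noise.motion_spike_translation_mm * rng.choice([-1.0, 1.0])
        motion[t_idx:, axis] += jump
        # step artifact coupled into the data for that scan
        Y[:, t_idx] += abs(jump)

    Y += baseline

    data = np.zeros(geometry.shape + (T,))
    data[mask] = Y

    # physiological traces sampled at the recorder rate
    ts = np.arange(0, T * design.tr_s, 1.0 / noise.trace_sampling_hz)
    cardiac = np.sin(2 * np.pi * noise.cardiac_freq_hz * ts + phase_c) \
        + 0.05 * rng.standard_normal(ts.size)
    resp = np.sin(2 * np.pi * noise.respiratory_freq_hz * ts + phase_r) \
        + 0.05 * rng.standard_normal(ts.size)

    return BOLDRun(
        data=data, geometry=geometry, tr_s=design.tr_s,
        motion_params=motion,
        cardiac_trace=np.column_stack([ts, cardiac]),
        respiratory_trace=np.column_stack([ts, resp]),
        truth=truth, participant_id=participant_id,
    )


def simulate_cohort(
    n_subjects: int,
    design_fn,
    geometry: VolumeGeometry,
    effect: EffectConfig = EffectConfig(),
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
) -> list[tuple[ExperimentDesign, BOLDRun]]:
    """Independent designs/noise per subject on a common grid.

    The effect configuration (sharing mode, amplitudes) is common to the
    cohort; pattern realizations are subject-specific.  ``design_fn(seed)``
    must return an :class:`~seqpos.design.ExperimentDesign`.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    out = []
    ss = np.random.SeedSequence(seed)
    for i, child in enumerate(ss.spawn(n_subjects)):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        design = design_fn(sub_seed)
        truth = sample_patterns(geometry, effect, seed=sub_seed + 1)
        run = simulate_run(design, geometry, truth, noise, seed=sub_seed + 2,
                           participant_id=f"sub-{i + 1:02d}")
        out.append((design, run))
    return out
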