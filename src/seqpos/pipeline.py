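"""End-to-end orchestration: simulate -> GLM -> searchlight -> group stats.

Scenario presets encode the logical cases the analysis is meant to
discriminate: a positional code shared between task phases, a phase-specific
code, a code whose first position drifts between phases, a pure univariate
load gradient, and a null with no positional signal at all.  Every stage's
seed derives deterministically from the master seed, so a config reproduces
its outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import bold, design, glm, group, mvpa
from .bold import EffectConfig, NoiseSpec, VolumeGeometry
from .glm import BetaImages, GLMConfig, ScrubConfig
from .group import StatsConfig
from .mvpa import MVPAConfig

logger = logging.getLogger(__name__)

SCENARIOS = ("shared", "phase_specific", "drifted_first_position", "load_only", "null")


def scenario_effect(scenario: str,
                    position_amplitude: float = 0.4,
                    identity_amplitude: float = 0.5,
                    load_amplitude: float = 0.7) -> EffectConfig:
    """Effect configuration realizing one of the scenario presets."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if scenario == "null":
        return EffectConfig(sharing_mode="shared", position_amplitude=0.0,
                            identity_amplitude=identity_amplitude, load_amplitude=0.0)
    if scenario == "load_only":
        return EffectConfig(sharing_mode="shared", position_amplitude=0.0,
                            identity_amplitude=identity_amplitude,
                            load_amplitude=load_amplitude)
    return EffectConfig(sharing_mode=scenario, position_amplitude=position_amplitude,
                        identity_amplitude=identity_amplitude, load_amplitude=0.0)


@dataclass
class PipelineConfig:
    master_seed: int = 0
    scenario: str = "shared"
    n_subjects: int = 4
    output_root: str | None = None
    # geometry
    shape: tuple[int, int, int] = (14, 14, 14)
    n_regions: int = 2
    region_voxels: int = 130
    mask_fraction: float = 0.5
    # design
    design_kind: str = "table_preset"   # or "random"
    # effects and noise
    position_amplitude: float = 0.4
    identity_amplitude: float = 0.5
    load_amplitude: float = 0.7
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    # analysis
    glm_config: GLMConfig = field(default_factory=GLMConfig)
    scrub: ScrubConfig = field(default_factory=ScrubConfig)
    mvpa_config: MVPAConfig = field(default_factory=MVPAConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    analysis_kind: str = "cross_phase"

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        raw = yaml.safe_load(text) or {}
        for key, sub in (("noise", NoiseSpec), ("glm_config", GLMConfig),
                         ("scrub", ScrubConfig), ("mvpa_config", MVPAConfig),
                         ("stats", StatsConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        if "shape" in raw:
            raw["shape"] = tuple(raw["shape"])
        return cls(**raw)


@dataclass
class SubjectResult:
    design: design.ExperimentDesign
    run: bold.BOLDRun
    betas: BetaImages
    acc_map: mvpa.AccuracyMap


@dataclass
class PipelineResult:
    config: PipelineConfig
    geometry: VolumeGeometry
    subjects: list[SubjectResult]
    distributions: np.ndarray          # (S, C, n_perm + 1)
    pmap: group.GroupPMap

    def mean_accuracy_map(self) -> np.ndarray:
        return np.mean([s.acc_map.accuracy for s in self.subjects], axis=0)


def _stage_seed(master_seed: int, stage: str, subject: int = 0) -> int:
    h = hashlib.sha256(f"{master_seed}|{stage}|{subject}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def _make_design(config: PipelineConfig, seed: int) -> design.ExperimentDesign:
    if config.design_kind == "table_preset":
        return design.replicate_table_design(seed)
    if config.design_kind == "random":
        return design.generate_design(seed)
    raise ValueError(f"unknown design_kind {config.design_kind!r}")


def run_subject(config: PipelineConfig, geometry: VolumeGeometry,
                subject: int, design_fn=None) -> SubjectResult:
    """Simulate and analyse one participant (no ground truth crosses into the
    analysis stages: the GLM and MVPA see only the run data and the schedule)."""
    seed = _stage_seed(config.master_seed, "design", subject)
    dsn = design_fn(seed) if design_fn is not None else _make_design(config, seed)
    effect = scenario_effect(config.scenario, config.position_amplitude,
                             config.identity_amplitude, config.load_amplitude)
    truth = bold.sample_patterns(
        geometry, effect, seed=_stage_seed(config.master_seed, "patterns", subject))
    run = bold.simulate_run(
        dsn, geometry, truth, config.noise,
        seed=_stage_seed(config.master_seed, "noise", subject),
        participant_id=f"sub-{subject + 1:02d}")
    occurrences = design.enumerate_occurrences(dsn)
    regressors = design.combine_occurrences(
        occurrences, seed=_stage_seed(config.master_seed, "combine", subject))
    betas = glm.estimate_betas_ls2(run, regressors, config.glm_config, config.scrub,
                                   enforce_exclusion=False)
    acc_map = mvpa.run_searchlight(
        betas, config.mvpa_config, config.analysis_kind,
        seed=_stage_seed(config.master_seed, "mvpa", subject))
    return SubjectResult(design=dsn, run=run, betas=betas, acc_map=acc_map)


def run_pipeline(config: PipelineConfig, design_fn=None) -> PipelineResult:
    """Execute all stages for a cohort and compute the group p-map.

    ``design_fn(seed)``, when given, overrides the configured design kind."""
    t0 = time.time()
    geometry = bold.make_geometry(
        shape=config.shape, seed=_stage_seed(config.master_seed, "geometry"),
        n_regions=config.n_regions, region_voxels=config.region_voxels,
        mask_fraction=config.mask_fraction)
    subjects = []
    for s in range(config.n_subjects):
        try:
            subjects.append(run_subject(config, geometry, s, design_fn))
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at subject {s}: {exc}") from exc
        logger.info("stage=subject idx=%d elapsed=%.1fs", s, time.time() - t0)

    dists = np.stack([
        group.map_permutation_distributions(
            sr.acc_map,
            StatsConfig(config.stats.n_permutations, config.stats.n_group_samples,
                        seed=_stage_seed(config.master_seed, "perm", s)),
        )
        for s, sr in enumerate(subjects)
    ])
    pmap = group.group_empirical_p(
        dists,
        StatsConfig(config.stats.n_permutations, config.stats.n_group_samples,
                    seed=_stage_seed(config.master_seed, "group")),
        centers=subjects[0].acc_map.centers)
    logger.info("stage=group elapsed=%.1fs", time.time() - t0)

    result = PipelineResult(config=config, geometry=geometry, subjects=subjects,
                            distributions=dists, pmap=pmap)
    if config.output_root:
        write_results(result, Path(config.output_root))
    return result


def write_results(result: PipelineResult, out_root: Path) -> dict:
    """Persist per-stage artifacts and a checksummed manifest."""
    from . import io as sio

    out_root = Path(out_root)
    out_root.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    for s, sr in enumerate(result.subjects):
        sub_dir = out_root / f"sub-{s + 1:02d}"
        files.extend(sio.save_run(sr.run, sub_dir).values())
        events = design.occurrences_to_events_table(
            design.enumerate_occurrences(sr.design))
        files.append(sio.save_events_tsv(events, sub_dir / "events.tsv"))
        (sub_dir / "design.json").write_text(sr.design.to_json())
        files.append(sub_dir / "design.json")
        files.extend(sio.save_betas(sr.betas, sub_dir).values())
        files.append(sio.save_nifti(sr.acc_map.accuracy, result.geometry.affine,
                                    sub_dir / "accuracy.nii"))
    files.append(sio.save_nifti(result.pmap.volume(result.geometry.shape),
                                result.geometry.affine, out_root / "group_p.nii"))
    summary = {
        "scenario": result.config.scenario,
        "n_subjects": result.config.n_subjects,
        "analysis_kind": result.config.analysis_kind,
        "mean_accuracy": float(np.mean([
            sr.acc_map.center_accuracies[sr.acc_map.evaluated].mean()
            for sr in result.subjects])),
        "min_group_p": float(result.pmap.p.min()),
        "n_centers_p_lt_0.05": int((result.pmap.p < 0.05).sum()),
    }
    files.append(sio.save_json(summary, out_root / "summary.json"))
    manifest = {
        str(p.relative_to(out_root)):
            hashlib.sha256(p.read_bytes()).hexdigest()
        for p in files
    }
    sio.save_json(manifest, out_root / "manifest.json")
    return manifest


def make_fixtures(seed: int, out_dir: Path | str) -> dict:
    """A tiny end-to-end dataset (small grid, short design, 2 subjects) for
    smoke tests and examples; loads in seconds."""
    config = PipelineConfig(
        master_seed=seed, scenario="shared", n_subjects=2,
        shape=(10, 10, 10), n_regions=1, region_voxels=60, mask_fraction=0.45,
        design_kind="random",
        mvpa_config=MVPAConfig(min_voxels=20),
        stats=StatsConfig(n_permutations=20, n_group_samples=100),
    )
    result = run_pipeline(config, design_fn=lambda s: design.generate_design(
        s, n_trials=12, n_changed_probes=1))
    return write_results(result, Path(out_dir))
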