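"""Reading and writing the pipeline's on-disk formats.

Volumes are NIfTI-1 (via nibabel), event schedules are tab-separated
BIDS-events-style tables, motion parameters are 6-column whitespace text,
physiological traces are 2-column text, and ground truth / summaries are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .bold import BOLDRun, VolumeGeometry
from .glm import BetaImages


def save_nifti(data: np.ndarray, affine: np.ndarray, path: Path | str) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.to_filename(str(path))
    return path


def load_nifti(path: Path | str) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_events_tsv(table: pd.DataFrame, path: Path | str) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def load_events_tsv(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_run(run: BOLDRun, out_dir: Path | str, stem: str = "bold") -> dict[str, Path]:
    """Write a simulated run: 4D data, mask, region labels, motion, traces,
    and the ground truth as JSON (kept separate from any analysis input)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = run.geometry.affine
    paths = {
        "bold": save_nifti(run.data, aff, out / f"{stem}.nii"),
        "mask": save_nifti(run.geometry.mask.astype(np.uint8), aff, out / "mask.nii"),
        "regions": save_nifti(run.geometry.region_labels.astype(np.int16), aff,
                              out / "regions.nii"),
    }
    np.savetxt(out / "motion.txt", run.motion_params, fmt="%.6f")
    paths["motion"] = out / "motion.txt"
    np.savetxt(out / "cardiac.txt", run.cardiac_trace, fmt="%.6f")
    paths["cardiac"] = out / "cardiac.txt"
    np.savetxt(out / "respiratory.txt", run.respiratory_trace, fmt="%.6f")
    paths["respiratory"] = out / "respiratory.txt"
    (out / "truth.json").write_text(run.truth.to_json())
    paths["truth"] = out / "truth.json"
    return paths


def save_betas(betas: BetaImages, out_dir: Path | str) -> dict[str, Path]:
    """Betas as a 4D NIfTI (one 3D volume per regressor) + a labels TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geom = betas.geometry
    vol = np.zeros(geom.shape + (betas.n_regressors,), dtype=np.float32)
    vol[geom.mask] = betas.betas.T
    paths = {
        "betas": save_nifti(vol, geom.affine, out / "betas.nii"),
        "labels": out / "beta_labels.tsv",
    }
    betas.labels.to_csv(paths["labels"], sep="\t", index=False)
    return paths


def load_geometry(dir_path: Path | str) -> VolumeGeometry:
    """Rebuild a :class:`VolumeGeometry` from mask.nii / regions.nii."""
    d = Path(dir_path)
    mask, affine = load_nifti(d / "mask.nii")
    regions, _ = load_nifti(d / "regions.nii")
    return VolumeGeometry(shape=tuple(mask.shape),
                          voxel_size_mm=tuple(np.diag(affine)[:3]),
                          mask=mask.astype(bool),
                          region_labels=regions.astype(int))


def load_run(dir_path: Path | str, stem: str = "bold",
             tr_s: float = 1.75) -> BOLDRun:
    """Rebuild a run from the files written by :func:`save_run`.

    The ground-truth record is deliberately not loaded: analysis stages
    operate on the measured data only.
    """
    d = Path(dir_path)
    geometry = load_geometry(d)
    data, _ = load_nifti(d / f"{stem}.nii")
    return BOLDRun(
        data=data, geometry=geometry, tr_s=tr_s,
        motion_params=np.loadtxt(d / "motion.txt"),
        cardiac_trace=np.loadtxt(d / "cardiac.txt"),
        respiratory_trace=np.loadtxt(d / "respiratory.txt"),
        truth=None,
    )


def load_betas(dir_path: Path | str,
               geometry: VolumeGeometry | None = None) -> BetaImages:
    """Rebuild labelled beta images from betas.nii + beta_labels.tsv."""
    d = Path(dir_path)
    if geometry is None:
        geometry = load_geometry(d)
    vol, _ = load_nifti(d / "betas.nii")
    labels = pd.read_csv(d / "beta_labels.tsv", sep="\t")
    return BetaImages(betas=vol[geometry.mask].T.astype(float), labels=labels,
                      geometry=geometry)


def save_predictions_tsv(acc_map, path: Path | str) -> Path:
    """Per-searchlight predictions: centre coordinates, analysis kind, true
    and predicted label per tested item (zero-scored centres are omitted)."""
    rows = []
    for centre, preds in zip(acc_map.centers, acc_map.predictions):
        if preds[0] < 0:
            continue
        for true, pred in zip(acc_map.true_labels, preds):
            rows.append({"x": centre[0], "y": centre[1], "z": centre[2],
                         "analysis": acc_map.analysis_kind,
                         "true_position": int(true),
                         "predicted_position": int(pred)})
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def save_json(obj, path: Path | str) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=1, default=_jsonable))
    return path


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
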