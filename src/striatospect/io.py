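"""File formats: NIfTI volumes, sinogram containers, CSV tables, manifests.

Volumes travel as NIfTI-1 with the voxel size in the header affine.
Sinograms are stored as a raw ``.npy`` count array plus a JSON sidecar
holding the acquisition geometry, so a round trip is bit-exact.  Metric
tables are CSV with fixed column schemas.  Every CLI run writes a
:class:`RunManifest` listing outputs, seeds and a config hash that is
stable under key reordering.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .projector import AcquisitionGeometry, Sinogram

__all__ = [
    "write_volume", "read_volume", "write_sinogram", "read_sinogram",
    "write_table", "read_table", "config_hash", "RunManifest",
    "write_labels_legend", "write_study_result",
]


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def config_hash(config) -> str:
    """SHA-256 of the canonical (sorted-keys) JSON form of *config*."""
    payload = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def write_volume(path, values: np.ndarray, voxel_size_mm: float) -> Path:
    path = Path(path)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), affine)
    img.header.set_zooms((voxel_size_mm,) * 3)
    nib.save(img, path)
    return path


def read_volume(path) -> Tuple[np.ndarray, float]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise ValueError(f"anisotropic voxels in {path}: {zooms}")
    return np.asarray(img.dataobj, dtype=np.float64), float(zooms[0])


def write_labels_legend(path, legend: Dict[int, str]) -> Path:
    path = Path(path)
    path.write_text(json.dumps({str(k): v for k, v in legend.items()},
                               indent=2))
    return path


def write_sinogram(path_base, sinogram: Sinogram) -> Tuple[Path, Path]:
    """``<base>.npy`` (counts) + ``<base>.json`` (geometry sidecar)."""
    base = Path(path_base)
    npy = base.with_suffix(".npy")
    np.save(npy, sinogram.counts)
    sidecar = {
        "shape": list(sinogram.counts.shape),
        "geometry": _jsonable(sinogram.geometry),
        "voxel_size_mm": sinogram.voxel_size_mm,
        "noiseless": sinogram.noiseless,
        "provenance": _jsonable(sinogram.provenance),
    }
    js = base.with_suffix(".json")
    js.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return npy, js


def read_sinogram(path_base) -> Sinogram:
    base = Path(path_base)
    counts = np.load(base.with_suffix(".npy"))
    sidecar = json.loads(base.with_suffix(".json").read_text())
    if list(counts.shape) != sidecar["shape"]:
        raise ValueError("sinogram array shape does not match its sidecar")
    geom = AcquisitionGeometry(**sidecar["geometry"])
    return Sinogram(counts=counts, geometry=geom,
                    voxel_size_mm=sidecar["voxel_size_mm"],
                    noiseless=sidecar["noiseless"],
                    provenance=sidecar.get("provenance", {}))


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_table(path, columns: Optional[List[str]] = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if columns is not None and list(df.columns) != list(columns):
        raise ValueError(f"unexpected columns in {path}: {list(df.columns)}")
    return df


@dataclass
class RunManifest:
    """Record of one pipeline run: config hash, seeds, outputs."""

    stage: str
    config_sha256: str
    seeds: Dict[str, int] = field(default_factory=dict)
    files: Dict[str, str] = field(default_factory=dict)  # role -> path
    version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__
            self.version = __version__
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")

    def add(self, role: str, path) -> None:
        self.files[role] = str(path)

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(_jsonable(self), indent=2, sort_keys=True))
        return path


def write_study_result(result, out_dir) -> RunManifest:
    """CSV tables + manifest for a completed phantom study."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(stage="phantom-study",
                           config_sha256=config_hash(result.config),
                           seeds={"master_seed": result.config.master_seed})
    manifest.add("voi_stats", write_table(result.voi_stats, out / "voi_stats.csv"))
    manifest.add("curves", write_table(result.curves_frame(), out / "curves.csv"))
    manifest.add("matched", write_table(result.matched, out / "matched.csv"))
    manifest.add("matched_detail",
                 write_table(result.matched_detail, out / "matched_detail.csv"))
    manifest.add("regressions",
                 write_table(result.regressions, out / "regressions.csv"))
    refs = pd.DataFrame([{"v": v, "p": p, "true_sur": val}
                         for (v, p), val in result.refs.items()])
    manifest.add("refs", write_table(refs, out / "true_sur.csv"))
    manifest.write(out / "manifest.json")
    return manifest
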