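"""Interchange formats: TIFF rasters, polyline/polygon CSV, YAML config,
and run manifests.

CSV dialect: comma-separated, UTF-8, header row required, '.' decimal.
Trace coordinates are px (tied to an image); EM coordinates are nm.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import JunctionTrace, PLANAR

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline constants, serializable to/from YAML losslessly.

    Defaults carry the method's fixed values: 400-nm correlation band,
    1/3-max apical reference fraction, 3/37/38-nm EM thresholds, and an
    80-nm PSF FWHM.
    """

    pixel_size: float = 20.0  # nm/px
    orientation: str = PLANAR
    band_width: float = 400.0  # nm
    profile_step: float = 20.0  # nm
    profile_half_length: float = 1000.0  # nm
    normalization_mode: str = "unit_integral"
    reference_fraction: float = 1.0 / 3.0
    straightness_threshold: float = 0.05
    psf_fwhm: float = 80.0  # nm
    em_linkage_lower: float = 3.0  # nm
    em_linkage_upper: float = 37.0  # nm
    em_membrane_threshold: float = 38.0  # nm
    max_lag: int = 50  # px
    clamp: bool = False
    seed: int = 0
    out_dir: str = "out"

    def __post_init__(self):
        for name in (
            "pixel_size",
            "band_width",
            "profile_step",
            "profile_half_length",
            "psf_fwhm",
            "em_linkage_upper",
            "em_membrane_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_image(path) -> np.ndarray:
    """Read a single- or multi-page grayscale TIFF.

    Returns a 2D array for one page or ``(pages, rows, cols)`` for
    several, in page order.  RGB input or a missing/truncated file is an
    explicit error naming the path.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise ValueError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] not in (3, 4):
        raise ValueError(f"RGB image not supported: {path}")
    if arr.ndim not in (2, 3):
        raise ValueError(f"unsupported TIFF dimensionality {arr.ndim}: {path}")
    return arr


def write_image(path, array: np.ndarray) -> None:
    """Write a 16-bit grayscale TIFF (values clipped to the uint16 range;
    multiple channels go to pages)."""
    arr = np.asarray(array)
    out = np.clip(np.round(arr), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), out)


_REQUIRED_COLUMNS = {
    "trace": ["junction_id", "vertex_index", "x_px", "y_px"],
    "membrane": ["vertex_index", "x_nm", "y_nm"],
    "polygon": ["polygon_id", "vertex_index", "x_nm", "y_nm"],
}


def read_polyline_csv(path, kind: str = "trace"):
    """Read grouped, ordered polylines/polygons from CSV.

    Rows are sorted by vertex_index within each group, so shuffled rows
    with a valid index yield identical structures.  Missing columns and
    duplicate (group, vertex_index) pairs raise with the offending
    row/column named.

    Returns: ``trace`` -> dict junction_id -> JunctionTrace;
    ``membrane`` -> (n, 2) nm array; ``polygon`` -> dict polygon_id ->
    (k, 2) nm array.
    """
    if kind not in _REQUIRED_COLUMNS:
        raise ValueError(f"unknown kind {kind!r}")
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    if kind == "membrane":
        dup = df["vertex_index"].duplicated()
        if dup.any():
            raise ValueError(f"{path}: duplicate vertex_index at row {int(dup.idxmax()) + 2}")
        df = df.sort_values("vertex_index")
        return df[["x_nm", "y_nm"]].to_numpy(dtype=float)

    group_col = "junction_id" if kind == "trace" else "polygon_id"
    dup = df.duplicated(subset=[group_col, "vertex_index"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate ({group_col}, vertex_index) at row {int(dup.idxmax()) + 2}"
        )
    out = {}
    for gid, sub in df.groupby(group_col, sort=False):
        sub = sub.sort_values("vertex_index")
        if kind == "trace":
            pts = sub[["x_px", "y_px"]].to_numpy(dtype=float)
            apical = None
            if {"apical_dx", "apical_dy"}.issubset(sub.columns):
                v = sub[["apical_dx", "apical_dy"]].iloc[0].to_numpy(dtype=float)
                if np.all(np.isfinite(v)) and np.hypot(*v) > 0:
                    apical = v
            out[gid] = JunctionTrace(points=pts, image_id=str(gid), apical_direction=apical)
        else:
            out[gid] = sub[["x_nm", "y_nm"]].to_numpy(dtype=float)
    return out


def write_traces_csv(path, traces: Dict[str, JunctionTrace]) -> None:
    rows = []
    for jid, tr in traces.items():
        for i, (x, y) in enumerate(tr.points):
            row = {"junction_id": jid, "vertex_index": i, "x_px": x, "y_px": y}
            if tr.apical_direction is not None:
                row["apical_dx"] = tr.apical_direction[0]
                row["apical_dy"] = tr.apical_direction[1]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_particles_csv(path) -> pd.DataFrame:
    """Per-particle table with columns id, x_nm, y_nm."""
    df = pd.read_csv(path)
    missing = [c for c in ("id", "x_nm", "y_nm") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_manifest(path, config: RunConfig, stage: str, inputs: List[str]) -> None:
    """Machine-readable record sufficient to re-execute a stage."""
    import junctionmap

    manifest = {
        "stage": stage,
        "inputs": sorted(str(i) for i in inputs),
        "config": dataclasses.asdict(config),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "versions": {
            "junctionmap": junctionmap.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
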