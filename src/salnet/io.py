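"""File formats: surface time series, motion/flags/phenotype tables.

Real-mode surface BOLD arrives as CIFTI-2 dense time series
(``*.dtseries.nii``) or GIFTI functional series (``*.func.gii``), read via
nibabel with vertices ordered left-hemisphere-then-right (CIFTI brain-model
order; medial-wall vertices are whatever the file carries — the count is
validated against the configured atlas, and the dialect is recorded in
provenance). Synthetic mode uses a documented flat-binary format:
little-endian float64, row-major vertices x time, with a JSON sidecar
(``<path>.json``) holding V, T, TR (seconds), and the generating seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BoldRun

__all__ = [
    "write_flat_bold",
    "read_surface_timeseries",
    "write_motion_tsv",
    "read_motion_tsv",
    "write_flags_tsv",
    "read_flags_tsv",
    "write_phenotypes_tsv",
    "read_phenotypes_tsv",
]

FLAT_FORMAT = "salnet-flat-v1"
MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def write_flat_bold(bold: BoldRun, path: str | Path, seed: int | None = None) -> Path:
    """Write a run in the flat-binary dialect (binary matrix + JSON sidecar)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(bold.data, dtype="<f8")
    data.tofile(path)
    sidecar = {
        "format": FLAT_FORMAT,
        "V": int(bold.V),
        "T": int(bold.T),
        "TR": float(bold.tr),
        "dtype": "<f8",
        "order": "C",
        "seed": seed,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def _read_flat(path: Path) -> BoldRun:
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"flat-binary sidecar missing: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    if meta.get("format") != FLAT_FORMAT:
        raise ValueError(f"unknown flat-binary format tag {meta.get('format')!r}")
    data = np.fromfile(path, dtype="<f8")
    V, T = int(meta["V"]), int(meta["T"])
    if data.size != V * T:
        raise ValueError(
            f"flat-binary payload has {data.size} values, sidecar implies {V}x{T}"
        )
    return BoldRun(data=data.reshape(V, T), tr=float(meta["TR"]))


def _read_cifti(path: Path) -> BoldRun:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)  # (T, greyordinates)
    axis = img.header.get_axis(0)
    step = float(axis.step)
    unit = getattr(axis, "unit", "second") or "second"
    tr = step / 1000.0 if "milli" in str(unit) else step
    return BoldRun(data=data.T, tr=tr)


def _read_gifti(path: Path) -> BoldRun:
    import nibabel as nib

    img = nib.load(str(path))
    if not img.darrays:
        raise ValueError(f"GIFTI file {path} carries no data arrays")
    data = np.column_stack([np.asarray(d.data, dtype=np.float64) for d in img.darrays])
    tr = 0.0
    meta = dict(img.meta) if img.meta else {}
    for key in ("TimeStep", "TR"):
        if key in meta:
            tr = float(meta[key])
            break
    if tr > 10:  # header stored in milliseconds
        tr /= 1000.0
    if tr <= 0:
        raise ValueError(f"GIFTI file {path} lacks a usable TimeStep/TR")
    return BoldRun(data=data, tr=tr)


def read_surface_timeseries(path: str | Path, expected_V: int | None = None) -> BoldRun:
    """Read surface BOLD from CIFTI-2, GIFTI, or the flat-binary dialect.

    ``expected_V`` (usually the configured atlas size) triggers a vertex
    count check with a descriptive mismatch error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name
    if name.endswith(".dtseries.nii"):
        run = _read_cifti(path)
    elif name.endswith(".func.gii"):
        run = _read_gifti(path)
    elif name.endswith(".gii") or name.endswith(".nii"):
        raise ValueError(
            f"unsupported surface format for {name}: expected *.dtseries.nii, "
            "*.func.gii, or the flat-binary dialect"
        )
    else:
        run = _read_flat(path)
    if expected_V is not None and run.V != expected_V:
        raise ValueError(
            f"vertex count mismatch: file {path.name} has {run.V} vertices, "
            f"configured atlas expects {expected_V}"
        )
    return run


def write_motion_tsv(motion: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = motion.copy()
    out.columns = MOTION_COLUMNS[: len(out.columns)]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_motion_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 6:
        raise ValueError(f"motion table must have 6 columns, found {df.shape[1]}")
    return df


def write_flags_tsv(flags: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"flagged": np.asarray(flags, dtype=int)}).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_flags_tsv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["flagged"].to_numpy(dtype=bool)


def write_phenotypes_tsv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_phenotypes_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
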