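"""File interchange: NIfTI phantoms, tidy CSV tables, JSON registries/manifests."""
from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .phantom import SlicePhantom
from .regions import SliceID


class SchemaError(ValueError):
    """A CSV is missing required columns."""


REQUIRED_COLUMNS = {
    "cohort": ["subject_id", "age_months", "group"],
    "hu": ["subject_id", "method", "region", "hu"],
    "gwr": ["subject_id", "formula_id", "value"],
}


def save_phantom(phantom: SlicePhantom, outdir: Path, subject_id: str | None = None) -> tuple[Path, Path]:
    """Write ``<subject>_<slice>_img.nii.gz`` / ``..._lbl.nii.gz`` pairs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sid = subject_id or phantom.subject_id or "subject"
    sp = phantom.pixel_spacing
    affine = np.diag([sp, sp, 1.0, 1.0])
    img_path = outdir / f"{sid}_{phantom.slice_id.value}_img.nii.gz"
    lbl_path = outdir / f"{sid}_{phantom.slice_id.value}_lbl.nii.gz"
    nib.save(nib.Nifti1Image(phantom.image.astype(np.float32), affine), img_path)
    nib.save(nib.Nifti1Image(phantom.labels.astype(np.int16), affine), lbl_path)
    return img_path, lbl_path


def load_phantom(outdir: Path, subject_id: str, slice_id: SliceID | str) -> SlicePhantom:
    sl = SliceID(slice_id)
    outdir = Path(outdir)
    img = nib.load(outdir / f"{subject_id}_{sl.value}_img.nii.gz")
    lbl = nib.load(outdir / f"{subject_id}_{sl.value}_lbl.nii.gz")
    spacing = float(img.header.get_zooms()[0])
    return SlicePhantom(
        slice_id=sl,
        image=np.asarray(img.dataobj, dtype=np.float64),
        labels=np.asarray(lbl.dataobj, dtype=np.int16),
        pixel_spacing=spacing,
        subject_id=subject_id,
    )


def write_csv(frame: pd.DataFrame, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


def read_csv(path: Path, schema: str | None = None) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if schema is not None:
        missing = [c for c in REQUIRED_COLUMNS[schema] if c not in frame.columns]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
    return frame


def write_json(obj, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(outdir: Path, seed, config: dict, files: list[Path]) -> Path:
    """One manifest per output directory: version, config, seed, checksums."""
    outdir = Path(outdir)
    manifest = {
        "tool": "pedct",
        "version": __version__,
        "seed": seed,
        "config": config,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "files": {
            str(Path(f).relative_to(outdir)): _sha256(f) for f in files if Path(f).exists()
        },
    }
    return write_json(manifest, outdir / "manifest.json")
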