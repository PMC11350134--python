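"""File formats: NIfTI images, long-table CSV, reports, configuration."""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ConfigError
from .phantom import LabelMap, VolumeImage
from .quantify import LONG_TABLE_COLUMNS

_NUMERIC_COLUMNS = ("age", "atrophy", "true_cl", "native_fwhm", "suvr", "cl")
_KEY_COLUMNS = ["subject_id", "pipeline_id", "harmonized"]


def save_image(img: VolumeImage, path) -> None:
    nifti = nib.Nifti1Image(np.asarray(img.grid, dtype=np.float32), img.affine)
    nifti.header["descrip"] = f"fwhm={img.effective_fwhm:.4f}".encode()
    nib.save(nifti, str(path))


def load_image(path) -> VolumeImage:
    nifti = nib.load(str(path))
    fwhm = 0.0
    descrip = bytes(nifti.header["descrip"].item() or b"").decode(errors="ignore")
    if descrip.startswith("fwhm="):
        fwhm = float(descrip.split("=", 1)[1])
    voxel = float(nifti.header.get_zooms()[0])
    return VolumeImage(np.asarray(nifti.get_fdata(), dtype=float), voxel,
                       np.asarray(nifti.affine), fwhm)


def save_labelmap(labels: LabelMap, path) -> None:
    nib.save(nib.Nifti1Image(labels.grid.astype(np.uint8), labels.affine),
             str(path))


def load_labelmap(path) -> LabelMap:
    nifti = nib.load(str(path))
    return LabelMap(np.asarray(nifti.get_fdata()).astype(np.uint8),
                    float(nifti.header.get_zooms()[0]),
                    np.asarray(nifti.affine))


def save_mask(mask: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def write_long_table(table: pd.DataFrame, path) -> None:
    missing = [c for c in LONG_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigError(f"long table lacks required columns: {missing}")
    extra = [c for c in table.columns if c not in LONG_TABLE_COLUMNS]
    table[LONG_TABLE_COLUMNS + extra].to_csv(path, index=False)


def read_long_table(path) -> pd.DataFrame:
    """Read and validate a long-format CL table.

    Unknown columns are preserved; missing required columns and duplicate
    (subject, pipeline, harmonization) keys are hard errors.
    """
    table = pd.read_csv(path)
    missing = [c for c in LONG_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigError(f"long table lacks required columns: {missing}")
    for col in _NUMERIC_COLUMNS:
        table[col] = pd.to_numeric(table[col], errors="raise")
    if table["harmonized"].dtype != bool:
        table["harmonized"] = table["harmonized"].astype(str).str.lower().map(
            {"true": True, "false": False, "1": True, "0": False})
        if table["harmonized"].isna().any():
            raise ConfigError("harmonized column is not boolean")
    dup = table.duplicated(subset=_KEY_COLUMNS, keep=False)
    if dup.any():
        key = table.loc[dup, _KEY_COLUMNS].iloc[0].tolist()
        raise ConfigError(f"duplicate (subject, pipeline, harmonized) key: {key}")
    return table


def export_report(results: dict, out_dir) -> list[Path]:
    """Write result tables/objects with deterministic names and content."""
    if not results:
        raise ConfigError("nothing to export")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def emit(name, payload):
        path = out / name
        if isinstance(payload, pd.DataFrame):
            payload.to_csv(path, index=False)
        elif isinstance(payload, str):
            path.write_text(payload)
        else:
            path.write_text(json.dumps(payload, indent=1, sort_keys=True,
                                       default=_jsonable))
        written.append(path)

    for key, payload in sorted(results.items()):
        if key == "calibration_bank":
            emit("calibration_bank.json", payload.to_json())
        elif key == "long_table":
            path = out / "long_table.csv"
            write_long_table(payload, path)
            written.append(path)
        elif isinstance(payload, pd.DataFrame):
            emit(f"{key}.csv", payload)
        else:
            emit(f"{key}.json", payload)
    return written


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return {k: v for k, v in vars(obj).items()
                if not k.startswith("_")}
    raise TypeError(f"not JSON serialisable: {type(obj)}")
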