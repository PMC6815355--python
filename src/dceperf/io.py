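"""NIfTI-1 and CSV round-trips with schema validation.

4D DCE series and 3D label/metric volumes are stored as NIfTI-1 via nibabel;
the frame spacing rides in ``pixdim[4]`` (seconds) and the number of
pre-contrast frames in the header description, so a series round-trips with
its temporal metadata. Trial tables are UTF-8 CSV with a header row and ""
as the missing-value token.
"""

from __future__ import annotations

import re
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .quantify import DceSeries, VoiMask

__all__ = [
    "write_dce_series",
    "read_dce_series",
    "write_label_volume",
    "read_label_volume",
    "write_mask",
    "read_mask",
    "write_trial_table",
    "read_trial_table",
]

_REQUIRED_TRIAL_COLUMNS = (
    "participant_id",
    "arm",
    "gender",
    "age",
    "weight",
    "attendance",
    "exercised_outside",
    "complete_dce",
)
_OUTCOME_COLUMN = re.compile(r"^[a-z0-9_]+_(baseline|followup)$")


def write_dce_series(series: DceSeries, path: str | Path) -> Path:
    """Write a 4D series as NIfTI-1, embedding the temporal metadata."""
    path = Path(path)
    img = nib.Nifti1Image(series.signal.astype(np.float64), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, float(series.frame_spacing_s)))
    img.header["descrip"] = f"nbase={series.n_baseline_frames}".encode()
    nib.save(img, path)
    return path


def read_dce_series(path: str | Path) -> DceSeries:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got {data.ndim}D")
    zooms = img.header.get_zooms()
    spacing = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 9.0
    descrip = bytes(img.header["descrip"]).decode(errors="ignore")
    m = re.search(r"nbase=(\d+)", descrip)
    n_base = int(m.group(1)) if m else 2
    return DceSeries(signal=data, frame_spacing_s=spacing, n_baseline_frames=n_base)


def write_label_volume(labels: np.ndarray, path: str | Path) -> Path:
    """Write a 3D integer label volume (mask, ground-truth map, class map)."""
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine=np.eye(4)), path)
    return path


def read_label_volume(path: str | Path) -> np.ndarray:
    data = np.asarray(nib.load(str(path)).dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    return data.astype(np.int16)


def write_metric_volume(vol: np.ndarray, path: str | Path) -> Path:
    """Write a 3D float parametric map."""
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float64), affine=np.eye(4)), path)
    return path


def write_mask(mask: VoiMask, path: str | Path) -> Path:
    return write_label_volume(mask.labels, path)


def read_mask(path: str | Path) -> VoiMask:
    return VoiMask(read_label_volume(path))


def write_trial_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, na_rep="")
    return path


def read_trial_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Required columns must be present; any other column must be an
    ``<outcome>_baseline`` / ``<outcome>_followup`` pair member, otherwise the
    unknown columns are reported by name.
    """
    table = pd.read_csv(path)
    missing = [c for c in _REQUIRED_TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    unknown = [
        c
        for c in table.columns
        if c not in _REQUIRED_TRIAL_COLUMNS and not _OUTCOME_COLUMN.match(c)
    ]
    if unknown:
        raise ValueError(f"{path}: unknown columns: {unknown}")
    if table["participant_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate participant ids")
    table["exercised_outside"] = table["exercised_outside"].astype(bool)
    table["complete_dce"] = table["complete_dce"].astype(bool)
    return table
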