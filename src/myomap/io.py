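"""NIfTI and CSV readers/writers for volumes, masks, maps and records.

Conventions: CT volumes are written as signed 16-bit HU, binary masks as
unsigned 8-bit {0,1}, deviation maps as 32-bit float with NaN outside the
myocardium; voxel spacing and orientation live in the NIfTI header.  All
tables are UTF-8 CSV with a header row; proportions are stored unscaled
and formatted as percentages only for display.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .colormap import CTVolume, DeviationMap

__all__ = [
    "write_volume",
    "read_volume",
    "write_mask",
    "read_mask",
    "write_map",
    "read_map_data",
    "write_records",
    "read_records",
    "write_truth",
    "read_truth",
]

RECORD_COLUMNS = [
    "session",
    "reader_id",
    "case_id",
    "condition",
    "hypodense",
    "certainty",
    "territory",
    "time_s",
]
TRUTH_COLUMNS = ["case_id", "adjudication", "territory"]


def _affine(spacing, affine) -> np.ndarray:
    if affine is not None:
        return np.asarray(affine, dtype=float)
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def write_volume(volume: CTVolume, path: str | Path) -> None:
    data = np.rint(volume.data).astype(np.int16)
    img = nib.Nifti1Image(data, _affine(volume.spacing, volume.affine))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_volume(path: str | Path) -> CTVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(data, spacing=spacing, affine=np.asarray(img.affine))


def write_mask(mask: np.ndarray, path: str | Path, spacing=(1.0, 1.0, 1.0), affine=None) -> None:
    img = nib.Nifti1Image(np.asarray(mask).astype(np.uint8), _affine(spacing, affine))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(bool)


def write_map(map_: DeviationMap, path: str | Path) -> None:
    img = nib.Nifti1Image(
        map_.data.astype(np.float32), _affine(map_.spacing, map_.affine)
    )
    img.header.set_zooms(map_.spacing)
    nib.save(img, str(path))


def read_map_data(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(float)


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    records[RECORD_COLUMNS].to_csv(path, index=False, lineterminator="\n")


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"reader_id": str, "case_id": str})
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records file missing columns: {sorted(missing)}")
    return df[RECORD_COLUMNS]


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth[TRUTH_COLUMNS].to_csv(path, index=False, lineterminator="\n")


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"case_id": str})
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"truth file missing columns: {sorted(missing)}")
    return df[TRUTH_COLUMNS]
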