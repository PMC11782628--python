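"""Readers and writers for the package's on-disk formats.

Events and confounds travel as BIDS-style tab-separated tables, volumes as
NIfTI, and ground-truth / manifest records as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .simulate.bold import VolumeSeries

__all__ = [
    "write_events_tsv", "read_events_tsv",
    "write_confounds_tsv", "read_confounds_tsv",
    "write_volume", "read_volume",
    "write_json", "read_json",
]


def write_events_tsv(events: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events.to_csv(path, sep="\t", index=False, na_rep="n/a")
    return path


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"])


def write_confounds_tsv(confounds: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    confounds.to_csv(path, sep="\t", index=False)
    return path


def read_confounds_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_volume(volume, path, affine=None, tr: float | None = None) -> Path:
    """Write a VolumeSeries, 3D/4D array or Nifti1Image to disk."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(volume, VolumeSeries):
        img = volume.to_nifti()
    elif isinstance(volume, nib.Nifti1Image):
        img = volume
    else:
        img = nib.Nifti1Image(np.asarray(volume, np.float64),
                              np.eye(4) if affine is None else affine)
        if tr is not None and img.ndim == 4:
            img.header.set_zooms((*img.header.get_zooms()[:3], tr))
    nib.save(img, str(path))
    return path


def read_volume(path) -> nib.Nifti1Image:
    return nib.load(str(path))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder))
    return path


def read_json(path):
    return json.loads(Path(path).read_text())
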