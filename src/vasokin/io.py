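"""Readers and writers for the pipeline's standard formats.

Conventions fixed here (the acquisition itself prescribes none): volumes are
NIfTI with axis order (x, y, z[, t]) and explicit voxel sizes in the header
(mm); cast stacks are multi-page TIFF with pages along z; arterial input
functions are CSV with a ``time_s`` column and one column per agent;
tabular results are CSV/JSON.  Coordinates are voxel-indexed and 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile


# -- NIfTI ----------------------------------------------------------------

def save_nifti(data, path, voxel_size_mm=(1.0, 1.0, 1.0), t_spacing_s=1.0):
    data = np.asarray(data)
    affine = np.diag(list(voxel_size_mm[:3]) + [1.0])
    img = nib.Nifti1Image(data.astype(np.float64), affine)
    zooms = list(voxel_size_mm[:3]) + ([t_spacing_s] if data.ndim == 4 else [])
    img.header.set_zooms(tuple(zooms))
    if data.ndim == 4:
        img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.header.get_zooms()


# -- TIFF -----------------------------------------------------------------

def save_tiff_stack(stack, path, voxel_size_um=28.0):
    tifffile.imwrite(str(path), np.asarray(stack).astype(np.float32),
                     metadata={"voxel_size_um": float(voxel_size_um)})


def load_tiff_stack(path):
    return np.asarray(tifffile.imread(str(path)), dtype=float)


# -- tables ---------------------------------------------------------------

def save_aif_csv(time_s, aifs, agents, path):
    df = pd.DataFrame({"time_s": np.asarray(time_s, dtype=float)})
    for name, curve in zip(agents, np.atleast_2d(aifs)):
        df[name] = curve
    df.to_csv(path, index=False)


def load_aif_csv(path):
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("AIF CSV must contain a 'time_s' column")
    agents = [c for c in df.columns if c != "time_s"]
    return df["time_s"].to_numpy(), df[agents].to_numpy().T, agents


def save_bvalues(b_values, path):
    np.savetxt(path, np.asarray(b_values, dtype=float), fmt="%.6g")


def load_bvalues(path):
    b = np.loadtxt(path, dtype=float).reshape(-1)
    if b.size == 0:
        raise ValueError(f"b-value table {path} is empty")
    return b


def save_json(obj, path):
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.bool_):
            return bool(o)
        raise TypeError(type(o))
    Path(path).write_text(json.dumps(obj, indent=2, default=default))
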