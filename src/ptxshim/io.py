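"""File interfaces: HDF5 coil maps, NIfTI volumes, CSV lead trajectories,
JSON weights/results, YAML configuration."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .core_model import Grid3D, LeadModel
from .shim_core import CoilFieldMaps, ShimWeights

__all__ = [
    "save_coil_maps",
    "load_coil_maps",
    "save_volume_nifti",
    "load_volume_nifti",
    "save_lead_csv",
    "load_lead_csv",
    "save_weights_json",
    "load_weights_json",
    "load_yaml_config",
]


def save_coil_maps(path, maps: CoilFieldMaps) -> None:
    """Write per-channel maps: groups /coils/<n>/ with E_real, E_imag
    (nx, ny, nz, 3; V/m) and B1_real, B1_imag (nx, ny, nz; tesla)."""
    with h5py.File(path, "w") as f:
        f.attrs["spacing"] = maps.grid.spacing
        f.attrs["origin"] = maps.grid.origin
        f.attrs["frequency"] = maps.frequency
        f.attrs["meta"] = json.dumps(maps.meta)
        coils = f.create_group("coils")
        for n in range(maps.n_channels):
            g = coils.create_group(str(n))
            g.create_dataset("E_real", data=maps.E[n].real)
            g.create_dataset("E_imag", data=maps.E[n].imag)
            g.create_dataset("B1_real", data=maps.B1[n].real)
            g.create_dataset("B1_imag", data=maps.B1[n].imag)


def load_coil_maps(path) -> CoilFieldMaps:
    with h5py.File(path, "r") as f:
        spacing = tuple(np.asarray(f.attrs["spacing"], float))
        origin = tuple(np.asarray(f.attrs["origin"], float))
        meta = json.loads(f.attrs.get("meta", "{}"))
        frequency = float(f.attrs["frequency"])
        keys = sorted(f["coils"].keys(), key=int)
        E, B1 = [], []
        for k in keys:
            g = f["coils"][k]
            E.append(np.asarray(g["E_real"]) + 1j * np.asarray(g["E_imag"]))
            B1.append(np.asarray(g["B1_real"]) + 1j * np.asarray(g["B1_imag"]))
    dims = B1[0].shape
    grid = Grid3D(dims=dims, spacing=spacing, origin=origin)
    return CoilFieldMaps(
        grid=grid, E=np.stack(E), B1=np.stack(B1), frequency=frequency, meta=meta
    )


def _affine(grid: Grid3D) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def save_volume_nifti(path, volume: np.ndarray, grid: Grid3D) -> None:
    """One scalar volume per file; the affine encodes spacing and origin."""
    img = nib.Nifti1Image(np.asarray(volume, np.float32), _affine(grid))
    nib.save(img, str(path))


def load_volume_nifti(path) -> tuple[np.ndarray, Grid3D]:
    img = nib.load(str(path))
    aff = img.affine
    data = np.asarray(img.dataobj)
    grid = Grid3D(
        dims=data.shape[:3],
        spacing=tuple(np.diag(aff)[:3]),
        origin=tuple(aff[:3, 3]),
    )
    return data, grid


def save_lead_csv(path, lead: LeadModel) -> None:
    """One vertex per row, header x,y,z, coordinates in metres."""
    np.savetxt(
        path, lead.vertices, delimiter=",", header="x,y,z", comments="", fmt="%.9g"
    )


def load_lead_csv(path, **lead_kwargs) -> LeadModel:
    verts = np.loadtxt(path, delimiter=",", skiprows=1)
    return LeadModel(vertices=verts, **lead_kwargs)


def save_weights_json(path, weights: ShimWeights) -> None:
    Path(path).write_text(json.dumps(weights.to_dict(), indent=2))


def load_weights_json(path) -> ShimWeights:
    return ShimWeights.from_dict(json.loads(Path(path).read_text()))


def load_yaml_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}
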