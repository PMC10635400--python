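"""Readers and writers for the package's on-disk formats.

Spectral cubes are HDF5 (``cube`` float32 [y, x, lambda] plus
``wavelengths_nm``), label masks 16-bit TIFF, D maps float32 TIFF with a
YAML sidecar, look-up tables two-column CSV with a YAML provenance sidecar,
and cohorts plain CSV tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .dmap import DMap, SpectralCube
from .optics import SigmaDLUT, build_lut_from_provenance

__all__ = [
    "write_cube", "read_cube", "write_mask", "read_mask",
    "write_dmap", "read_dmap", "write_lut", "read_lut",
    "write_cohort", "read_cohort_tables",
]


def write_cube(path, cube: SpectralCube):
    with h5py.File(path, "w") as fh:
        fh.create_dataset("cube", data=cube.data.astype(np.float32))
        fh.create_dataset("wavelengths_nm", data=cube.wavelengths)
        fh.attrs["normalized"] = cube.normalized
        fh.attrs["meta"] = json.dumps(cube.meta)


def read_cube(path) -> SpectralCube:
    with h5py.File(path, "r") as fh:
        data = fh["cube"][...].astype(float)
        wl = fh["wavelengths_nm"][...]
        meta = json.loads(fh.attrs.get("meta", "{}"))
        normalized = bool(fh.attrs.get("normalized", False))
    return SpectralCube(data=data, wavelengths=wl, normalized=normalized,
                        meta=meta)


def write_mask(path, mask: np.ndarray):
    tifffile.imwrite(path, np.asarray(mask, np.uint16))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path)


def write_dmap(path, dmap: DMap):
    """Float32 TIFF (page 0: D, page 1: Sigma) + YAML sidecar with the LUT
    id, noise floor and clamp statistics."""
    path = Path(path)
    tifffile.imwrite(path, np.stack([dmap.d_values, dmap.sigma_values])
                     .astype(np.float32))
    tifffile.imwrite(path.with_suffix(".mask.tif"),
                     np.asarray(dmap.mask, np.uint16))
    inside = dmap.mask > 0
    sidecar = {
        "provenance": dmap.provenance,
        "clamped_frac": float((dmap.flags[inside] > 0).mean())
        if inside.any() else 0.0,
        "n_masked_pixels": int(inside.sum()),
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))


def read_dmap(path) -> DMap:
    path = Path(path)
    pages = tifffile.imread(path)
    mask = tifffile.imread(path.with_suffix(".mask.tif"))
    sidecar = yaml.safe_load(path.with_suffix(".yaml").read_text())
    d, sigma = pages[0].astype(float), pages[1].astype(float)
    flags = np.zeros_like(mask, dtype=np.uint8)
    return DMap(d_values=d, sigma_values=sigma, mask=mask, flags=flags,
                provenance=sidecar.get("provenance", {}))


def write_lut(path, lut: SigmaDLUT):
    """Two-column CSV (``D,sigma``) plus ``.yaml`` provenance sidecar."""
    path = Path(path)
    pd.DataFrame({"D": lut.d_grid, "sigma": lut.sigma_grid}).to_csv(
        path, index=False)
    sidecar = {"provenance": lut.provenance, "lut_id": lut.lut_id}
    if lut.estimator_nodes is not None:
        sidecar["estimator"] = {
            "nodes": [float(x) for x in lut.estimator_nodes],
            "values": [float(x) for x in lut.estimator_values],
        }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))


def read_lut(path, rebuild: bool = False) -> SigmaDLUT:
    """Load a LUT from CSV + sidecar; with ``rebuild=True`` recompute it
    from provenance instead (bitwise identical for identical code)."""
    path = Path(path)
    sidecar = yaml.safe_load(path.with_suffix(".yaml").read_text())
    if rebuild:
        return build_lut_from_provenance(sidecar["provenance"])
    df = pd.read_csv(path)
    est = sidecar.get("estimator")
    return SigmaDLUT(
        df["D"].to_numpy(), df["sigma"].to_numpy(), sidecar["provenance"],
        estimator_nodes=None if est is None else np.asarray(est["nodes"]),
        estimator_values=None if est is None else np.asarray(est["values"]))


def write_cohort(prefix, cohort):
    """Write ``<prefix>_patients.csv`` and ``<prefix>_cells.csv``."""
    prefix = Path(prefix)
    cohort.to_patient_table().to_csv(
        prefix.parent / f"{prefix.name}_patients.csv", index=False)
    cohort.to_cell_table().to_csv(
        prefix.parent / f"{prefix.name}_cells.csv", index=False)


def read_cohort_tables(prefix):
    prefix = Path(prefix)
    patients = pd.read_csv(prefix.parent / f"{prefix.name}_patients.csv")
    cells = pd.read_csv(prefix.parent / f"{prefix.name}_cells.csv")
    return patients, cells
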