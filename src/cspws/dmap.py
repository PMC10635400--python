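"""From spectral cubes to Sigma maps, per-pixel D maps and nuclear averages."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import NormalizationError, QualityError, ProvenanceWarning
from .optics import SigmaDLUT, sigma_to_d, FLAG_OK

__all__ = [
    "SpectralCube", "DMap", "NuclearAverage",
    "normalize_cube", "compute_sigma_map", "compute_dmap",
    "nuclear_average_d", "estimate_noise_floor",
]


@dataclass
class SpectralCube:
    """Reference-normalized interference spectra, indexed ``[y, x, lambda]``."""

    data: np.ndarray
    wavelengths: np.ndarray
    normalized: bool = False
    reference: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        self.wavelengths = np.asarray(self.wavelengths, float)
        if self.data.ndim != 3:
            raise ValueError("cube must be 3D [y, x, lambda]")
        if self.data.shape[2] != len(self.wavelengths):
            raise ValueError("lambda axis does not match wavelength grid")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly ascending")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values")


@dataclass
class DMap:
    """Per-pixel packing scaling map with Sigma, mask, clamp flags."""

    d_values: np.ndarray
    sigma_values: np.ndarray
    mask: np.ndarray
    flags: np.ndarray
    provenance: dict = field(default_factory=dict)


@dataclass
class NuclearAverage:
    label: int
    mean_d: float
    n_pixels: int
    clamped_frac: float


def normalize_cube(raw: np.ndarray, reference: np.ndarray,
                   wavelengths) -> SpectralCube:
    """Divide by the blank-region reference spectrum and subtract unity."""
    reference = np.asarray(reference, float)
    bad = np.where(reference <= 0)[0]
    if bad.size:
        raise NormalizationError(
            f"reference spectrum non-positive at wavelength indices {bad.tolist()}")
    data = np.asarray(raw, float) / reference[None, None, :] - 1.0
    return SpectralCube(data=data, wavelengths=np.asarray(wavelengths, float),
                        normalized=True, reference=reference)


def compute_sigma_map(cube: SpectralCube) -> np.ndarray:
    """Per-pixel population standard deviation of the spectrum across
    wavelengths (the spectral mean is removed by the definition of the
    standard deviation)."""
    if not cube.normalized:
        raise ValueError("cube must be reference-normalized first")
    if cube.data.shape[2] < 2:
        raise ValueError("need at least two wavelengths")
    return cube.data.std(axis=2, ddof=0)


def estimate_noise_floor(cube: SpectralCube, blank_mask: np.ndarray) -> float:
    """Noise floor as the RMS Sigma over signal-free (blank) pixels."""
    sig = compute_sigma_map(cube)
    vals = sig[np.asarray(blank_mask, bool)]
    if vals.size == 0:
        raise ValueError("blank mask selects no pixels")
    return float(np.sqrt(np.mean(vals ** 2)))


def compute_dmap(cube: SpectralCube, mask: np.ndarray, lut: SigmaDLUT,
                 noise_floor: float = 0.0,
                 provenance_mismatch: str = "warn") -> DMap:
    """Sigma map + LUT inversion inside the nucleus mask.

    Pixels outside the mask are NaN.  If the cube records the optics it was
    simulated or acquired with and they disagree with the LUT provenance,
    a :class:`ProvenanceWarning` is issued (or an error raised when
    ``provenance_mismatch='error'``).
    """
    mask = np.asarray(mask)
    if mask.shape != cube.data.shape[:2]:
        raise ValueError("mask shape does not match cube transverse shape")
    cube_opt = cube.meta.get("optics")
    if cube_opt is not None:
        lut_opt = lut.provenance.get("optics", {})
        keys = ("n_media", "alpha", "depth_of_field", "axial_step")
        diffs = [k for k in keys if not np.isclose(cube_opt.get(k, np.nan),
                                                   lut_opt.get(k, np.nan))]
        if list(cube_opt.get("wavelengths", [])) != list(lut_opt.get("wavelengths", [])):
            diffs.append("wavelengths")
        if diffs:
            msg = f"cube optics disagree with LUT provenance on {diffs}"
            if provenance_mismatch == "error":
                raise ValueError(msg)
            warnings.warn(msg, ProvenanceWarning)
    sigma = compute_sigma_map(cube)
    d = np.full(sigma.shape, np.nan)
    flags = np.zeros(sigma.shape, dtype=np.uint8)
    inside = mask > 0
    if np.any(inside):
        d_in, f_in = sigma_to_d(sigma[inside], lut, noise_floor=noise_floor)
        d[inside] = d_in
        flags[inside] = f_in
    return DMap(d_values=d, sigma_values=sigma, mask=mask, flags=flags,
                provenance={"lut_id": lut.lut_id,
                            "noise_floor": float(noise_floor)})


def nuclear_average_d(dmap: DMap, label: int,
                      include_clamped: bool = True) -> NuclearAverage:
    """Mean packing scaling over one nucleus.

    The calibrated per-pixel estimator is unbiased over its full output
    distribution, so clamped pixels are included by default; the clamped
    fraction is always reported as a quality metric.  Requires at least one
    unclamped pixel.
    """
    sel = dmap.mask == label
    if not np.any(sel):
        raise KeyError(f"label {label} absent from mask")
    flags = dmap.flags[sel]
    vals = dmap.d_values[sel]
    unclamped = flags == FLAG_OK
    if not np.any(unclamped):
        raise QualityError(f"all pixels of nucleus {label} are clamped")
    use = vals if include_clamped else vals[unclamped]
    return NuclearAverage(label=int(label), mean_d=float(np.mean(use)),
                          n_pixels=int(sel.sum()),
                          clamped_frac=float(1.0 - unclamped.mean()))
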