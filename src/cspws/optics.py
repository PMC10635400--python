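"""Chromatin autocorrelation model and the interference forward/inverse map.

The refractive index inside a nucleus is ``n(r) = n_media + alpha * rho(r)``
where ``rho`` is the macromolecular density fluctuation.  Within a packing
domain the density autocorrelation function (ACF) ``B(r)`` follows a power
law whose log-log slope encodes the packing scaling exponent::

    D - 3 = d log B(r) / d log r       (r_min <= r <= r_max)

The spectral interference signal of a partial-wave measurement has, per
pixel, a standard deviation across wavelengths (``Sigma``) whose expected
value is a band-limited functional of ``B``.  This module provides

* :func:`acf_model` -- the truncated power-law ACF family,
* :func:`forward_sigma` -- expected Sigma for a given ``D`` (either through
  the exact interference transfer window derived from the optics, or an
  idealized flat/raised-cosine band window),
* :func:`build_lut` / :func:`sigma_to_d` -- tabulated monotone inversion,
  optionally calibrated so that the *per-pixel* estimator is unbiased under
  the finite spectral sampling noise of a single measurement.

With the ACF anchored at the inner scale (``B(r_min) = sigma_n_sq``) the
interference functional is monotone *decreasing* in D over the physical
range; the idealized positive band windows are monotone increasing.  The
look-up table records its own orientation and the inversion handles both.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import lsq_linear
from scipy.special import gammaln

from .exceptions import ModelConfigError

__all__ = [
    "ACFParams",
    "OpticsConfig",
    "SigmaDLUT",
    "acf_model",
    "forward_sigma",
    "sigma_moments",
    "transfer_window",
    "band_constant",
    "build_lut",
    "build_lut_from_provenance",
    "sigma_to_d",
    "FLAG_OK",
    "FLAG_CLAMPED_LOW",
    "FLAG_CLAMPED_HIGH",
]

#: per-pixel inversion flags
FLAG_OK = 0
FLAG_CLAMPED_LOW = 1   # sigma outside range on the low-D side
FLAG_CLAMPED_HIGH = 2  # sigma outside range on the high-D side


@dataclass(frozen=True)
class ACFParams:
    """Parameters of the chromatin mass-density ACF.

    Parameters
    ----------
    d : float
        Packing scaling exponent, physical range (1, 3].
    sigma_n_sq : float
        Variance of the refractive-index fluctuation at the inner scale.
    r_min, r_max : float
        Inner and outer length scales of the power-law regime, nm.  The
        defaults span the 23-334 nm sensitivity band of the instrument.
    phi : float
        Chromatin volume concentration, in (0, 1).  Enters the model as
        provenance (it rescales the fluctuation amplitude upstream); it is
        not estimated per pixel.
    n_f : float
        Genomic size of a packing domain in base pairs (informational).
    """

    d: float
    sigma_n_sq: float = 1e-3
    r_min: float = 23.0
    r_max: float = 334.0
    phi: float = 0.35
    n_f: float = 200_000.0

    def __post_init__(self):
        if not (1.0 < self.d <= 3.6):
            # the physical range is (1, 3]; values up to 3.6 are accepted so
            # LUT grids may pad beyond the physical ceiling
            raise ValueError(f"packing scaling d={self.d} outside (1, 3.6]")
        if not (0.0 < self.r_min < self.r_max):
            raise ValueError("need 0 < r_min < r_max")
        if self.sigma_n_sq < 0:
            raise ValueError("sigma_n_sq must be >= 0")
        if not (0.0 < self.phi < 1.0):
            raise ValueError("phi must lie in (0, 1)")

    def replace(self, **kw) -> "ACFParams":
        d = asdict(self)
        d.update(kw)
        return ACFParams(**d)


def _default_wavelengths() -> tuple:
    return tuple(np.arange(500.0, 700.0 + 1e-9, 2.0))


@dataclass(frozen=True)
class OpticsConfig:
    """Instrument geometry and the spectral acquisition grid.

    Wavelengths default to 500-700 nm in 2 nm steps (101 bands).  The axial
    depth of field ``depth_of_field`` (~3 um) bounds the interference
    integral; ``axial_step`` is the axial quadrature step, which must also
    match the axial voxel size of any simulated density field the forward
    model is compared against.
    """

    wavelengths: tuple = field(default_factory=_default_wavelengths)
    n_media: float = 1.337
    alpha: float = 0.18
    na_illum: float = 0.6
    na_collect: float = 0.8
    coherence_xy: float = 458.0     # transverse coherence length per side, nm
    depth_of_field: float = 3000.0  # axial extent L, nm
    axial_step: float = 10.0        # quadrature / voxel step, nm
    smoothing_kernel: str = "interference"  # or "flat", "raised_cosine"
    kernel_edge: float = 0.1        # raised-cosine edge fraction

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, float)
        if wl.ndim != 1 or len(wl) < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing, >= 2")
        if not self.n_media > 1.0:
            raise ValueError("n_media must exceed 1")
        if self.depth_of_field <= 0 or self.axial_step <= 0:
            raise ValueError("depth_of_field and axial_step must be positive")
        if not (0.0 < self.na_illum <= self.na_collect < self.n_media):
            raise ValueError("need 0 < na_illum <= na_collect < n_media")
        if self.smoothing_kernel not in ("interference", "flat", "raised_cosine"):
            raise ValueError(f"unknown smoothing_kernel {self.smoothing_kernel!r}")
        object.__setattr__(self, "wavelengths", tuple(float(w) for w in wl))

    @property
    def wavelength_array(self) -> np.ndarray:
        return np.asarray(self.wavelengths, float)

    @property
    def amplitude_norm(self) -> float:
        """Normalization c0 of the interference integral (1/L)."""
        return 1.0 / self.depth_of_field

    def replace(self, **kw) -> "OpticsConfig":
        d = asdict(self)
        d.update(kw)
        return OpticsConfig(**d)


# ---------------------------------------------------------------------------
# ACF family

def acf_model(r, params: ACFParams):
    """Evaluate the density ACF ``B(r)`` at separation ``r`` (nm).

    Piecewise: constant ``sigma_n_sq`` below the inner scale, power law with
    log-log slope ``d - 3`` on ``[r_min, r_max]``, exponential rolloff with
    decay length ``r_max`` beyond the outer scale.  Continuous everywhere.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError("separation r must be positive")
    scalar = r_arr.ndim == 0
    r_arr = np.atleast_1d(r_arr)
    s2, rmin, rmax, d = params.sigma_n_sq, params.r_min, params.r_max, params.d
    out = np.empty_like(r_arr)
    inner = r_arr <= rmin
    mid = (r_arr > rmin) & (r_arr <= rmax)
    outer = r_arr > rmax
    out[inner] = s2
    out[mid] = s2 * (r_arr[mid] / rmin) ** (d - 3.0)
    b_edge = s2 * (rmax / rmin) ** (d - 3.0)
    out[outer] = b_edge * np.exp(-(r_arr[outer] - rmax) / rmax)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# interference transfer kernel (cached per optics configuration)

@lru_cache(maxsize=8)
def _kernel(optics: OpticsConfig):
    """Axial grid, centered cosine design matrix and its Gram kernel."""
    nz = int(round(optics.depth_of_field / optics.axial_step))
    z = (np.arange(nz) + 0.5) * optics.axial_step
    k = 4.0 * np.pi * optics.n_media / optics.wavelength_array
    a = np.cos(np.outer(k, z))
    ac = a - a.mean(axis=0, keepdims=True)  # spectral mean removal
    g = ac.T @ ac / len(k)
    return z, g


@lru_cache(maxsize=8)
def _kernel_sqrt(optics: OpticsConfig):
    _, g = _kernel(optics)
    lam, u = eigh(g)
    return (u * np.sqrt(np.clip(lam, 0.0, None))) @ u.T


def _line_cov(params: ACFParams, optics: OpticsConfig) -> np.ndarray:
    """Axial line covariance matrix with its 1D spectrum clipped at zero.

    Clipping mirrors the spectral-synthesis generator, which clips the
    (possibly slightly indefinite) transform of the truncated ACF so the
    target covariance is valid.
    """
    dz = optics.axial_step
    nz = int(round(optics.depth_of_field / dz))
    n = 1 << max(12, int(np.ceil(np.log2(4 * nz))))
    lag = np.minimum(np.arange(n), n - np.arange(n)) * dz
    b = acf_model(lag, params)
    spec = np.clip(np.fft.rfft(b).real, 0.0, None)
    b_valid = np.fft.irfft(spec, n)
    idx = np.abs(np.arange(nz)[:, None] - np.arange(nz)[None, :])
    return b_valid[idx]


def transfer_window(optics: OpticsConfig) -> tuple[np.ndarray, np.ndarray]:
    """Lag-domain instrument transfer window ``T(r)``.

    Returns the lags (nm) and weights such that
    ``E[Sigma^2] = (c0*alpha*dz)^2 * (w[0] B(0) + 2 sum_m w[m] B(m dz))``.
    """
    z, g = _kernel(optics)
    nz = len(z)
    w = np.array([np.trace(g, offset=m) for m in range(nz)])
    lags = np.arange(nz) * optics.axial_step
    return lags, w


def band_constant(optics: OpticsConfig) -> float:
    """Constant ``C`` of the idealized band-window model ``Sigma^2 = C int B T dr``."""
    return optics.alpha ** 2 / optics.depth_of_field


def _band_window(r, params: ACFParams, optics: OpticsConfig):
    rmin, rmax = params.r_min, params.r_max
    t = ((r >= rmin) & (r <= rmax)).astype(float)
    if optics.smoothing_kernel == "raised_cosine":
        edge = optics.kernel_edge * (rmax - rmin)
        lo = (r >= rmin) & (r < rmin + edge)
        hi = (r > rmax - edge) & (r <= rmax)
        t[lo] = 0.5 * (1 - np.cos(np.pi * (r[lo] - rmin) / edge))
        t[hi] = 0.5 * (1 - np.cos(np.pi * (rmax - r[hi]) / edge))
    return t


def sigma_moments(params: ACFParams, optics: OpticsConfig) -> tuple[float, float]:
    """Mean and variance of the per-pixel ``Sigma^2`` statistic.

    Only defined for the interference kernel; both moments follow from the
    quadratic form ``Sigma^2 = x' K x`` of the Gaussian axial column.
    """
    z, g = _kernel(optics)
    cb = _line_cov(params, optics)
    scale = (optics.amplitude_norm * optics.alpha * optics.axial_step) ** 2
    m = scale * (cb @ g)
    mu = float(np.trace(m))
    var = float(2.0 * np.sum(m * m.T))
    return mu, var


def forward_sigma(params: ACFParams, optics: OpticsConfig,
                  statistic: str = "mean") -> float:
    """Expected interference-spectrum standard deviation ``Sigma``.

    For the ``interference`` kernel the per-pixel ``Sigma^2`` is a quadratic
    form in the Gaussian density column, approximated as a scaled chi-square
    by moment matching (Welch--Satterthwaite); ``statistic`` selects what is
    reported: the expected Sigma (``"mean"``, default), the root of the
    expected ``Sigma^2`` (``"rms"``) or the geometric mean (``"geometric"``).
    For the idealized band windows Sigma is deterministic:
    ``sqrt(C * int B(r) T(r) dr)``.
    """
    if params.sigma_n_sq == 0.0:
        return 0.0
    if optics.smoothing_kernel == "interference":
        mu, var = sigma_moments(params, optics)
        if mu <= 0.0:
            return 0.0
        if statistic == "rms":
            return float(np.sqrt(mu))
        dof = 2.0 * mu * mu / var
        if statistic == "mean":
            return float(np.sqrt(2.0 * mu / dof)
                         * np.exp(gammaln((dof + 1) / 2) - gammaln(dof / 2)))
        if statistic == "geometric":
            from scipy.special import digamma
            return float(np.sqrt(mu / dof)
                         * np.exp(0.5 * (np.log(2.0) + digamma(dof / 2))))
        raise ValueError(f"unknown statistic {statistic!r}")
    # idealized positive band window: quadrature of B * T
    r = np.linspace(params.r_min, params.r_max, 4001)
    b = acf_model(r, params)
    t = _band_window(r, params, optics)
    integral = np.trapezoid(b * t, r)
    return float(np.sqrt(band_constant(optics) * integral))


# ---------------------------------------------------------------------------
# look-up table and inversion

@dataclass
class SigmaDLUT:
    """Tabulated ``Sigma(D)`` curve with optional pixel-calibrated inverse.

    ``sigma_grid`` is strictly monotone over ``d_grid`` (orientation in
    ``increasing``).  When ``estimator_nodes``/``estimator_values`` are
    present, :func:`sigma_to_d` uses them: they define a monotone estimator
    ``g(sigma)`` calibrated so that the mean of ``g`` over the per-pixel
    sampling distribution of Sigma equals the true D.
    """

    d_grid: np.ndarray
    sigma_grid: np.ndarray
    provenance: dict
    increasing: bool = True
    estimator_nodes: np.ndarray | None = None
    estimator_values: np.ndarray | None = None

    def __post_init__(self):
        self.d_grid = np.asarray(self.d_grid, float)
        self.sigma_grid = np.asarray(self.sigma_grid, float)
        if len(self.d_grid) != len(self.sigma_grid) or len(self.d_grid) < 2:
            raise ValueError("grids must have equal length >= 2")
        diffs = np.diff(self.sigma_grid)
        if np.all(diffs > 0):
            self.increasing = True
        elif np.all(diffs < 0):
            self.increasing = False
        else:
            raise ModelConfigError(
                "sigma grid is not strictly monotone in D; "
                "the configured smoothing window does not yield an invertible map")

    @property
    def grid_spacing(self) -> float:
        return float(np.max(np.diff(self.d_grid)))

    @property
    def lut_id(self) -> str:
        blob = json.dumps(self.provenance, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _default_d_grid() -> np.ndarray:
    return np.round(np.arange(1.5, 3.0 + 1e-9, 0.01), 10)


def _calibrate_estimator(params_template: ACFParams, optics: OpticsConfig,
                         d_lo: float, d_hi: float, n_sim: int, rank: int,
                         n_nodes: int, ridge: float, seed: int):
    """Solve ``E[g(Sigma) | D] = D`` for a monotone decreasing ``g``.

    The sampling distribution of Sigma at each D follows from the
    eigenvalues of the interference quadratic form; a fixed-seed draw of
    chi-square weights makes the construction deterministic.  ``g`` is a
    piecewise-linear function on quantile-placed sigma nodes, constrained
    monotone through a nonnegative-increment parameterization and fit by
    bounded least squares with a small ridge penalty on the increments.
    """
    d_targets = np.round(np.arange(d_lo, d_hi + 1e-9, 0.01), 10)
    sqk = _kernel_sqrt(optics)
    scale = (optics.amplitude_norm * optics.alpha * optics.axial_step) ** 2
    rng = np.random.default_rng(seed)
    z2 = rng.standard_normal((n_sim, rank)) ** 2
    samples = []
    for d in d_targets:
        cb = _line_cov(params_template.replace(d=float(d)), optics)
        ev = np.sort(np.linalg.eigvalsh(scale * (sqk @ cb @ sqk)))[::-1]
        head = np.clip(ev[:rank], 0.0, None)
        tail = float(np.clip(ev[rank:], 0.0, None).sum())
        samples.append(np.sqrt(z2 @ head + tail))
    pooled = np.concatenate(samples)
    nodes = np.quantile(pooled, np.linspace(5e-4, 1 - 5e-4, n_nodes))
    nodes = np.unique(nodes)
    n_nodes = len(nodes)
    weights = np.zeros((len(d_targets), n_nodes))
    for t, s in enumerate(samples):
        idx = np.clip(np.searchsorted(nodes, s), 1, n_nodes - 1)
        w = np.clip((s - nodes[idx - 1]) / (nodes[idx] - nodes[idx - 1]), 0.0, 1.0)
        np.add.at(weights[t], idx, w)
        np.add.at(weights[t], idx - 1, 1.0 - w)
    weights /= n_sim
    lower_tri = np.tril(np.ones((n_nodes, n_nodes)), -1)
    design = np.hstack([np.ones((len(d_targets), 1)), -weights @ lower_tri])
    design_r = np.vstack(
        [design, np.hstack([np.zeros((n_nodes, 1)), ridge * np.eye(n_nodes)])])
    target_r = np.concatenate([d_targets, np.zeros(n_nodes)])
    fit = lsq_linear(design_r, target_r,
                     bounds=([-np.inf] + [0.0] * n_nodes,
                             [np.inf] * (n_nodes + 1)))
    values = fit.x[0] - lower_tri @ fit.x[1:]
    return nodes, values


def build_lut(params_template: ACFParams, optics: OpticsConfig,
              d_grid=None, statistic: str = "mean",
              calibrate: bool = False, calib_d_range: tuple = (1.8, 3.0),
              calib_n_sim: int = 4000, calib_rank: int = 40,
              calib_n_nodes: int = 60, calib_ridge: float = 1e-3,
              calib_seed: int = 12345) -> SigmaDLUT:
    """Tabulate ``forward_sigma`` over a D grid.

    Raises :class:`ModelConfigError` if the resulting curve is not strictly
    monotone.  With ``calibrate=True`` (interference kernel only) the LUT
    additionally carries the pixel-calibrated estimator ``g(sigma)`` whose
    conditional mean over the per-pixel Sigma distribution reproduces the
    true D across ``calib_d_range``; its output range deliberately extends
    past the physical ceiling so nuclear averages stay unbiased.
    """
    if d_grid is None:
        d_grid = _default_d_grid()
    d_grid = np.asarray(d_grid, float)
    if np.any(np.diff(d_grid) <= 0):
        raise ValueError("d_grid must be strictly ascending")
    sigma_grid = np.array([
        forward_sigma(params_template.replace(d=float(d)), optics, statistic)
        for d in d_grid])
    # normalized to plain JSON types so serialization round-trips exactly
    prov = {
        "params": asdict(params_template),
        "optics": asdict(optics),
        "d_grid": [float(x) for x in d_grid],
        "statistic": statistic,
        "calibrate": bool(calibrate),
        "calib": {
            "d_range": list(calib_d_range), "n_sim": calib_n_sim,
            "rank": calib_rank, "n_nodes": calib_n_nodes,
            "ridge": calib_ridge, "seed": calib_seed,
        },
    }
    prov = json.loads(json.dumps(prov))
    nodes = values = None
    if calibrate:
        if optics.smoothing_kernel != "interference":
            raise ModelConfigError(
                "pixel calibration requires the interference kernel")
        nodes, values = _calibrate_estimator(
            params_template, optics, calib_d_range[0], calib_d_range[1],
            calib_n_sim, calib_rank, calib_n_nodes, calib_ridge, calib_seed)
    return SigmaDLUT(d_grid, sigma_grid, prov,
                     estimator_nodes=nodes, estimator_values=values)


def build_lut_from_provenance(provenance: dict) -> SigmaDLUT:
    """Rebuild a LUT from its serialized provenance (bitwise reproducible)."""
    params = ACFParams(**provenance["params"])
    opt_kw = dict(provenance["optics"])
    opt_kw["wavelengths"] = tuple(opt_kw["wavelengths"])
    optics = OpticsConfig(**opt_kw)
    c = provenance["calib"]
    return build_lut(params, optics,
                     d_grid=np.asarray(provenance["d_grid"]),
                     statistic=provenance["statistic"],
                     calibrate=provenance["calibrate"],
                     calib_d_range=tuple(c["d_range"]), calib_n_sim=c["n_sim"],
                     calib_rank=c["rank"], calib_n_nodes=c["n_nodes"],
                     calib_ridge=c["ridge"], calib_seed=c["seed"])


def sigma_to_d(sigma, lut: SigmaDLUT, noise_floor: float = 0.0):
    """Invert Sigma (value or map) to packing scaling D.

    The measured Sigma is first corrected for additive detection noise in
    quadrature, ``sigma_c = sqrt(max(sigma^2 - noise_floor^2, 0))``, then
    mapped through the LUT's calibrated estimator if present, else by
    monotone linear interpolation of the forward curve.  Returns
    ``(d, flags)`` with flags 0 (ok), 1 (clamped at the low-D end) or
    2 (clamped at the high-D end).  NaN inputs (e.g. outside a mask)
    propagate as NaN with flag 0.
    """
    sig = np.asarray(sigma, dtype=float)
    scalar = sig.ndim == 0
    sig = np.atleast_1d(sig)
    finite = np.isfinite(sig)
    if np.any(sig[finite] < 0):
        raise ValueError("sigma must be nonnegative")
    if noise_floor < 0:
        raise ValueError("noise_floor must be nonnegative")
    sig_c = np.sqrt(np.clip(sig ** 2 - noise_floor ** 2, 0.0, None))
    if lut.estimator_nodes is not None:
        x, y = lut.estimator_nodes, lut.estimator_values
    elif lut.increasing:
        x, y = lut.sigma_grid, lut.d_grid
    else:
        x, y = lut.sigma_grid[::-1], lut.d_grid[::-1]
    d = np.interp(sig_c, x, y)
    d[~finite] = np.nan
    flags = np.zeros(sig.shape, dtype=np.uint8)
    lo_d_side = x[0] if y[0] < y[-1] else x[-1]   # sigma bound mapping to min D
    if y[0] < y[-1]:
        below, above = sig_c < x[0], sig_c > x[-1]
        flags[below & finite] = FLAG_CLAMPED_LOW
        flags[above & finite] = FLAG_CLAMPED_HIGH
    else:
        flags[(sig_c > x[-1]) & finite] = FLAG_CLAMPED_LOW
        flags[(sig_c < x[0]) & finite] = FLAG_CLAMPED_HIGH
    if scalar:
        return float(d[0]), int(flags[0])
    return d, flags
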