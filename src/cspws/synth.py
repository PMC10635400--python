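"""Synthetic inputs: mass-fractal density fields, spectral cubes, nucleus
masks and images, and patient cohorts with group-level packing-scaling
structure.

Everything is seeded and bitwise reproducible.  The generators emulate the
study conditions: 101 spectral bands over 500-700 nm, a >30 cells-per-patient
floor, group mean shifts expressed as standardized effect sizes, and
colonoscopy-history strata feeding the 5-year risk model.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .dmap import SpectralCube
from .exceptions import PlacementError
from .optics import ACFParams, OpticsConfig, acf_model
from . import risk as risk_mod

__all__ = [
    "DensityField", "GroupSpec", "CohortSpec", "PatientRecord", "Cohort",
    "gen_density_field", "simulate_spectral_cube", "gen_nucleus_masks",
    "gen_cohort", "gen_history_table", "gen_nucleus_image",
    "gen_cohort_images", "two_group_spec", "five_group_risk_spec",
    "empirical_acf_radial",
]


@dataclass
class DensityField:
    """Zero-mean Gaussian density fluctuation field on a regular grid.

    ``values`` is indexed ``[y, x, z]``; ``voxel_size`` gives the grid step
    per axis in nm (the axial step must resolve the inner length scale).
    """

    values: np.ndarray
    voxel_size: tuple
    seed: int
    params: ACFParams | None = None

    def __post_init__(self):
        v = self.values
        if v.ndim != 3 or min(v.shape) < 8:
            raise ValueError("field must be 3D with >= 8 voxels per axis")
        if abs(v.mean()) > 1e-6 * max(v.std(), 1e-300):
            raise ValueError("field is not zero mean")

    @property
    def axial_step(self) -> float:
        return self.voxel_size[2]

    @property
    def axial_extent(self) -> float:
        return self.values.shape[2] * self.voxel_size[2]


def _grid_acf(params: ACFParams, shape, spacing) -> np.ndarray:
    axes = []
    for n, d in zip(shape, spacing):
        i = np.arange(n)
        axes.append(np.minimum(i, n - i) * d)  # periodic min-image distance
    rr = np.sqrt(axes[0][:, None, None] ** 2
                 + axes[1][None, :, None] ** 2
                 + axes[2][None, None, :] ** 2)
    return acf_model(rr, params)


def gen_density_field(params: ACFParams, shape, voxel_size, seed: int) -> DensityField:
    """Spectral synthesis of a Gaussian field with target ACF ``acf_model``.

    The ACF is evaluated on the periodic grid, transformed, clipped at zero
    (guaranteeing a valid covariance despite the truncation edits to B) and
    used to color white noise.  The axial (last) axis is the sensing axis:
    its step must be <= r_min/2 and its extent >= 2 r_max.  Transverse axes
    may be sampled coarsely (e.g. one column per coherence area).
    """
    shape = tuple(int(n) for n in shape)
    if np.isscalar(voxel_size):
        spacing = (float(voxel_size),) * 3
    else:
        spacing = tuple(float(v) for v in voxel_size)
    if spacing[2] > params.r_min / 2:
        raise ValueError(
            f"axial voxel {spacing[2]} nm too coarse for inner scale "
            f"{params.r_min} nm (need <= r_min/2)")
    if shape[2] * spacing[2] < 2 * params.r_max:
        raise ValueError("axial extent must cover >= 2 r_max")
    bg = _grid_acf(params, shape, spacing)
    psd = np.clip(np.fft.fftn(bg).real, 0.0, None)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    values = np.fft.ifftn(np.fft.fftn(white) * np.sqrt(psd)).real
    values -= values.mean()
    return DensityField(values, spacing, seed, params)


def empirical_acf_radial(field: DensityField, n_bins: int = 40,
                         correct_finite_volume: bool = True):
    """Radially averaged sample ACF of a (cubic-voxel) field via FFT.

    A zero-mean periodic field's sample ACF estimates ``B(r) - mean(B)``
    over the grid (the sample ACF of a mean-removed field integrates to
    zero); with ``correct_finite_volume`` and a field that carries its
    target parameters, that exact offset is added back so the profile
    estimates ``B(r)`` itself.  Returns bin-center radii (nm) and ACF
    estimates; used to verify the realized log-log slope against the
    target ``d - 3``.
    """
    v = field.values - field.values.mean()
    n = np.prod(v.shape)
    spec = np.abs(np.fft.fftn(v)) ** 2
    acf = np.fft.ifftn(spec).real / n
    axes = []
    for npts, d in zip(v.shape, field.voxel_size):
        i = np.arange(npts)
        axes.append(np.minimum(i, npts - i) * d)
    rr = np.sqrt(axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2
                 + axes[2][None, None, :] ** 2)
    rmax = min(s * d for s, d in zip(v.shape, field.voxel_size)) / 2
    bins = np.linspace(0, rmax, n_bins + 1)
    idx = np.digitize(rr.ravel(), bins) - 1
    sums = np.bincount(idx, weights=acf.ravel(), minlength=n_bins + 1)
    counts = np.bincount(idx, minlength=n_bins + 1)
    with np.errstate(invalid="ignore"):
        prof = sums[:n_bins] / counts[:n_bins]
    centers = 0.5 * (bins[:-1] + bins[1:])
    if correct_finite_volume and field.params is not None:
        prof = prof + _grid_acf(field.params, v.shape,
                                field.voxel_size).mean()
    return centers, prof


def simulate_spectral_cube(field: DensityField, optics: OpticsConfig,
                           noise_sd: float = 0.0, seed: int = 0) -> SpectralCube:
    """First-Born interference spectra of each transverse pixel's column.

    Per pixel, ``s(lambda) = c0 * dz * sum_z alpha * rho(x, y, z) *
    cos(4 pi n_media z / lambda)`` plus i.i.d. Gaussian detection noise of
    standard deviation ``noise_sd``.  The cube is reference-normalized by
    construction and carries the optics and the amplitude constant ``c0``
    used, so the forward model can be compared against it consistently.
    """
    if field.axial_extent < optics.depth_of_field - 1e-9:
        raise ValueError("field axial extent shorter than the depth of field")
    dz = field.axial_step
    nz = int(round(optics.depth_of_field / dz))
    z = (np.arange(nz) + 0.5) * dz
    k = 4.0 * np.pi * optics.n_media / optics.wavelength_array
    basis = np.cos(np.outer(z, k))  # [z, lambda]
    c0 = optics.amplitude_norm
    data = c0 * optics.alpha * dz * (field.values[:, :, :nz] @ basis)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    meta = {
        "seed": int(seed), "field_seed": int(field.seed),
        "noise_sd": float(noise_sd), "c0": float(c0),
        "optics": asdict(optics),
    }
    if field.params is not None:
        meta["d_true"] = float(field.params.d)
    return SpectralCube(data=data, wavelengths=optics.wavelength_array,
                        normalized=True, meta=meta)


# ---------------------------------------------------------------------------
# nucleus masks / images

@dataclass
class EllipseSpec:
    label: int
    cy: float
    cx: float
    a: float      # semi-axis along y, px
    b: float      # semi-axis along x, px
    theta: float  # orientation, rad


def gen_nucleus_masks(n_nuclei: int, image_shape, radius_range=(8, 16),
                      seed: int = 0, max_attempts: int = 2000):
    """Place non-overlapping elliptical nuclei by rejection sampling.

    Returns ``(labels, ellipses)``: a label image (0 background, 1..n) and
    the generating :class:`EllipseSpec` list (the analytic areas are the
    ground truth for segmentation tests).
    """
    h, w = image_shape
    labels = np.zeros((h, w), dtype=np.uint16)
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    ellipses = []
    for lab in range(1, n_nuclei + 1):
        for attempt in range(max_attempts):
            a = rng.uniform(*radius_range)
            b = rng.uniform(*radius_range)
            theta = rng.uniform(0, np.pi)
            m = max(a, b) + 1
            if 2 * m >= min(h, w):
                continue
            cy = rng.uniform(m, h - m)
            cx = rng.uniform(m, w - m)
            ct, st = np.cos(theta), np.sin(theta)
            u = (yy - cy) * ct + (xx - cx) * st
            v = -(yy - cy) * st + (xx - cx) * ct
            inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            if not np.any(labels[inside]):
                labels[inside] = lab
                ellipses.append(EllipseSpec(lab, cy, cx, a, b, theta))
                break
        else:
            raise PlacementError(
                f"could not place nucleus {lab} of {n_nuclei} after "
                f"{max_attempts} attempts")
    return labels, ellipses


def gen_nucleus_image(d_value: float, size: int = 32, texture_sd: float = 0.08,
                      texture_ref: float = 1.8, texture_slope: float = 6.0,
                      d_ref: float = 2.55, seed: int = 0) -> np.ndarray:
    """One synthetic per-nucleus D-map crop.

    An elliptical nucleus whose pixels fluctuate around the cell's mean D
    with smoothed Gaussian texture; background is NaN sentinel.  The
    texture correlation length grows linearly with D
    (``texture_ref + texture_slope * (D - d_ref)`` pixels): higher packing
    scaling means larger, coarser packing domains, so the D level remains
    readable after the classifier's per-nucleus min-max normalization.
    """
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((size, size))
    from scipy.ndimage import gaussian_filter
    scale = max(0.5, texture_ref + texture_slope * (d_value - d_ref))
    tex = gaussian_filter(noise, scale, mode="wrap")
    tex *= texture_sd / max(tex.std(), 1e-12)
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2
    a = rng.uniform(0.65, 0.8) * size / 2
    b = rng.uniform(0.65, 0.8) * size / 2
    inside = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
    img = np.full((size, size), np.nan)
    img[inside] = d_value + tex[inside]
    return img


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class GroupSpec:
    """One diagnosis/history group of a synthetic cohort."""

    name: str
    n_patients: int
    mean_d: float
    label: str = "control"            # "control" or "case"
    sd_between: float = 0.05          # between-patient sd of true D
    sd_within: float = 0.05           # cell-to-cell sd around a patient's D
    history: str = "no_history"       # no_history / low_risk / high_risk
    current_aa: bool = False          # currently harbors an advanced adenoma
    frac_prior_cancer: float = 0.0
    assigned_risk: float | None = None
    age_mean: float = 57.0
    age_sd: float = 8.0
    frac_female: float = 0.49
    frac_smoker: float = 0.25
    frac_drinker: float = 0.5
    lesion_size_probs: dict | None = None  # e.g. {"<1 cm": .311, ...}

    def __post_init__(self):
        if not (1.0 < self.mean_d <= 3.0):
            raise ValueError("group mean D must lie in (1, 3]")
        for p in (self.frac_female, self.frac_smoker, self.frac_drinker,
                  self.frac_prior_cancer):
            if not (0.0 <= p <= 1.0):
                raise ValueError("proportions must lie in [0, 1]")


@dataclass
class CohortSpec:
    groups: list
    cells_per_patient: int = 40
    age_coeff: float = 0.0   # optional linear age effect on D (per year)
    age_ref: float = 60.0
    stratify_patients: bool = False  # quantile-stratified true-D draws
    seed: int = 0

    def __post_init__(self):
        if self.cells_per_patient <= 30:
            raise ValueError("cells_per_patient must exceed 30")
        if not self.groups:
            raise ValueError("at least one group required")


@dataclass
class PatientRecord:
    patient_id: str
    group: str
    label: str
    age: float
    sex: str
    smoking: bool
    drinking: bool
    history: str
    current_aa: bool
    prior_cancer: bool
    assigned_risk: float | None
    lesion_size: str | None
    true_d: float
    cell_d_values: np.ndarray


@dataclass
class Cohort:
    patients: list
    spec: CohortSpec | None = None

    def __post_init__(self):
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique")
        for p in self.patients:
            if len(p.cell_d_values) <= 30:
                raise ValueError(f"{p.patient_id} has <= 30 cells")
            if p.label not in ("control", "case"):
                raise ValueError("labels must be control/case")

    def to_cell_table(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            for i, d in enumerate(p.cell_d_values):
                rows.append((p.patient_id, f"{p.patient_id}_c{i:03d}", d))
        return pd.DataFrame(rows, columns=["patient_id", "cell_id", "d"])

    def to_patient_table(self) -> pd.DataFrame:
        cols = ["patient_id", "group", "label", "age", "sex", "smoking",
                "drinking", "history", "current_aa", "prior_cancer",
                "assigned_risk", "lesion_size"]
        return pd.DataFrame(
            [[getattr(p, c) for c in cols] for p in self.patients],
            columns=cols)


def gen_cohort(spec: CohortSpec) -> Cohort:
    """Sample a cohort: patient true D ~ Normal(group mean, sd_between),
    cell values ~ Normal(true D, sd_within), demographics per group."""
    rng = np.random.default_rng(spec.seed)
    patients = []
    pid = 0
    for g in spec.groups:
        if spec.stratify_patients:
            # permuted stratified normal quantiles: the realized group mean
            # and sd match the nominal ones, so nominal effect sizes are
            # reproduced without cohort-level sampling luck
            from scipy.stats import norm as _norm
            q = _norm.ppf((np.arange(g.n_patients) + 0.5) / g.n_patients)
            true_d_draws = g.mean_d + g.sd_between * rng.permutation(q)
        else:
            true_d_draws = rng.normal(g.mean_d, g.sd_between, g.n_patients)
        for j in range(g.n_patients):
            pid += 1
            age = float(rng.normal(g.age_mean, g.age_sd))
            sex = "F" if rng.random() < g.frac_female else "M"
            smoking = bool(rng.random() < g.frac_smoker)
            drinking = bool(rng.random() < g.frac_drinker)
            prior_cancer = bool(rng.random() < g.frac_prior_cancer)
            true_d = float(true_d_draws[j])
            true_d += spec.age_coeff * (age - spec.age_ref)
            cells = rng.normal(true_d, g.sd_within, size=spec.cells_per_patient)
            lesion = None
            if g.lesion_size_probs:
                cats = list(g.lesion_size_probs)
                probs = np.array([g.lesion_size_probs[c] for c in cats], float)
                lesion = str(rng.choice(cats, p=probs / probs.sum()))
            patients.append(PatientRecord(
                patient_id=f"P{pid:04d}", group=g.name, label=g.label,
                age=age, sex=sex, smoking=smoking, drinking=drinking,
                history=g.history, current_aa=g.current_aa,
                prior_cancer=prior_cancer,
                assigned_risk=g.assigned_risk, lesion_size=lesion,
                true_d=true_d, cell_d_values=cells))
    return Cohort(patients, spec)


def gen_history_table(cohort: Cohort, risk_table) -> pd.DataFrame:
    """Per-patient risk inputs: pool membership and stratum annual rates.

    Each patient resolves to a (history category, sex, age stratum) row of
    the risk table; patients with prior cancer enter the metachronous (Nc)
    pool, everyone else the advanced-adenoma (Na) pool.
    """
    rows = []
    for p in cohort.patients:
        rates = risk_table.row_for(p.history, p.sex, p.age)
        rows.append({
            "patient_id": p.patient_id, "group": p.group,
            "history": p.history, "sex": p.sex,
            "age_stratum": risk_mod.age_stratum(p.age),
            "pool": "nc" if p.prior_cancer else "na",
            "annual_aa_incidence": rates.annual_aa_incidence,
            "annual_aa_to_crc": rates.annual_aa_to_crc,
            "annual_metachronous": rates.annual_metachronous,
        })
    return pd.DataFrame(rows)


def gen_cohort_images(cohort: Cohort, size: int = 32, texture_sd: float = 0.08,
                      seed: int = 0):
    """Synthetic nucleus D-map crops for every cell of every patient.

    Returns a list of :class:`cspws.classifier.NucleusImage`.
    """
    from .classifier import NucleusImage
    ss = np.random.SeedSequence([seed, cohort.spec.seed if cohort.spec else 0])
    child = ss.generate_state(len(cohort.patients) * cohort_cells(cohort))
    images = []
    i = 0
    for p in cohort.patients:
        for ci, d in enumerate(p.cell_d_values):
            img = gen_nucleus_image(d, size=size, texture_sd=texture_sd,
                                    seed=int(child[i] % (2 ** 31)))
            images.append(NucleusImage(pixels=img, patient_id=p.patient_id,
                                       cell_id=f"{p.patient_id}_c{ci:03d}",
                                       label=p.label))
            i += 1
    return images


def cohort_cells(cohort: Cohort) -> int:
    return max(len(p.cell_d_values) for p in cohort.patients)


def two_group_spec(shift: float, n_per_group: int = 50,
                   cells_per_patient: int = 40, base_d: float = 2.55,
                   sd_between: float = 0.05, sd_within: float = 0.05,
                   seed: int = 0) -> CohortSpec:
    """Control/case spec whose patient-level standardized mean difference
    (Cohen's d on patient means) targets ``shift``.

    The sd of patient means is ``sqrt(sd_between^2 + sd_within^2 / cells)``;
    the case group mean is offset by ``shift`` times that.
    """
    sd_mean = float(np.sqrt(sd_between ** 2 + sd_within ** 2 / cells_per_patient))
    delta = shift * sd_mean
    groups = [
        GroupSpec("control", n_per_group, base_d, label="control",
                  sd_between=sd_between, sd_within=sd_within),
        GroupSpec("case", n_per_group, base_d + delta, label="case",
                  sd_between=sd_between, sd_within=sd_within,
                  age_mean=62.0),
    ]
    return CohortSpec(groups=groups, cells_per_patient=cells_per_patient,
                      stratify_patients=True, seed=seed)


def five_group_risk_spec(risk_table=None, n_per_group: int = 20,
                         base_d: float = 2.50, d_per_risk: float = 2.0,
                         d_noise_sd: float = 0.008, cells_per_patient: int = 40,
                         seed: int = 0) -> CohortSpec:
    """Five history-stratified groups with linear D-risk coupling.

    Group mean D is ``base_d + d_per_risk * (5-year group risk) + noise``,
    emulating the monotone control < high-risk-history control < advanced
    adenoma (no / low / high-risk history) ordering.  The group risks are
    evaluated on a provisional cohort drawn with the same seed so the
    construction is deterministic.
    """
    if risk_table is None:
        risk_table = risk_mod.default_risk_table()
    defs = [
        ("control_no_history", "control", "no_history", 0.0, False),
        ("control_high_risk", "control", "high_risk", 0.3, False),
        ("aa_no_history", "case", "no_history", 0.0, True),
        ("aa_low_risk", "case", "low_risk", 0.0, True),
        ("aa_high_risk", "case", "high_risk", 0.3, True),
    ]
    def mk(groups_mean):
        groups = []
        for (name, label, history, fpc, cur), mean_d in zip(defs, groups_mean):
            groups.append(GroupSpec(
                name, n_per_group, mean_d, label=label, history=history,
                frac_prior_cancer=fpc, current_aa=cur,
                age_mean=57.0 if label == "control" else 62.0))
        return CohortSpec(groups=groups, cells_per_patient=cells_per_patient,
                          seed=seed)
    provisional = gen_cohort(mk([2.5] * len(defs)))
    risks = risk_mod.cohort_group_risks(provisional, risk_table)
    risk_of = dict(zip(risks["group"], risks["five_year_risk"]))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    means, assigned = [], []
    for name, *_ in defs:
        r = risk_of[name]
        means.append(base_d + d_per_risk * r + rng.normal(0.0, d_noise_sd))
        assigned.append(r)
    spec = mk(means)
    for g, r in zip(spec.groups, assigned):
        g.assigned_risk = float(r)
    return spec
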