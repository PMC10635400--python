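"""Feature-engineering classifier for advanced-adenoma screening.

Workflow: nucleus segmentation on D maps, resize + min-max preprocessing,
deterministic convolutional feature extraction, autoencoder compression of
the feature vectors, and a grid-tuned random-forest classifier evaluated by
repeated stratified cross-validation with patient-level fold splitting.
Per-nucleus probabilities are averaged into a patient score; sensitivity
and specificity are reported at the ROC cut-point maximizing the number of
correct patient classifications within each fold.

The default feature extractor is a fixed-seed random convolution bank plus
D-map summary statistics (512 features), so the full pipeline runs with no
downloaded weights; any object with ``extractor_id``, ``n_features``,
``input_size`` and ``__call__(image) -> vector`` (e.g. a pretrained
convolutional network with global-average pooling) can be plugged in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage, stats
from skimage import filters as skfilters
from skimage import measure as skmeasure
from skimage.transform import resize as sk_resize
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import (GridSearchCV, RepeatedStratifiedKFold,
                                     StratifiedGroupKFold)

from .dmap import DMap
from .exceptions import InsufficientDataError, ModelConfigError

__all__ = [
    "NucleusImage", "FeatureMatrix", "CVResult", "Autoencoder",
    "RandomConvFeatures", "DEFAULT_RF_GRID",
    "segment_nuclei", "preprocess", "extract_features",
    "build_feature_matrix", "train_autoencoder", "fit_classifier",
    "cross_validate", "evaluate_endpoints", "optimal_cutpoint",
]

#: full hyperparameter grid of the inner 3-fold search
DEFAULT_RF_GRID = {
    "n_estimators": [100, 300],
    "max_depth": [None, 5, 10],
    "min_samples_leaf": [1, 5],
}

#: reduced grid used by default inside repeated cross-validation, where the
#: full sweep would be refit 20 times; the forest size matters little there
#: and the structural parameters are still tuned
DEFAULT_CV_GRID = {
    "n_estimators": [100],
    "max_depth": [None, 5, 10],
    "min_samples_leaf": [1, 5],
}


@dataclass
class NucleusImage:
    """One segmented nucleus: a D-map crop with NaN background sentinel."""

    pixels: np.ndarray
    patient_id: str
    cell_id: str
    label: str | None = None

    def __post_init__(self):
        if self.pixels.ndim != 2:
            raise ValueError("nucleus crop must be 2D")


@dataclass
class FeatureMatrix:
    """Per-nucleus feature vectors with patient ids and labels."""

    features: np.ndarray
    patient_ids: np.ndarray
    labels: np.ndarray
    cell_ids: np.ndarray | None = None
    extractor_id: str = ""
    encoder_id: str | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, np.float32)
        self.patient_ids = np.asarray(self.patient_ids)
        self.labels = np.asarray(self.labels)
        n = len(self.features)
        if len(self.patient_ids) != n or len(self.labels) != n:
            raise ValueError("row metadata must match feature rows")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature matrix contains non-finite values")

    def subset(self, row_mask) -> "FeatureMatrix":
        m = np.asarray(row_mask)
        return FeatureMatrix(self.features[m], self.patient_ids[m],
                             self.labels[m],
                             None if self.cell_ids is None else self.cell_ids[m],
                             self.extractor_id, self.encoder_id)

    def with_labels(self, labels) -> "FeatureMatrix":
        return FeatureMatrix(self.features, self.patient_ids,
                             np.asarray(labels), self.cell_ids,
                             self.extractor_id, self.encoder_id)


# ---------------------------------------------------------------------------
# segmentation and preprocessing

def _crop(values: np.ndarray, region_mask: np.ndarray) -> np.ndarray:
    ys, xs = np.where(region_mask)
    crop = np.full((ys.max() - ys.min() + 1, xs.max() - xs.min() + 1), np.nan)
    sel = region_mask[ys.min():ys.max() + 1, xs.min():xs.max() + 1]
    crop[sel] = values[ys.min():ys.max() + 1, xs.min():xs.max() + 1][sel]
    return crop


def segment_nuclei(dmap, mask: np.ndarray | None = None,
                   min_area: int = 100, patient_id: str = "",
                   labels_by_nucleus: dict | None = None) -> list:
    """Per-nucleus crops from a D map.

    With a label mask (given explicitly or carried by the
    :class:`~cspws.dmap.DMap`), each labeled region is cropped directly and
    background values never enter the crop.  Without one, an automated
    stand-in for manual outlining is used: Otsu threshold on finite pixels,
    hole filling, connected components and a minimum-area filter.
    """
    if isinstance(dmap, DMap):
        values = dmap.d_values
        if mask is None and dmap.mask is not None and np.any(dmap.mask > 0):
            mask = dmap.mask
    else:
        values = np.asarray(dmap, float)
    out = []
    if mask is not None:
        for lab in np.unique(mask):
            if lab == 0:
                continue
            crop = _crop(values, mask == lab)
            cid = f"{patient_id}_n{int(lab):03d}"
            out.append(NucleusImage(crop, patient_id, cid,
                                    None if labels_by_nucleus is None
                                    else labels_by_nucleus.get(int(lab))))
        return out
    finite = np.isfinite(values)
    if not np.any(finite):
        warnings.warn("blank D map: no nuclei found")
        return []
    try:
        thr = skfilters.threshold_otsu(values[finite])
    except ValueError:
        warnings.warn("degenerate D map: no nuclei found")
        return []
    fg = np.where(finite, values > thr, False)
    fg = ndimage.binary_fill_holes(fg)
    labeled = skmeasure.label(fg)
    kept = 0
    for region in skmeasure.regionprops(labeled):
        if region.area < min_area:
            continue
        kept += 1
        crop = _crop(values, labeled == region.label)
        out.append(NucleusImage(crop, patient_id,
                                f"{patient_id}_n{kept:03d}"))
    if not out:
        warnings.warn("no components above the minimum area")
    return out


def preprocess(nucleus, out_size=(224, 224)) -> np.ndarray:
    """Min-max normalize over nucleus pixels, zero-fill the background,
    bilinear-resize to ``out_size`` and rescale the result to [0, 1].

    A constant nucleus maps to all zeros (convention).  The per-nucleus
    min-max step makes the output invariant to any constant offset of the
    input D values.
    """
    img = nucleus.pixels if isinstance(nucleus, NucleusImage) else np.asarray(nucleus, float)
    if img.size < 2 or min(img.shape) < 2:
        raise ValueError("degenerate nucleus crop (needs >= 2 px per side)")
    finite = np.isfinite(img)
    if not np.any(finite):
        raise ValueError("empty nucleus crop")
    vals = img[finite]
    lo, hi = vals.min(), vals.max()
    norm = np.zeros_like(img, dtype=float)
    if hi > lo:
        norm[finite] = (vals - lo) / (hi - lo)
    resized = sk_resize(norm, out_size, order=1, mode="edge",
                        anti_aliasing=False, preserve_range=True)
    lo2, hi2 = resized.min(), resized.max()
    if hi2 > lo2:
        resized = (resized - lo2) / (hi2 - lo2)
    else:
        resized = np.zeros_like(resized)
    return resized


# ---------------------------------------------------------------------------
# feature extraction

class RandomConvFeatures:
    """Deterministic 512-feature extractor: fixed-seed random convolution
    bank plus intensity-histogram and texture statistics.

    The filter bank is drawn once from a fixed seed, each filter zero-mean
    and unit-norm, and applied at a coarse working resolution; per-filter
    response statistics (mean, sd, max, mean absolute response) are
    concatenated with a 24-bin histogram and 8 global statistics.
    """

    def __init__(self, n_filters: int = 120, filter_size: int = 5,
                 input_size: int = 32, n_hist_bins: int = 24,
                 seed: int = 2024):
        rng = np.random.default_rng(seed)
        f = rng.standard_normal((filter_size * filter_size, n_filters))
        f -= f.mean(axis=0, keepdims=True)
        f /= np.linalg.norm(f, axis=0, keepdims=True)
        self.filters = f.astype(np.float32)
        self.filter_size = filter_size
        self.input_size = input_size
        self.n_hist_bins = n_hist_bins
        self.n_features = 4 * n_filters + n_hist_bins + 8
        self.extractor_id = f"randconv{n_filters}x{filter_size}-s{seed}"

    def __call__(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, np.float32)
        if img.shape != (self.input_size, self.input_size):
            img = sk_resize(img, (self.input_size,) * 2, order=1, mode="edge",
                            anti_aliasing=False, preserve_range=True
                            ).astype(np.float32)
        k = self.filter_size
        patches = sliding_window_view(img, (k, k)).reshape(-1, k * k)
        maps = patches @ self.filters
        feats = [maps.mean(axis=0), maps.std(axis=0), maps.max(axis=0),
                 np.abs(maps).mean(axis=0)]
        hist, _ = np.histogram(img, bins=self.n_hist_bins, range=(0.0, 1.0))
        feats.append(hist / img.size)
        gy, gx = np.gradient(img)
        flat = img.ravel().astype(np.float64)
        feats.append(np.array([
            flat.mean(), flat.std(), stats.skew(flat), stats.kurtosis(flat),
            np.percentile(flat, 10), np.percentile(flat, 50),
            np.percentile(flat, 90), float(np.mean(np.hypot(gy, gx))),
        ]))
        return np.concatenate(feats).astype(np.float32)


def extract_features(image: np.ndarray, extractor) -> np.ndarray:
    """Apply a feature extractor, enforcing its declared dimensionality."""
    vec = np.asarray(extractor(image))
    if vec.shape != (extractor.n_features,):
        raise ModelConfigError(
            f"extractor {extractor.extractor_id!r} returned {vec.shape}, "
            f"declared dimension {extractor.n_features}")
    return vec


def build_feature_matrix(nuclei: list, extractor=None,
                         out_size=None) -> FeatureMatrix:
    """Preprocess and featurize a list of :class:`NucleusImage`."""
    if extractor is None:
        extractor = RandomConvFeatures()
    if out_size is None:
        out_size = (extractor.input_size, extractor.input_size)
    rows, pids, labels, cids = [], [], [], []
    for nuc in nuclei:
        rows.append(extract_features(preprocess(nuc, out_size), extractor))
        pids.append(nuc.patient_id)
        labels.append(nuc.label)
        cids.append(nuc.cell_id)
    return FeatureMatrix(np.asarray(rows, np.float32), np.asarray(pids),
                         np.asarray(labels), np.asarray(cids),
                         extractor_id=extractor.extractor_id)


# ---------------------------------------------------------------------------
# autoencoder

class Autoencoder:
    """Fully connected autoencoder ``in -> 256 -> code -> 256 -> in``.

    Tanh hidden layers, linear code and output, mean-squared reconstruction
    loss minimized by Adam on standardized inputs.  Training stops early
    when the epoch loss has not improved for ``patience`` epochs.  All
    initialization and batching derive from the seed, so encoding is
    reproducible bit for bit.
    """

    def __init__(self, input_dim: int, code_dim: int = 64, hidden: int = 256,
                 seed: int = 0):
        if code_dim >= input_dim:
            raise ModelConfigError("code_dim must be smaller than input dim")
        self.input_dim, self.code_dim, self.hidden = input_dim, code_dim, hidden
        self.seed = seed
        rng = np.random.default_rng(seed)
        def init(n_in, n_out):
            return (rng.standard_normal((n_in, n_out))
                    * np.sqrt(2.0 / (n_in + n_out))).astype(np.float32)
        self.w = [init(input_dim, hidden), init(hidden, code_dim),
                  init(code_dim, hidden), init(hidden, input_dim)]
        self.b = [np.zeros(s, np.float32) for s in
                  (hidden, code_dim, hidden, input_dim)]
        self.mu_ = np.zeros(input_dim, np.float32)
        self.scale_ = np.ones(input_dim, np.float32)
        self.loss_history_ = []
        self.encoder_id = f"ae{input_dim}-{hidden}-{code_dim}-s{seed}"

    def _forward(self, x):
        h1 = np.tanh(x @ self.w[0] + self.b[0])
        code = h1 @ self.w[1] + self.b[1]
        h2 = np.tanh(code @ self.w[2] + self.b[2])
        out = h2 @ self.w[3] + self.b[3]
        return h1, code, h2, out

    def fit(self, x: np.ndarray, epochs: int = 60, batch_size: int = 64,
            lr: float = 1e-3, patience: int = 10,
            max_train_rows: int = 1024) -> dict:
        x = np.asarray(x, np.float32)
        if len(x) < 10 * self.code_dim:
            warnings.warn(
                f"only {len(x)} rows for code_dim {self.code_dim}; "
                "10x is recommended")
        rng = np.random.default_rng(self.seed + 1)
        if len(x) > max_train_rows:
            x = x[rng.choice(len(x), max_train_rows, replace=False)]
        self.mu_ = x.mean(axis=0)
        self.scale_ = np.maximum(x.std(axis=0), 1e-6).astype(np.float32)
        xs = (x - self.mu_) / self.scale_
        params = self.w + self.b
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        best, stale = np.inf, 0
        self.loss_history_ = []
        for epoch in range(epochs):
            order = rng.permutation(len(xs))
            ep_loss = 0.0
            for start in range(0, len(xs), batch_size):
                xb = xs[order[start:start + batch_size]]
                h1, code, h2, out = self._forward(xb)
                err = out - xb
                ep_loss += float((err ** 2).sum())
                n = len(xb)
                g_out = 2.0 * err / (n * xb.shape[1])
                grads = [None] * 8
                grads[3] = h2.T @ g_out
                grads[7] = g_out.sum(axis=0)
                g_h2 = (g_out @ self.w[3].T) * (1 - h2 ** 2)
                grads[2] = code.T @ g_h2
                grads[6] = g_h2.sum(axis=0)
                g_code = g_h2 @ self.w[2].T
                grads[1] = h1.T @ g_code
                grads[5] = g_code.sum(axis=0)
                g_h1 = (g_code @ self.w[1].T) * (1 - h1 ** 2)
                grads[0] = xb.T @ g_h1
                grads[4] = g_h1.sum(axis=0)
                t += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi += (1 - beta1) * (g - mi)
                    vi += (1 - beta2) * (g * g - vi)
                    p -= lr * (mi / (1 - beta1 ** t)) / (
                        np.sqrt(vi / (1 - beta2 ** t)) + eps)
            ep_loss /= xs.size
            self.loss_history_.append(ep_loss)
            if ep_loss < best - 1e-7:
                best, stale = ep_loss, 0
            else:
                stale += 1
                if stale >= patience:
                    break
        return {"epochs_run": len(self.loss_history_),
                "initial_loss": self.loss_history_[0],
                "final_loss": self.loss_history_[-1]}

    def encode(self, x: np.ndarray) -> np.ndarray:
        xs = (np.asarray(x, np.float32) - self.mu_) / self.scale_
        return np.tanh(xs @ self.w[0] + self.b[0]) @ self.w[1] + self.b[1]

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        xs = (np.asarray(x, np.float32) - self.mu_) / self.scale_
        out = self._forward(xs)[3]
        return out * self.scale_ + self.mu_


def train_autoencoder(features, code_dim: int = 64, seed: int = 0,
                      **fit_kw):
    """Fit an :class:`Autoencoder` on a feature matrix (or raw array).

    Returns ``(encoder, training_log)``; the log records epochs run and the
    initial/final mean-squared reconstruction loss.
    """
    x = features.features if isinstance(features, FeatureMatrix) else np.asarray(features)
    ae = Autoencoder(x.shape[1], code_dim=code_dim, seed=seed)
    log = ae.fit(x, **fit_kw)
    return ae, log


# ---------------------------------------------------------------------------
# classification and cross-validation

def _binary_labels(labels) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.dtype.kind in "iub":
        return lab.astype(int)
    mapping = {"control": 0, "case": 1}
    bad = [str(x) for x in np.unique(lab) if str(x) not in mapping]
    if bad:
        raise ValueError(f"labels must be control/case or 0/1; got {bad}")
    return np.array([mapping[str(x)] for x in lab])


def fit_classifier(codes: np.ndarray, labels, grid: dict | None = None,
                   seed: int = 0, groups=None, inner_folds: int = 3,
                   search_subsample: int | None = None):
    """Grid-searched random forest on encoded features.

    The inner search is 3-fold (group-aware and label-stratified when
    patient groups are supplied) scored by ROC AUC.  With
    ``search_subsample`` the sweep is scored on a seeded group-stratified
    row subsample of that size and the winning configuration is refit on
    all rows.  Returns the refit best model and the chosen configuration.
    """
    y = _binary_labels(labels)
    if len(np.unique(y)) < 2:
        raise InsufficientDataError("both classes must be present")
    if grid is None:
        grid = DEFAULT_RF_GRID
    codes = np.asarray(codes)
    sel = np.arange(len(y))
    if search_subsample is not None and len(y) > search_subsample:
        rng = np.random.default_rng(seed)
        if groups is not None:
            keep_groups = rng.permutation(np.unique(groups))
            counts = pd.Series(groups).value_counts()
            total, kept = 0, []
            for gname in keep_groups:
                kept.append(gname)
                total += counts[gname]
                if total >= search_subsample:
                    break
            sel = np.where(np.isin(groups, kept))[0]
        else:
            sel = rng.choice(len(y), search_subsample, replace=False)
        if len(np.unique(y[sel])) < 2:
            sel = np.arange(len(y))
    x_sub = codes[sel]
    y_sub = y[sel]
    g_sub = None if groups is None else np.asarray(groups)[sel]
    rf = RandomForestClassifier(random_state=seed, n_jobs=1)
    if g_sub is not None:
        cv = StratifiedGroupKFold(n_splits=inner_folds, shuffle=True,
                                  random_state=seed)
        split = list(cv.split(x_sub, y_sub, groups=g_sub))
    else:
        split = inner_folds
    search = GridSearchCV(rf, grid, scoring="roc_auc", cv=split, n_jobs=1,
                          refit=False)
    search.fit(x_sub, y_sub)
    best = dict(search.best_params_)
    model = RandomForestClassifier(random_state=seed, n_jobs=1,
                                   **best).fit(codes, y)
    return model, best


def optimal_cutpoint(y_true: np.ndarray, scores: np.ndarray):
    """Threshold maximizing correct classifications (TP + TN).

    Candidates are the observed scores; a patient is called positive when
    its score is >= the threshold.  Ties are broken toward the lowest
    threshold (favoring sensitivity).  Returns (threshold, sensitivity,
    specificity).
    """
    y = np.asarray(y_true)
    s = np.asarray(scores, float)
    candidates = np.unique(s)
    best_t, best_correct, best_sens, best_spec = None, -1, 0.0, 0.0
    n_pos = max(int((y == 1).sum()), 1)
    n_neg = max(int((y == 0).sum()), 1)
    for t in candidates:  # ascending: first maximizer = lowest threshold
        pred = s >= t
        tp = int(np.sum(pred & (y == 1)))
        tn = int(np.sum(~pred & (y == 0)))
        if tp + tn > best_correct:
            best_correct = tp + tn
            best_t, best_sens, best_spec = t, tp / n_pos, tn / n_neg
    return float(best_t), float(best_sens), float(best_spec)


@dataclass
class CVResult:
    """Repeated stratified CV metrics with patient-level fold bookkeeping."""

    folds: pd.DataFrame
    summary: dict
    fold_assignments: pd.DataFrame
    fold_scores: list = field(default_factory=list)
    seed: int = 0


def _patient_table(fm: FeatureMatrix) -> pd.DataFrame:
    df = pd.DataFrame({"patient_id": fm.patient_ids, "label": fm.labels})
    per = df.groupby("patient_id")["label"].agg(["nunique", "first", "count"])
    missing = per.index[per["first"].isna() |
                        (per["first"].astype(str) == "None")].tolist()
    if missing:
        raise ValueError(f"patients with nuclei but no label: {missing}")
    if (per["nunique"] > 1).any():
        bad = per.index[per["nunique"] > 1].tolist()
        raise ValueError(f"inconsistent labels within patients: {bad}")
    out = per.reset_index()[["patient_id", "first"]]
    out.columns = ["patient_id", "label"]
    return out


def cross_validate(features: FeatureMatrix, n_folds: int = 4,
                   n_repeats: int = 5, seed: int = 0, code_dim: int = 64,
                   grid: dict | None = None, ae_kwargs: dict | None = None,
                   search_subsample: int | None = 1200) -> CVResult:
    """Repeated stratified k-fold evaluation, split at the patient level.

    All nuclei of a patient share a fold.  Within each training fold the
    autoencoder and the grid-searched random forest are fit from scratch;
    test nuclei are encoded and scored, nucleus probabilities are averaged
    per patient, and AUC / sensitivity / specificity at the optimal
    cut-point are computed on patient scores.  The summary reports mean and
    sd over all ``n_folds * n_repeats`` fold results.
    """
    patients = _patient_table(features)
    y_pat = _binary_labels(patients["label"].to_numpy())
    if min(np.bincount(y_pat)) < n_folds:
        raise InsufficientDataError(
            f"need >= {n_folds} patients per class for {n_folds}-fold CV")
    ae_kwargs = dict(ae_kwargs or {})
    pid_arr = patients["patient_id"].to_numpy()
    splitter = RepeatedStratifiedKFold(n_splits=n_folds, n_repeats=n_repeats,
                                       random_state=seed)
    rows, assignments, fold_scores = [], [], []
    for split_idx, (train_p, test_p) in enumerate(
            splitter.split(pid_arr.reshape(-1, 1), y_pat)):
        repeat, fold = divmod(split_idx, n_folds)
        fold_seed = int(np.random.SeedSequence(
            [seed, repeat, fold]).generate_state(1)[0] % (2 ** 31))
        train_ids = set(pid_arr[train_p])
        in_train = np.array([p in train_ids for p in features.patient_ids])
        fm_tr, fm_te = features.subset(in_train), features.subset(~in_train)
        ae, _ = train_autoencoder(fm_tr, code_dim=code_dim, seed=fold_seed,
                                  **ae_kwargs)
        model, _cfg = fit_classifier(ae.encode(fm_tr.features),
                                     fm_tr.labels,
                                     grid=DEFAULT_CV_GRID if grid is None else grid,
                                     seed=fold_seed,
                                     groups=fm_tr.patient_ids,
                                     search_subsample=search_subsample)
        prob = model.predict_proba(ae.encode(fm_te.features))[:, 1]
        te = pd.DataFrame({"patient_id": fm_te.patient_ids, "prob": prob})
        scores = te.groupby("patient_id")["prob"].mean()
        lab = patients.set_index("patient_id").loc[scores.index, "label"]
        y_te = _binary_labels(lab.to_numpy())
        auc = roc_auc_score(y_te, scores.to_numpy())
        cut, sens, spec = optimal_cutpoint(y_te, scores.to_numpy())
        rows.append({"repeat": repeat, "fold": fold, "auc": auc,
                     "sensitivity": sens, "specificity": spec,
                     "cutpoint": cut, "n_test_patients": len(y_te)})
        for p in pid_arr[test_p]:
            assignments.append({"patient_id": p, "repeat": repeat,
                                "fold": fold})
        fold_scores.append({"repeat": repeat, "fold": fold,
                            "patient_ids": scores.index.to_numpy(),
                            "y": y_te, "scores": scores.to_numpy()})
    folds = pd.DataFrame(rows)
    summary = {m: (float(folds[m].mean()), float(folds[m].std(ddof=1)))
               for m in ("auc", "sensitivity", "specificity")}
    return CVResult(folds=folds, summary=summary,
                    fold_assignments=pd.DataFrame(assignments),
                    fold_scores=fold_scores, seed=seed)


def sensitivity_at_specificity(fold_scores: list, min_specificity: float):
    """Mean fold sensitivity at the lowest threshold whose specificity
    reaches ``min_specificity``."""
    sens = []
    for fs in fold_scores:
        y, s = fs["y"], fs["scores"]
        n_neg = max(int((y == 0).sum()), 1)
        n_pos = max(int((y == 1).sum()), 1)
        best = 0.0
        for t in np.unique(s):
            spec = np.sum((s < t) & (y == 0)) / n_neg
            if spec >= min_specificity:
                best = np.sum((s >= t) & (y == 1)) / n_pos
                break  # lowest such threshold maximizes sensitivity
        sens.append(best)
    return float(np.mean(sens))


def evaluate_endpoints(features: FeatureMatrix, patient_meta: pd.DataFrame,
                       endpoints: dict, size_within: str | None = None,
                       size_col: str = "lesion_size",
                       fixed_specificity: float = 0.88,
                       **cv_kwargs) -> pd.DataFrame:
    """Cross-validate each diagnostic endpoint and lesion-size subgroup.

    ``endpoints`` maps an endpoint name to ``{"control": [...groups],
    "case": [...groups]}``.  For ``size_within`` (an endpoint name), the
    case patients are additionally partitioned by ``size_col`` and each
    subgroup is evaluated against all endpoint controls, reporting
    sensitivity at the configured fixed specificity.
    """
    meta = patient_meta.set_index("patient_id")
    group_of = meta["group"]
    rows = []

    def run(name, control_groups, case_groups, subgroup=None):
        roles = {}
        for g in control_groups:
            roles[g] = "control"
        for g in case_groups:
            roles[g] = "case"
        pid_role = group_of.map(roles)
        keep_pids = pid_role.dropna()
        if subgroup is not None:
            case_pids = keep_pids[keep_pids == "case"].index
            in_sub = meta.loc[case_pids, size_col] == subgroup
            drop = set(case_pids[~in_sub])
            keep_pids = keep_pids[~keep_pids.index.isin(drop)]
        n_ctrl = int((keep_pids == "control").sum())
        n_case = int((keep_pids == "case").sum())
        if n_ctrl == 0 or n_case == 0:
            raise ValueError(
                f"endpoint {name!r}: empty class "
                f"(controls={n_ctrl}, cases={n_case})")
        keep = np.isin(features.patient_ids, keep_pids.index.to_numpy())
        fm = features.subset(keep)
        fm = fm.with_labels(keep_pids.loc[fm.patient_ids].to_numpy())
        cv = cross_validate(fm, **cv_kwargs)
        row = {"endpoint": name, "subgroup": subgroup,
               "n_control": n_ctrl, "n_case": n_case,
               "auc_mean": cv.summary["auc"][0],
               "auc_sd": cv.summary["auc"][1],
               "sensitivity_mean": cv.summary["sensitivity"][0],
               "specificity_mean": cv.summary["specificity"][0]}
        if subgroup is not None:
            row["sens_at_fixed_spec"] = sensitivity_at_specificity(
                cv.fold_scores, fixed_specificity)
        rows.append(row)

    for name, spec_ in endpoints.items():
        run(name, spec_["control"], spec_["case"])
    if size_within is not None:
        spec_ = endpoints[size_within]
        case_groups = spec_["case"]
        case_pids = group_of[group_of.isin(case_groups)].index
        cats = (meta.loc[case_pids, size_col].dropna().unique().tolist())
        for cat in sorted(cats):
            run(size_within, spec_["control"], case_groups, subgroup=cat)
    return pd.DataFrame(rows)
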