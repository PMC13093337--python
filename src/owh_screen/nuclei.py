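"""Pyknotic-nucleus quantification: preprocessing, LoG detection with watershed
splitting, per-nucleus features, and random-forest pyknosis classification."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import feature as skfeature
from skimage import measure as skmeasure
from skimage import segmentation as skseg
from skimage.filters import gaussian
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

FEATURE_NAMES = ("A", "P", "r_I", "eps", "I_M", "I_T", "I_W", "sigma")

DEFAULT_PIXEL_SIZE = 0.863
#: LoG scale bounds, printed in pixel units; divide by pixel_size for the
#: micrometre reading of the same numbers (config option `sigma_units`).
LOG_MIN_SIGMA = 0.863
LOG_MAX_SIGMA = 5.179
LOG_NUM_SIGMA = 25
LOG_OVERLAP = 0.7
LOG_THRESHOLD_FRACTION = 0.005
MASK_RELATIVE_INTENSITY = 0.10
HIGHPASS_SIGMA = 1.0


@dataclass(frozen=True)
class HistologyImage:
    """2-D intensity grid with physical pixel size and acquisition metadata."""

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "pixels", px)


@dataclass
class NucleusRecord:
    """One detected nucleus with its 8-feature vector and pyknosis label."""

    center: tuple[float, float]
    member_pixels: np.ndarray  # (n, 2) row/col indices
    A: float
    P: float
    r_I: float
    eps: float
    I_M: float
    I_T: float
    I_W: float
    sigma: float
    label: str = "unlabeled"

    @property
    def n(self) -> int:
        return len(self.member_pixels)

    def feature_vector(self) -> np.ndarray:
        return np.array([self.A, self.P, self.r_I, self.eps, self.I_M,
                         self.I_T, self.I_W, self.sigma])


def preprocess(img: HistologyImage) -> HistologyImage:
    """Normalize intensities to [0, 1], remove low-frequency background with a
    high-pass Gaussian filter (sigma = 1 px) and mask pixels below 10% relative
    intensity.

    The output is invariant to positive affine rescaling of the raw input.
    """
    px = img.pixels
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        raise ValueError("degenerate image: constant intensity")
    norm = (px - lo) / (hi - lo)
    hp = norm - gaussian(norm, sigma=HIGHPASS_SIGMA, preserve_range=True)
    hp = np.clip(hp, 0.0, None)
    m = hp.max()
    if m > 0:
        hp = hp / m
    hp[hp < MASK_RELATIVE_INTENSITY] = 0.0
    return HistologyImage(hp, img.pixel_size, dict(img.metadata))


def detect_nuclei(img: HistologyImage, min_sigma: float = LOG_MIN_SIGMA,
                  max_sigma: float = LOG_MAX_SIGMA,
                  num_sigma: int = LOG_NUM_SIGMA,
                  overlap: float = LOG_OVERLAP):
    """Laplacian-of-Gaussian blob detection followed by seeded watershed.

    Returns a list of ``(center, sigma, member_pixels)`` tuples.  The watershed
    runs on the above-mask foreground with the blob centers as markers, so
    member-pixel sets are pairwise disjoint; each detection is additionally
    capped at radius ``2*sigma*sqrt(2)`` around its center.
    """
    px = img.pixels
    if px.max() <= 0:
        return []
    threshold = LOG_THRESHOLD_FRACTION * float(px.max())
    blobs = skfeature.blob_log(px, min_sigma=min_sigma, max_sigma=max_sigma,
                               num_sigma=num_sigma, overlap=overlap,
                               threshold=threshold, threshold_rel=0.0)
    if len(blobs) == 0:
        return []
    foreground = px > 0
    markers = np.zeros(px.shape, dtype=int)
    centers = []
    for i, (r, c, s) in enumerate(blobs, start=1):
        ri, ci = int(round(r)), int(round(c))
        ri = min(max(ri, 0), px.shape[0] - 1)
        ci = min(max(ci, 0), px.shape[1] - 1)
        markers[ri, ci] = i
        centers.append((float(r), float(c), float(s)))
    labels = skseg.watershed(-px, markers=markers, mask=foreground)
    yy, xx = np.mgrid[0 : px.shape[0], 0 : px.shape[1]]
    out = []
    for i, (r, c, s) in enumerate(centers, start=1):
        radius = 2.0 * s * math.sqrt(2.0)
        within = (yy - r) ** 2 + (xx - c) ** 2 <= radius**2
        member = np.argwhere((labels == i) & within)
        if len(member) == 0:
            member = np.array([[int(round(r)), int(round(c))]])
        out.append(((r, c), s, member))
    return out


def crofton_perimeter(member_pixels, pixel_size: float = DEFAULT_PIXEL_SIZE) -> float:
    """Perimeter from the Crofton four-direction approximation, in um."""
    member_pixels = np.asarray(member_pixels)
    if member_pixels.size == 0:
        raise ValueError("empty pixel set")
    rmin, cmin = member_pixels.min(axis=0)
    rmax, cmax = member_pixels.max(axis=0)
    mask = np.zeros((rmax - rmin + 3, cmax - cmin + 3), dtype=bool)
    mask[member_pixels[:, 0] - rmin + 1, member_pixels[:, 1] - cmin + 1] = True
    return float(skmeasure.perimeter_crofton(mask, directions=4)) * pixel_size


def nucleus_features(img: HistologyImage, member_pixels, center,
                     sigma: float) -> NucleusRecord:
    """Compute the eight per-nucleus features from normalized intensities.

    A = n*a, r_I = sqrt(A/pi), eps = P/(2*pi*r_I);
    I_M = (1/n) * sum(I_i * d_i), I_T = A * I_M,
    I_W = sum(I_i * d_i) / sum(d_i),
    with d_i the pixel distance from the detection center.  A single-pixel
    nucleus (sum d_i = 0) falls back to I_W = I of that pixel.
    """
    member_pixels = np.asarray(member_pixels)
    if member_pixels.size == 0:
        raise ValueError("empty pixel set")
    a = img.pixel_size**2
    n = len(member_pixels)
    A = n * a
    P = crofton_perimeter(member_pixels, img.pixel_size)
    r_I = math.sqrt(A / math.pi)
    eps = P / (2.0 * math.pi * r_I)
    intensities = img.pixels[member_pixels[:, 0], member_pixels[:, 1]]
    d = np.hypot(member_pixels[:, 0] - center[0], member_pixels[:, 1] - center[1])
    weighted = intensities * d
    I_M = float(weighted.sum() / n)
    I_T = A * I_M
    dsum = float(d.sum())
    I_W = float(weighted.sum() / dsum) if dsum > 0 else float(intensities[0])
    return NucleusRecord(center=tuple(center), member_pixels=member_pixels,
                         A=A, P=P, r_I=r_I, eps=eps, I_M=I_M, I_T=I_T, I_W=I_W,
                         sigma=float(sigma))


def extract_records(img: HistologyImage) -> list[NucleusRecord]:
    """Preprocess, detect, and featurize every nucleus in a raw image."""
    pre = preprocess(img)
    return [nucleus_features(pre, member, center, sigma)
            for center, sigma, member in detect_nuclei(pre)]


@dataclass
class PyknosisModel:
    """Fitted random-forest pyknosis classifier with its training manifest."""

    classifier: RandomForestClassifier
    manifest: dict
    cv_metrics: pd.DataFrame
    holdout_metrics: dict

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.classifier.predict(np.asarray(features, dtype=float))


def _features_and_labels(records):
    if isinstance(records, pd.DataFrame):
        X = records[list(FEATURE_NAMES)].to_numpy(dtype=float)
        y = records["pyknotic"].to_numpy(dtype=bool)
    else:
        X = np.array([r.feature_vector() for r in records])
        y = np.array([r.label == "pyknotic" for r in records])
    return X, y


def train_pyknosis_model(labeled, seed: int = 0,
                         n_estimators: int = 500) -> PyknosisModel:
    """Train the pyknosis classifier with 1:3 class-imbalance subsampling.

    Keeps every pyknotic record and three times as many randomly chosen
    non-pyknotic records (all of them if fewer are available), then fits a
    random forest on an 80:20 split with 5-fold cross-validation inside the
    80% partition.
    """
    X, y = _features_and_labels(labeled)
    n_pyk = int(y.sum())
    n_non = int((~y).sum())
    if n_pyk == 0 or n_non == 0:
        raise ValueError("both classes must be present to train")
    rng = np.random.default_rng(seed)
    non_idx = np.flatnonzero(~y)
    n_keep = min(3 * n_pyk, n_non)
    keep_non = rng.choice(non_idx, size=n_keep, replace=False)
    pool = np.concatenate([np.flatnonzero(y), keep_non])
    Xp, yp = X[pool], y[pool]

    X_tr, X_te, y_tr, y_te = train_test_split(
        Xp, yp, test_size=0.2, random_state=seed, stratify=yp)
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)

    folds = []
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    for k, (tr, va) in enumerate(skf.split(X_tr, y_tr)):
        fold_clf = RandomForestClassifier(n_estimators=n_estimators,
                                          random_state=seed)
        fold_clf.fit(X_tr[tr], y_tr[tr])
        proba = fold_clf.predict_proba(X_tr[va])[:, 1]
        folds.append({"fold": k,
                      "accuracy": accuracy_score(y_tr[va], proba > 0.5),
                      "auroc": roc_auc_score(y_tr[va], proba)})
    clf.fit(X_tr, y_tr)
    proba_te = clf.predict_proba(X_te)[:, 1]
    holdout = {"accuracy": float(accuracy_score(y_te, proba_te > 0.5)),
               "auroc": float(roc_auc_score(y_te, proba_te))}
    manifest = {"n_pyknotic": n_pyk, "n_nonpyknotic_subsampled": n_keep,
                "split_ratio": "80:20", "cv_folds": 5, "seed": seed,
                "n_estimators": n_estimators}
    return PyknosisModel(clf, manifest, pd.DataFrame(folds), holdout)


def classify_and_count(model: PyknosisModel, images,
                       records_per_image=None) -> pd.DataFrame:
    """Per-image nucleus totals, pyknotic fractions and log fractions.

    ``records_per_image`` lets callers pass pre-extracted records; otherwise
    each image is run through preprocess/detect/featurize.  The log transform
    uses a half-count pseudo-fraction offset ``c = 0.5/total`` for zeros.
    """
    rows = []
    for i, img in enumerate(images):
        records = (records_per_image[i] if records_per_image is not None
                   else extract_records(img))
        total = len(records)
        meta = img.metadata if isinstance(img, HistologyImage) else {}
        if total == 0:
            rows.append({"image": i, "total": 0, "pyknotic": 0,
                         "fraction": np.nan, "log_fraction": np.nan,
                         "flagged_empty": True, **meta})
            continue
        X = np.array([r.feature_vector() for r in records])
        pred = model.predict(X)
        n_pyk = int(pred.sum())
        frac = n_pyk / total
        c = 0.5 / total
        rows.append({"image": i, "total": total, "pyknotic": n_pyk,
                     "fraction": frac, "log_fraction": math.log(frac + c),
                     "flagged_empty": False, **meta})
    return pd.DataFrame(rows)
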