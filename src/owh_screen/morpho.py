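"""Cell-shape morphometrics: Otsu segmentation with size/border filters,
nine per-cell morphology parameters, stratified splitting, and the
contour-registration + PCA + k-means shape-mode model (5 modes, 50 boundary
points)."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure as skmeasure
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

MIN_OBJECT_PIXELS = 25
N_MODES = 5
N_REGISTRATION_POINTS = 50


@dataclass
class CellMask:
    """Binary pixel mask of one segmented cell, with provenance metadata."""

    mask: np.ndarray
    source_image: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def segment_cells(img: np.ndarray, source_image: str = "",
                  metadata: dict | None = None) -> list[CellMask]:
    """Otsu-threshold segmentation with the stated post-filters.

    Holes are filled; objects smaller than 25 pixels and objects touching the
    image border are removed.  Returns one full-frame boolean mask per cell.
    """
    img = np.asarray(img, dtype=float)
    if img.max() == img.min():
        return []
    binary = img > threshold_otsu(img)
    binary = ndi.binary_fill_holes(binary)
    labels, n = ndi.label(binary)
    out = []
    for lab in range(1, n + 1):
        mask = labels == lab
        if mask.sum() < MIN_OBJECT_PIXELS:
            continue
        rows, cols = np.nonzero(mask)
        if (rows.min() == 0 or cols.min() == 0
                or rows.max() == img.shape[0] - 1
                or cols.max() == img.shape[1] - 1):
            continue
        out.append(CellMask(mask, source_image, dict(metadata or {})))
    return out


def split_quadrants(img: np.ndarray):
    """Split an image into four equal quadrants, edge-padding odd dimensions.

    Returns ``(quadrants, padded)`` where quadrants are ordered top-left,
    top-right, bottom-left, bottom-right and tile the (padded) original.
    """
    img = np.asarray(img)
    pr = img.shape[0] % 2
    pc = img.shape[1] % 2
    padded = np.pad(img, ((0, pr), (0, pc)), mode="edge") if (pr or pc) else img
    h, w = padded.shape[0] // 2, padded.shape[1] // 2
    quads = [padded[:h, :w], padded[:h, w:], padded[h:, :w], padded[h:, w:]]
    return quads, padded


def stratified_split(meta: pd.DataFrame, ratio: float = 0.2, seed: int = 0,
                     strata=("sex", "region", "group"),
                     min_per_stratum: int = 2) -> pd.Series:
    """80:20 train/test assignment keeping >= 2 images per stratum in train.

    ``meta`` has one row per image with the stratum columns.  Test counts per
    stratum are apportioned by the largest-remainder method so the global
    split lands within one image of the requested ratio.  Returns a Series of
    "train"/"test" aligned with ``meta``'s index.
    """
    key = meta[list(strata)].astype(str).agg("|".join, axis=1)
    groups = {k: idx.to_numpy() for k, idx in meta.groupby(key).groups.items()}
    for k, idx in groups.items():
        if len(idx) < min_per_stratum + 1:
            raise ValueError(f"stratum {k!r} has only {len(idx)} images; "
                             f"needs >= {min_per_stratum + 1}")
    n_total = len(meta)
    target_test = int(round(ratio * n_total))
    quotas = {k: ratio * len(idx) for k, idx in groups.items()}
    base = {k: max(1, math.floor(q)) for k, q in quotas.items()}
    # cap so train keeps min_per_stratum
    for k in base:
        base[k] = min(base[k], len(groups[k]) - min_per_stratum)
    assigned = sum(base.values())
    remainders = sorted(groups, key=lambda k: (quotas[k] - base[k], k),
                        reverse=True)
    i = 0
    while assigned < target_test and i < len(remainders):
        k = remainders[i]
        if base[k] < len(groups[k]) - min_per_stratum:
            base[k] += 1
            assigned += 1
        i += 1
    rng = np.random.default_rng(seed)
    assignment = pd.Series("train", index=meta.index)
    for k, idx in sorted(groups.items()):
        chosen = rng.choice(idx, size=base[k], replace=False)
        assignment.loc[chosen] = "test"
    return assignment


def morphology_params(cell: CellMask) -> dict:
    """Nine standard morphology parameters of a cell mask.

    circularity = 4*pi*A/P^2; solidity = A / convex-hull area; extent =
    A / bounding-box area; aspect_ratio = major/minor axis length;
    orientation = major-axis angle (radians).
    """
    props = skmeasure.regionprops(cell.mask.astype(int))[0]
    area = float(props.area)
    perimeter = float(props.perimeter)
    minor = max(float(props.axis_minor_length), 1e-9)
    return {
        "area": area,
        "perimeter": perimeter,
        "circularity": 4.0 * math.pi * area / max(perimeter, 1e-9) ** 2,
        "eccentricity": float(props.eccentricity),
        "solidity": float(props.solidity),
        "extent": float(props.extent),
        "major_axis_length": float(props.axis_major_length),
        "aspect_ratio": float(props.axis_major_length) / minor,
        "orientation": float(props.orientation),
    }


# ---------------------------------------------------------------------------
# contour registration
# ---------------------------------------------------------------------------

def _outer_contour(mask: np.ndarray) -> np.ndarray:
    contours = skmeasure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no contour")
    return max(contours, key=len)


def _resample_closed(contour: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed contour to n equally spaced arc-length points."""
    if not np.allclose(contour[0], contour[-1]):
        contour = np.vstack([contour, contour[0]])
    seg = np.linalg.norm(np.diff(contour, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate contour")
    t = np.linspace(0.0, total, n_points, endpoint=False)
    rows = np.interp(t, s, contour[:, 0])
    cols = np.interp(t, s, contour[:, 1])
    return np.column_stack([rows, cols])


def register_contour(mask: np.ndarray,
                     n_points: int = N_REGISTRATION_POINTS) -> np.ndarray:
    """Extract, resample and register a cell outline.

    Registration: translate to centroid, normalize RMS radius to 1, rotate the
    principal axis onto x, resolve the 180-degree and reflection ambiguities by
    making the x third moment and y skew non-negative, start at the boundary
    point farthest from the centroid (ties by angle) and traverse
    counterclockwise.  Returns a (n_points, 2) array of (x, y) coordinates.
    """
    contour = _outer_contour(mask)
    pts = _resample_closed(contour, n_points)
    xy = np.column_stack([pts[:, 1], -pts[:, 0]])  # image rows grow downward
    xy = xy - xy.mean(axis=0)
    scale = math.sqrt((xy**2).sum(axis=1).mean())
    if scale <= 0:
        raise ValueError("degenerate contour: zero spread")
    xy /= scale
    cov = xy.T @ xy / len(xy)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, int(np.argmax(evals))]
    theta = math.atan2(major[1], major[0])
    rot = np.array([[math.cos(-theta), -math.sin(-theta)],
                    [math.sin(-theta), math.cos(-theta)]])
    xy = xy @ rot.T
    if np.sum(xy[:, 0] ** 3) < 0:
        xy[:, 0] = -xy[:, 0]
    if np.sum(xy[:, 1] ** 3) < 0:
        xy[:, 1] = -xy[:, 1]
    # counterclockwise traversal (positive signed area)
    x, y = xy[:, 0], xy[:, 1]
    signed_area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if signed_area < 0:
        xy = xy[::-1]
    radii = np.hypot(xy[:, 0], xy[:, 1])
    best = np.max(radii)
    candidates = np.flatnonzero(np.isclose(radii, best))
    angles = np.arctan2(xy[candidates, 1], xy[candidates, 0])
    start = candidates[int(np.argmin(angles))]
    return np.roll(xy, -start, axis=0)


def _to_complex(xy: np.ndarray) -> np.ndarray:
    return xy[:, 0] + 1j * xy[:, 1]


def _from_complex(z: np.ndarray) -> np.ndarray:
    return np.column_stack([z.real, z.imag])


def _align_to_reference(z: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Best match of a complex contour to a reference over cyclic shift,
    rotation (unit phase) and reflection; the initial deterministic
    registration alone is unstable for near-symmetric shapes."""
    n = len(z)
    idx = (np.arange(n)[None, :] + np.arange(n)[:, None]) % n
    best_val, best = -1.0, z
    for cand in (z, np.conj(z[::-1])):
        rolls = cand[idx]                      # (n shifts, n points)
        corr = rolls @ np.conj(ref)
        s = int(np.argmax(np.abs(corr)))
        val = float(np.abs(corr[s]))
        if val > best_val:
            best_val = val
            best = rolls[s] * np.exp(-1j * np.angle(corr[s]))
    return best


@dataclass
class ShapeModeModel:
    """Contour-registration + PCA + k-means model mapping outlines to 5 modes."""

    pca: PCA
    kmeans: KMeans
    n_modes: int
    n_points: int
    reference: np.ndarray  # complex aligned mean contour
    mean_contour: np.ndarray
    manifest: dict

    def _registered_vectors(self, masks) -> np.ndarray:
        vecs = []
        for m in masks:
            arr = m.mask if isinstance(m, CellMask) else m
            z = _to_complex(register_contour(arr, self.n_points))
            vecs.append(_from_complex(_align_to_reference(z, self.reference)))
        return np.array(vecs).reshape(len(vecs), -1)

    def transform(self, masks) -> np.ndarray:
        """Assign each mask a shape mode in 1..n_modes."""
        vecs = self._registered_vectors(masks)
        return self.kmeans.predict(self.pca.transform(vecs)) + 1


def fit_shape_modes(masks, n_modes: int = N_MODES,
                    n_points: int = N_REGISTRATION_POINTS,
                    seed: int = 0, n_pcs: int = 10,
                    align_iterations: int = 3) -> ShapeModeModel:
    """Fit the shape-mode model on training cell masks.

    Pipeline: registered 50-point contours -> iterative alignment of every
    contour to the running mean shape (cyclic shift + rotation + reflection)
    -> PCA on flattened aligned coordinates -> seeded k-means (k = n_modes,
    20 restarts) on the leading PCs.  Degenerate contours are skipped with a
    warning.
    """
    import warnings

    zs = []
    for m in masks:
        arr = m.mask if isinstance(m, CellMask) else m
        try:
            zs.append(_to_complex(register_contour(arr, n_points)))
        except ValueError as exc:
            warnings.warn(f"skipping degenerate cell contour: {exc}")
    if len(zs) < n_modes * 5:
        raise ValueError(f"need >= {n_modes * 5} training cells, got {len(zs)}")
    ref = zs[0]
    aligned = zs
    for _ in range(align_iterations):
        aligned = [_align_to_reference(z, ref) for z in zs]
        ref = np.mean(aligned, axis=0)
        ref = ref - ref.mean()
        ref = ref / np.sqrt(np.mean(np.abs(ref) ** 2))
    vecs = np.array([_from_complex(z) for z in aligned]).reshape(len(aligned), -1)
    pca = PCA(n_components=min(n_pcs, vecs.shape[1], len(vecs)),
              random_state=seed)
    scores = pca.fit_transform(vecs)
    km = KMeans(n_clusters=n_modes, n_init=20, random_state=seed)
    km.fit(scores)
    manifest = {"n_train": int(len(vecs)), "n_modes": n_modes,
                "n_points": n_points, "seed": seed,
                "n_pcs": int(pca.n_components_),
                "align_iterations": align_iterations}
    return ShapeModeModel(pca=pca, kmeans=km, n_modes=n_modes,
                          n_points=n_points, reference=ref,
                          mean_contour=vecs.mean(axis=0).reshape(-1, 2),
                          manifest=manifest)


COUNT_SCALE_FACTOR = 5  # test images are the 20% partition


def assign_shape_modes(model: ShapeModeModel, masks,
                       meta: pd.DataFrame | None = None,
                       strata=("group", "region")) -> pd.DataFrame:
    """Assign shape modes and tabulate per-stratum distributions.

    Returns one row per stratum with SM1..SM5 proportions, the raw test-image
    cell count, and the x5-scaled estimated total.
    """
    labels = model.transform(masks)
    if meta is None:
        meta = pd.DataFrame({"group": ["all"] * len(labels),
                             "region": ["all"] * len(labels)})
    df = meta.copy().reset_index(drop=True)
    df["shape_mode"] = labels
    rows = []
    for key, sub in df.groupby(list(strata)):
        key = key if isinstance(key, tuple) else (key,)
        counts = sub["shape_mode"].value_counts()
        n = len(sub)
        row = dict(zip(strata, key))
        for sm in range(1, model.n_modes + 1):
            row[f"SM{sm}"] = counts.get(sm, 0) / n
        row["n_cells"] = n
        row["estimated_total"] = n * COUNT_SCALE_FACTOR
        rows.append(row)
    return pd.DataFrame(rows)


def shape_mode_labels(model: ShapeModeModel, masks) -> np.ndarray:
    """Per-cell shape-mode labels in 1..n_modes."""
    return model.transform(masks)
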