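"""Seeded generators for every input the screening pipeline consumes.

Each generator returns both the synthetic data and a ground-truth table so
downstream modules (detection, classification, shape modes, synergy, networks,
emergence) can be benchmarked without any external downloads.  Identical
:class:`SimulationConfig` objects yield bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi
from skimage import draw as skdraw

GROUPS = ("control", "OGD", "Az", "Epo", "AzEpo")
REGIONS = ("cortex", "white matter", "deep gray")
SEXES = ("F", "M")

#: default parametric shape families (name -> geometry parameters)
DEFAULT_SHAPE_FAMILIES = [
    {"name": "rod", "kind": "ellipse", "axes": (30.0, 3.0)},
    {"name": "ramified", "kind": "branched", "radius": 6.0, "n_branches": 5,
     "branch_len": 18.0},
    {"name": "ameboid", "kind": "ellipse", "axes": (8.0, 8.0)},
    {"name": "intermediate_elongated", "kind": "ellipse", "axes": (16.0, 6.0)},
    {"name": "intermediate_branched", "kind": "branched", "radius": 7.0,
     "n_branches": 2, "branch_len": 10.0},
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for all synthetic generators.

    Scales default to the study design this pipeline targets: 512x512 images
    at 0.863 um/px, a 255-transcript panel, 6 samples per group x region and
    12 slices per group for scalar outcomes.
    """

    seed: int = 0
    image_size: tuple[int, int] = (512, 512)
    pixel_size: float = 0.863
    n_nuclei: int = 50
    pyknotic_fraction: float = 0.2
    min_separation: float = 10.0
    shape_family_spec: list = field(
        default_factory=lambda: [dict(f, count=200) for f in DEFAULT_SHAPE_FAMILIES]
    )
    group_effects: dict = field(
        default_factory=lambda: {
            "control": {"fractional_effect": 1.0},
            "OGD": {"fractional_effect": 0.0},
            "Az": {"fractional_effect": 0.0},
            "Epo": {"fractional_effect": 0.0},
            "AzEpo": {"fractional_effect": 0.6},
        }
    )
    panel_size: int = 255
    n_samples_per_cell: int = 6
    n_deg: int = 20
    n_emergent: int = 14
    n_restored_combo: int = 0
    n_restored_az: int = 0
    n_restored_epo: int = 0
    deg_log2_shift: float = 1.0
    emergent_offset_sd: float = 6.0
    noise_sd: float = 0.25
    n_slices_per_group: int = 12
    outcome_control_mean: float = 0.2
    outcome_ogd_mean: float = 1.0
    outcome_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for name in ("n_nuclei", "panel_size", "n_samples_per_cell", "n_deg",
                     "n_emergent", "n_slices_per_group"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.pyknotic_fraction <= 1.0:
            raise ValueError("pyknotic_fraction must be in [0, 1]")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "image_size" in raw:
            raw["image_size"] = tuple(raw["image_size"])
        cfg = cls(**raw)
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        return cfg


class PackingError(ValueError):
    """Requested nucleus count cannot be placed at the minimum separation."""


# ---------------------------------------------------------------------------
# nucleus fields
# ---------------------------------------------------------------------------

def _place_centers(rng, shape, n, min_sep, margin, max_attempts=20_000):
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n:
        if attempts >= max_attempts:
            raise PackingError(
                f"could not place {n} centers with separation {min_sep} "
                f"in a {shape[0]}x{shape[1]} image"
            )
        attempts += 1
        r = rng.uniform(margin, shape[0] - margin)
        c = rng.uniform(margin, shape[1] - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep**2 for r0, c0 in centers):
            centers.append((r, c))
    return centers


def gen_nuclei_image(config: SimulationConfig):
    """Render a DAPI-like nucleus field with a pyknotic subpopulation.

    Pyknotic nuclei are small (sigma 1-2 px), compact and bright (peak
    1.5-2x non-pyknotic); non-pyknotic nuclei are larger (sigma 2-3 px) and
    dimmer Gaussian spots.

    Returns ``(image, truth)`` where ``image`` is a float array in [0, 1] and
    ``truth`` is a DataFrame with columns row, col, sigma, peak, pyknotic.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.image_size)
    img = np.zeros(shape, dtype=float)
    n = config.n_nuclei
    n_pyk = int(round(config.pyknotic_fraction * n))
    rows = []
    if n > 0:
        margin = max(8.0, config.min_separation / 2.0)
        centers = _place_centers(rng, shape, n, config.min_separation, margin)
        flags = np.zeros(n, dtype=bool)
        flags[rng.permutation(n)[:n_pyk]] = True
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        base_peak = 0.45
        for (r, c), pyk in zip(centers, flags):
            if pyk:
                sigma = rng.uniform(1.0, 2.0)
                peak = base_peak * rng.uniform(1.5, 2.0)
            else:
                # kept narrow enough to survive the sigma=1 high-pass filter
                sigma = rng.uniform(2.0, 3.0)
                peak = base_peak * rng.uniform(0.9, 1.1)
            d2 = (yy - r) ** 2 + (xx - c) ** 2
            img += peak * np.exp(-d2 / (2.0 * sigma**2))
            rows.append({"row": r, "col": c, "sigma": sigma, "peak": peak,
                         "pyknotic": bool(pyk)})
        # kept below the 10% relative-intensity mask even after the high-pass
        # filter renormalizes (white noise passes the filter and gains ~3x)
        img += rng.normal(0.0, 0.003, size=shape)
        img = np.clip(img, 0.0, 1.0)
    truth = pd.DataFrame(rows, columns=["row", "col", "sigma", "peak", "pyknotic"])
    return img, truth


def gen_nucleus_features(n: int, pyknotic_fraction: float, effect_size: float,
                         seed: int) -> pd.DataFrame:
    """Synthetic 8-feature nucleus records with a given class effect size.

    Produces the feature table (columns A, P, r_I, eps, I_M, I_T, I_W, sigma,
    pyknotic) used to benchmark the pyknosis classifier at a controlled
    standardized separation ``effect_size`` between classes.
    """
    rng = np.random.default_rng(seed)
    n_pyk = int(round(pyknotic_fraction * n))
    labels = np.zeros(n, dtype=bool)
    labels[rng.permutation(n)[:n_pyk]] = True
    base = {"A": 40.0, "P": 25.0, "r_I": 3.5, "eps": 1.0, "I_M": 1.0,
            "I_T": 40.0, "I_W": 0.4, "sigma": 3.5}
    spread = {k: 0.15 * abs(v) for k, v in base.items()}
    # pyknotic class shifts: smaller, brighter, tighter sigma
    direction = {"A": -1, "P": -1, "r_I": -1, "eps": 0, "I_M": 1, "I_T": -1,
                 "I_W": 1, "sigma": -1}
    data = {}
    for k in base:
        shift = direction[k] * effect_size * spread[k]
        mu = np.where(labels, base[k] + shift, base[k])
        data[k] = rng.normal(mu, spread[k])
    df = pd.DataFrame(data)
    df["pyknotic"] = labels
    return df


# ---------------------------------------------------------------------------
# microglia-like shapes
# ---------------------------------------------------------------------------

def _raster_family(rng, spec, canvas=96):
    """Rasterize one cell of a parametric family onto its own canvas."""
    mask = np.zeros((canvas, canvas), dtype=bool)
    cy = cx = canvas // 2
    theta = rng.uniform(0.0, np.pi)
    # narrow jitter keeps small digital disks above solidity 0.95
    jitter = rng.uniform(0.95, 1.05)
    kind = spec["kind"]
    if kind == "ellipse":
        a, b = spec["axes"]
        ra = max(a * jitter / 2.0, 1.5)
        rb = max(b * jitter / 2.0, 1.5)
        rr, cc = skdraw.ellipse(cy, cx, ra, rb, shape=mask.shape,
                                rotation=theta)
        mask[rr, cc] = True
        if a == b:
            # disks are convex; the hull removes raster notches that would
            # otherwise depress solidity below its analytic value
            from skimage.morphology import convex_hull_image

            mask = convex_hull_image(mask)
    elif kind == "branched":
        radius = spec["radius"] * jitter
        rr, cc = skdraw.disk((cy, cx), max(radius, 2.0), shape=mask.shape)
        mask[rr, cc] = True
        n_br = int(spec["n_branches"])
        blen = spec["branch_len"] * jitter
        for i in range(n_br):
            ang = theta + 2.0 * np.pi * i / n_br + rng.normal(0.0, 0.1)
            er = int(round(cy + blen * np.sin(ang)))
            ec = int(round(cx + blen * np.cos(ang)))
            er = int(np.clip(er, 1, canvas - 2))
            ec = int(np.clip(ec, 1, canvas - 2))
            rr, cc = skdraw.line(cy, cx, er, ec)
            for dr in (-1, 0, 1):
                rrc = np.clip(rr + dr, 0, canvas - 1)
                mask[rrc, cc] = True
    else:  # pragma: no cover - config validation
        raise ValueError(f"unknown shape family kind {kind!r}")
    return ndi.binary_fill_holes(mask)


def gen_microglia_images(config: SimulationConfig):
    """Generate per-cell masks from the 5 parametric shape families.

    Returns ``(masks, truth)``: a list of boolean arrays (one per cell) and a
    DataFrame with columns cell_id, family, family_name, sex, region, group.
    Metadata cycles through every sex x region x group combination so each
    stratum receives at least two cells whenever counts allow.
    """
    spec = config.shape_family_spec
    if len(spec) != 5:
        raise ValueError("exactly 5 shape families must be specified")
    rng = np.random.default_rng(config.seed)
    combos = [(s, r, g) for s in SEXES for r in REGIONS for g in GROUPS]
    masks, rows = [], []
    cell_id = 0
    for fam_idx, fam in enumerate(spec, start=1):
        for _ in range(int(fam.get("count", 0))):
            mask = _raster_family(rng, fam)
            sex, region, group = combos[cell_id % len(combos)]
            masks.append(mask)
            rows.append({"cell_id": cell_id, "family": fam_idx,
                         "family_name": fam["name"], "sex": sex,
                         "region": region, "group": group})
            cell_id += 1
    truth = pd.DataFrame(rows, columns=["cell_id", "family", "family_name",
                                        "sex", "region", "group"])
    return masks, truth


# ---------------------------------------------------------------------------
# expression panel
# ---------------------------------------------------------------------------

def gen_expression_panel(config: SimulationConfig):
    """Simulate a transcripts x samples log2 expression panel.

    Structure: 5 groups x 3 regions x ``n_samples_per_cell`` samples, additive
    Gaussian noise on the log2 scale.  Planted truth:

    - the first ``n_deg`` transcripts carry an injury (OGD-vs-control) shift of
      ``deg_log2_shift`` that persists in all treated groups;
    - within the DEG block, ``n_restored_combo`` transcripts return to the
      control mean in the combination group only, ``n_restored_az`` /
      ``n_restored_epo`` in the respective monotherapy (and combination);
    - for every non-emergent transcript the combination mean is the midpoint of
      the two monotherapy means (a deterministic, learnable map); the last
      ``n_emergent`` transcripts deviate from that map by
      ``emergent_offset_sd * noise_sd``.

    Returns ``(values, meta, truth)``: DataFrame transcripts x samples, sample
    metadata (sample_id, group, region, slice, sex), and the planted-effect
    truth table.
    """
    p = config.panel_size
    if p < config.n_deg + config.n_emergent:
        raise ValueError("panel_size must be >= n_deg + n_emergent")
    rng = np.random.default_rng(config.seed)
    transcripts = [f"T{i:03d}" for i in range(p)]
    baseline = rng.normal(8.0, 1.0, size=p)

    deg_idx = np.arange(config.n_deg)
    emergent_idx = np.arange(p - config.n_emergent, p)
    shift = np.zeros(p)
    shift[deg_idx] = config.deg_log2_shift

    restored_combo = set(deg_idx[: config.n_restored_combo])
    rest = deg_idx[config.n_restored_combo :]
    restored_az = set(rest[: config.n_restored_az])
    rest = rest[config.n_restored_az :]
    restored_epo = set(rest[: config.n_restored_epo])

    means = {g: np.copy(baseline) for g in GROUPS}
    for g in ("OGD", "Az", "Epo", "AzEpo"):
        means[g] = baseline + shift
    for i in restored_az:
        means["Az"][i] = baseline[i]
    for i in restored_epo:
        means["Epo"][i] = baseline[i]
    # combination mean: learnable midpoint map, then explicit restorations and
    # emergent offsets
    means["AzEpo"] = 0.5 * (means["Az"] + means["Epo"])
    for i in restored_combo | restored_az | restored_epo:
        means["AzEpo"][i] = baseline[i]
    offset = config.emergent_offset_sd * config.noise_sd
    means["AzEpo"][emergent_idx] += offset

    cols, data, meta_rows = [], [], []
    for g in GROUPS:
        for region in REGIONS:
            for k in range(config.n_samples_per_cell):
                sid = f"{g}_{region.replace(' ', '')}_{k}"
                cols.append(sid)
                data.append(means[g] + rng.normal(0.0, config.noise_sd, size=p))
                meta_rows.append({"sample_id": sid, "group": g, "region": region,
                                  "slice": k, "sex": SEXES[k % 2]})
    values = pd.DataFrame(np.column_stack(data), index=transcripts, columns=cols)
    meta = pd.DataFrame(meta_rows)

    truth_rows = []
    for i in deg_idx:
        truth_rows.append({"transcript": transcripts[i], "effect": "deg",
                           "log2_effect": config.deg_log2_shift,
                           "restored_by": ("AzEpo" if i in restored_combo
                                           else "Az" if i in restored_az
                                           else "Epo" if i in restored_epo
                                           else "")})
    for i in emergent_idx:
        truth_rows.append({"transcript": transcripts[i], "effect": "emergent",
                           "log2_effect": offset, "restored_by": ""})
    truth = pd.DataFrame(truth_rows,
                         columns=["transcript", "effect", "log2_effect",
                                  "restored_by"])
    return values, meta, truth


# ---------------------------------------------------------------------------
# per-slice outcomes
# ---------------------------------------------------------------------------

def gen_group_outcomes(config: SimulationConfig, regions=("global",),
                       assay: str = "LDH") -> pd.DataFrame:
    """Per-slice scalar outcomes with planted fractional treatment effects.

    The configured ``fractional_effect`` f of group X places its mean at
    ``mean(OGD) - f * (mean(OGD) - mean(control))``; f=1 matches control, f=0
    matches untreated injury.
    """
    missing = [g for g in GROUPS if g not in config.group_effects]
    if missing:
        raise ValueError(f"group_effects missing groups: {missing}")
    rng = np.random.default_rng(config.seed)
    injury = config.outcome_ogd_mean - config.outcome_control_mean
    rows = []
    for region in regions:
        for g in GROUPS:
            f = float(config.group_effects[g].get("fractional_effect", 0.0))
            mu = config.outcome_ogd_mean - f * injury
            vals = mu + rng.normal(0.0, config.outcome_noise_sd,
                                   size=config.n_slices_per_group)
            for s, v in enumerate(vals):
                rows.append({"slice": f"{g}_{s}", "group": g, "region": region,
                             "assay": assay, "value": v})
    return pd.DataFrame(rows, columns=["slice", "group", "region", "assay",
                                       "value"])


def write_image_tiff(path, img: np.ndarray) -> None:
    """Write a float image in [0, 1] as 16-bit grayscale TIFF."""
    import tifffile

    arr = np.clip(img, 0.0, 1.0)
    tifffile.imwrite(path, (arr * 65535.0 + 0.5).astype(np.uint16))


def _as_uint16(img: np.ndarray) -> np.ndarray:
    return (np.clip(img, 0.0, 1.0) * 65535.0 + 0.5).astype(np.uint16)
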