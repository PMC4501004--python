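"""Seedable generator of synthetic clustered-cell images with ground truth.

The generator emulates the controllable statistics of simulated fluorescence
microscopy benchmarks: a fixed number of elliptical cells placed either
uniformly at random or — with clustering probability ``p`` — touching or
overlapping a previously placed cell, with the permitted overlap depth set
by the overlap level ``L``.  Rendering adds per-cell brightness variation,
Gaussian blur, a linear illumination gradient and additive noise.  A second
preset degrades the image further in the style of Nissl-stained
micro-optical sections: dark cells on a bright background, stronger
illumination gradient, crescent-shaped cells and small cross-sections.

Ground truth records the analytic centroid of every placed cell plus a
pre-merging label mask, so nucleus-based evaluation needs no manual marking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as _draw_ellipse

from .preprocess import GrayImage

log = logging.getLogger(__name__)

#: The overlap level L scales the maximum permitted overlap depth between a
#: clustered cell and its neighbors, as a fraction of the smaller effective
#: radius: L = 0 means tangency only, L = 1 lets a cell sink in up to the
#: smaller cell's full radius (half-buried), so heavily merged pairs occur.
_OVERLAP_FRACTION_PER_LEVEL = 1.0

_MAX_TRIES = 200


@dataclass
class SimParams:
    """Generator settings; defaults mirror the clustered benchmark preset."""

    image_size: tuple[int, int] = (950, 950)
    n_cells: int = 300
    cluster_probability: float = 0.3
    overlap_level: float = 1.0
    cell_radius: tuple[float, float] = (11.0, 1.5)  # (mean, sd) px
    eccentricity: tuple[float, float] = (0.75, 1.0)  # minor/major axis ratio
    intensity: tuple[float, float, float] = (120.0, 25.0, 8.0)  # cell mean, sd, bg
    blur_sigma: float = 1.5
    noise_sd: float = 6.0
    illumination_gradient: float = 0.25
    crescent_fraction: float = 0.0
    dark_cells: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0.0 <= self.cluster_probability <= 1.0:
            raise ValueError("cluster_probability must be in [0, 1]")
        if self.cell_radius[0] <= 0:
            raise ValueError("cell radius must be positive")


@dataclass
class GroundTruth:
    """True centroids and pre-merging label mask of the placed cells."""

    centroids: np.ndarray
    truth_labels: np.ndarray
    n_placed: int = field(default=0)

    def __post_init__(self) -> None:
        self.n_placed = len(self.centroids)


PRESETS: dict[str, SimParams] = {
    "simcep_set1": SimParams(),
    "nsmost": SimParams(
        image_size=(600, 600),
        n_cells=200,
        cluster_probability=0.3,
        overlap_level=1.0,
        cell_radius=(7.0, 2.0),
        eccentricity=(0.6, 1.0),
        intensity=(140.0, 22.0, 10.0),
        blur_sigma=1.0,
        noise_sd=8.0,
        illumination_gradient=0.4,
        crescent_fraction=0.15,
        dark_cells=True,
    ),
}


def preset(name: str, **overrides) -> SimParams:
    """A copy of a named preset with field overrides applied."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)


def _place_cells(params: SimParams, rng: np.random.Generator):
    """Sequential placement; returns list of (r, c, a, b, theta, r_eff)."""
    h, w = params.image_size
    mean_r, sd_r = params.cell_radius
    e_lo, e_hi = params.eccentricity
    cells: list[tuple[float, float, float, float, float, float]] = []

    def sample_shape():
        r_eff = max(rng.normal(mean_r, sd_r), 1.5)
        ratio = rng.uniform(e_lo, e_hi)
        a = r_eff / np.sqrt(ratio)  # major semi-axis
        b = r_eff * np.sqrt(ratio)
        theta = rng.uniform(0, np.pi)
        return a, b, theta, r_eff

    def max_overlap(r1: float, r2: float) -> float:
        return _OVERLAP_FRACTION_PER_LEVEL * params.overlap_level * min(r1, r2)

    def admissible(r, c, r_eff, a_new: float, clustered: bool) -> bool:
        """Inside the frame and not too deep into any existing cell.

        A clustered placement is constrained only to the L-allowance with
        every neighbor, so dense clusters accumulate multiple touching and
        overlapping partners; a random placement may not touch anyone
        (clustering probability alone controls touching).
        """
        if not (r_eff <= r <= h - 1 - r_eff and r_eff <= c <= w - 1 - r_eff):
            return False
        for pr, pc, pa, *_rest, pr_eff in cells:
            d = float(np.hypot(r - pr, c - pc))
            if clustered:
                if d < r_eff + pr_eff - max_overlap(r_eff, pr_eff) - 1e-9:
                    return False
            else:
                # spacing against the major semi-axes plus a one-pixel gap,
                # so rasterized outlines of random placements never touch
                if d < a_new + pa + 1.0:
                    return False
        return True

    for _ in range(params.n_cells):
        a, b, theta, r_eff = sample_shape()
        placed = False
        for _try in range(_MAX_TRIES):
            if cells and rng.random() < params.cluster_probability:
                anchor_idx = int(rng.integers(len(cells)))
                ar, ac, *_r, a_eff = cells[anchor_idx]
                ov = rng.uniform(0, max_overlap(r_eff, a_eff))
                d = a_eff + r_eff - ov
                ang = rng.uniform(0, 2 * np.pi)
                r = ar + d * np.sin(ang)
                c = ac + d * np.cos(ang)
                if admissible(r, c, r_eff, a, clustered=True):
                    placed = True
                    break
            else:
                r = rng.uniform(r_eff, h - 1 - r_eff)
                c = rng.uniform(r_eff, w - 1 - r_eff)
                if admissible(r, c, r_eff, a, clustered=False):
                    placed = True
                    break
        if placed:
            cells.append((r, c, a, b, theta, r_eff))
    if len(cells) < params.n_cells:
        warnings.warn(
            f"placed only {len(cells)}/{params.n_cells} cells", stacklevel=2
        )
    return cells


def _cell_mask(shape, r, c, a, b, theta, crescent: bool, rng) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of one (possibly crescent-shaped) cell."""
    rr, cc = _draw_ellipse(r, c, a, b, shape=shape, rotation=theta)
    if not crescent:
        return rr, cc
    # subtract a shifted, shrunken ellipse to hollow out one side
    off = 0.55 * a
    rr2, cc2 = _draw_ellipse(
        r + off * np.sin(theta), c + off * np.cos(theta), 0.9 * a, 0.9 * b,
        shape=shape, rotation=theta,
    )
    keep = np.ones(len(rr), dtype=bool)
    hole = set(zip(rr2.tolist(), cc2.tolist()))
    for k, (pr, pc) in enumerate(zip(rr.tolist(), cc.tolist())):
        if (pr, pc) in hole:
            keep[k] = False
    if keep.sum() < 5:  # degenerate crescent: keep the full ellipse
        return rr, cc
    return rr[keep], cc[keep]


def generate(params: SimParams | None = None) -> tuple[GrayImage, GroundTruth]:
    """Render one synthetic image and its ground truth."""
    params = params or SimParams()
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    cell_mean, cell_sd, bg = params.intensity

    cells = _place_cells(params, rng)
    canvas = np.zeros((h, w), dtype=np.float64)
    truth_labels = np.zeros((h, w), dtype=np.int32)
    centroids = []
    for idx, (r, c, a, b, theta, _reff) in enumerate(cells, start=1):
        crescent = rng.random() < params.crescent_fraction
        rr, cc = _cell_mask((h, w), r, c, a, b, theta, crescent, rng)
        level = max(rng.normal(cell_mean, cell_sd), 30.0)
        texture = 1.0 + 0.05 * rng.standard_normal(len(rr))
        np.maximum.at(canvas, (rr, cc), level * texture)
        truth_labels[rr, cc] = idx
        if crescent and len(rr):
            centroids.append((float(rr.mean()), float(cc.mean())))
        else:
            centroids.append((r, c))

    img = canvas + bg
    if params.illumination_gradient > 0:
        g = params.illumination_gradient
        ramp = np.linspace(1 - g / 2, 1 + g / 2, w)[None, :]
        img = img * ramp
    if params.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, params.blur_sigma)
    if params.noise_sd > 0:
        img = img + rng.normal(0, params.noise_sd, size=img.shape)
    img = np.clip(img, 0, 255)
    if params.dark_cells:
        img = 255 - img
    gray = GrayImage(np.round(img).astype(np.uint8), bit_depth=8)
    truth = GroundTruth(
        centroids=np.asarray(centroids, dtype=np.float64).reshape(-1, 2),
        truth_labels=truth_labels,
    )
    return gray, truth


def nsmost_style(params: SimParams | None = None) -> tuple[GrayImage, GroundTruth]:
    """Degraded dark-cell preset: heterogeneous brightness, crescents,
    small cross-sections."""
    params = params or PRESETS["nsmost"]
    if not params.dark_cells:
        params = replace(params, dark_cells=True)
    return generate(params)


def count_touching_cells(truth: GroundTruth) -> int:
    """Number of truth cells 8-adjacent to (or overlapping) another cell."""
    labels = truth.truth_labels
    touching: set[int] = set()
    footprint = np.ones((3, 3), dtype=bool)
    dil_max = ndimage.maximum_filter(labels, footprint=footprint)
    lab_for_min = np.where(labels == 0, np.iinfo(np.int32).max, labels)
    dil_min = ndimage.minimum_filter(lab_for_min, footprint=footprint)
    fg = labels > 0
    conflict = fg & (dil_max != dil_min) & (dil_min != np.iinfo(np.int32).max)
    for lab in np.unique(labels[conflict]):
        if lab > 0:
            touching.add(int(lab))
    neigh = np.unique(dil_max[conflict])
    touching.update(int(x) for x in neigh if x > 0)
    return len(touching)


def write_truth(
    truth: GroundTruth, csv_path: str | None = None, label_path: str | None = None
) -> None:
    """Write the truth centroid CSV and/or label TIFF."""
    if csv_path is not None:
        import pandas as pd

        pd.DataFrame(
            {
                "cell_id": np.arange(1, truth.n_placed + 1),
                "row": truth.centroids[:, 0],
                "col": truth.centroids[:, 1],
            }
        ).to_csv(csv_path, index=False)
    if label_path is not None:
        import tifffile

        tifffile.imwrite(label_path, truth.truth_labels.astype(np.uint16))
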