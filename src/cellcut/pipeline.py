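"""End-to-end segmentation: image -> cleaned mask -> per-component graph
cuts -> global label mask and centroid table.

Each connected component of the binarized image is processed independently:
its contour and concave points are found, an affinity graph is built on the
component's bounding-box crop, and the recursive normalized cut partitions
it into cell groups.  Coordinates are 0-based (row, col) with row increasing
downward; centroids are arithmetic means of group pixel coordinates in that
frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import contours
from .affinity import AffinityParams, build_affinity
from .ncut import CutConfig, recursive_cut
from .preprocess import (
    BinaryMask,
    GrayImage,
    LabeledComponents,
    enhance_linear_stretch,
    label_components,
    otsu_binarize,
    remove_small_components,
    subtract_background,
)

log = logging.getLogger(__name__)


@dataclass
class SegmentationConfig:
    """All knobs of the full chain, grouped by stage."""

    polarity: str = "light_cells"
    flat_background: bool = False
    min_area: int = 30
    concave_T: float = contours.DEFAULT_T
    affinity: AffinityParams = field(default_factory=AffinityParams)
    cut: CutConfig = field(default_factory=CutConfig)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SegmentationResult:
    """Label mask (0 = background, 1..M = cells), centroids and provenance.

    ``centroids[m - 1]`` is the (row, col) mean of label ``m``;
    ``provenance`` records each cell's source connected component and the
    number of cuts that component underwent.
    """

    labels: np.ndarray
    centroids: np.ndarray
    provenance: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return len(self.centroids)


def binarize(img: GrayImage, config: SegmentationConfig) -> BinaryMask:
    """Preprocessing sub-chain shared by segmentation and diagnostics."""
    enhanced = enhance_linear_stretch(img)
    normalized = subtract_background(
        enhanced, polarity=config.polarity, flat_background=config.flat_background
    )
    mask = otsu_binarize(normalized)
    return remove_small_components(mask, config.min_area)


def segment_image(img: GrayImage, config: SegmentationConfig | None = None) -> SegmentationResult:
    """Run the full segmentation chain on one grayscale image."""
    config = config or SegmentationConfig()
    mask = binarize(img, config)
    comps = label_components(mask)
    if comps.count == 0:
        log.warning("empty foreground: no cells found")
        return SegmentationResult(
            labels=np.zeros(img.shape, dtype=np.int32),
            centroids=np.zeros((0, 2)),
            provenance=pd.DataFrame(columns=["cell_id", "component_id", "n_cuts"]),
        )

    edge = contours.extract_edges(mask)
    concave = contours.detect_concave_contour(mask, edge, T=config.concave_T)
    concave_mask = concave.point_mask(mask.shape)

    out = np.zeros(img.shape, dtype=np.int32)
    prov_rows = []
    next_label = 1
    for cid in range(1, comps.count + 1):
        graph = build_affinity(comps, cid, edge, concave, config.affinity)
        r0, r1, c0, c1 = comps.bounding_boxes[cid - 1]
        n_concave = int(
            concave_mask[r0:r1, c0:c1][
                comps.labels[r0:r1, c0:c1] == cid
            ].sum()
        )
        part = recursive_cut(graph.weights, n_concave, config.cut)
        groups = _merge_slivers(graph, part.groups, config.cut.min_segment_area)
        for g in groups:
            out[graph.rows[g], graph.cols[g]] = next_label
            prov_rows.append(
                {"cell_id": next_label, "component_id": cid, "n_cuts": part.n_cuts_accepted}
            )
            next_label += 1

    centroids = compute_centroids(out)
    return SegmentationResult(
        labels=out, centroids=centroids, provenance=pd.DataFrame(prov_rows)
    )


def _merge_slivers(graph, groups: list[np.ndarray], min_area: int) -> list[np.ndarray]:
    """Fold groups below ``min_area`` into their best-connected neighbor.

    Barrier shadows can leave near-disconnected crumbs; a crumb is not a
    cell, so it joins the group it shares the most affinity with.
    """
    groups = [np.asarray(g) for g in groups]
    if len(groups) < 2:
        return groups
    W = graph.weights
    while True:
        sizes = [len(g) for g in groups]
        small = [i for i, s in enumerate(sizes) if s < min_area]
        if not small or len(groups) < 2:
            return groups
        i = small[0]
        gi = groups[i]
        links = np.asarray(W[gi].sum(axis=0)).ravel()
        best, best_w = None, -1.0
        for j, gj in enumerate(groups):
            if j == i:
                continue
            w = float(links[gj].sum())
            if w > best_w:
                best, best_w = j, w
        groups[best] = np.concatenate([groups[best], gi])
        del groups[i]


def compute_centroids(labels: np.ndarray) -> np.ndarray:
    """Per-label (row, col) coordinate means, in label order (1..M)."""
    n = int(labels.max())
    if n == 0:
        return np.zeros((0, 2))
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=n + 1)[1:].astype(np.float64)
    rr, cc = np.indices(labels.shape)
    sum_r = np.bincount(flat, weights=rr.ravel(), minlength=n + 1)[1:]
    sum_c = np.bincount(flat, weights=cc.ravel(), minlength=n + 1)[1:]
    with np.errstate(invalid="ignore"):
        cents = np.column_stack([sum_r / counts, sum_c / counts])
    return cents[counts > 0]


def write_outputs(
    result: SegmentationResult,
    label_path: str | None = None,
    csv_path: str | None = None,
    overlay_path: str | None = None,
    image: GrayImage | None = None,
) -> None:
    """Write the 16-bit label TIFF, centroid CSV and optional overlay PNG."""
    if label_path is not None:
        import tifffile

        tifffile.imwrite(label_path, result.labels.astype(np.uint16))
    if csv_path is not None:
        areas = np.bincount(result.labels.ravel())[1:]
        df = pd.DataFrame(
            {
                "cell_id": np.arange(1, result.n_cells + 1),
                "row": result.centroids[:, 0],
                "col": result.centroids[:, 1],
                "area": areas[: result.n_cells],
                "component_id": (
                    result.provenance["component_id"].to_numpy()
                    if len(result.provenance)
                    else np.zeros(0, int)
                ),
            }
        )
        df.to_csv(csv_path, index=False)
    if overlay_path is not None:
        _write_overlay(overlay_path, result, image)


def _write_overlay(path: str, result: SegmentationResult, image: GrayImage | None) -> None:
    """Cyan group boundaries and magenta centroids over the source image."""
    import imageio.v3 as iio
    from scipy import ndimage

    labels = result.labels
    if image is not None:
        base = (image.pixels.astype(np.float64) / image.max_level * 255).astype(np.uint8)
    else:
        base = ((labels > 0) * 160).astype(np.uint8)
    rgb = np.stack([base] * 3, axis=-1)
    interior = ndimage.grey_erosion(labels, size=(3, 3))
    boundary = (labels > 0) & (labels != interior)
    rgb[boundary] = (0, 255, 255)
    for r, c in np.round(result.centroids).astype(int):
        rgb[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2] = (255, 0, 255)
    iio.imwrite(path, rgb)
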