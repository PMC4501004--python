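"""Sparse affinity graph over the pixels of one connected component.

Each foreground pixel is a graph node.  The weight between two pixels i, j is

    W(i, j) = W_s(i, j) * W_c(i, j)

where the spatial term ``W_s = exp(-||X_i - X_j||^2 / sigma_x^2)`` for pixel
distance below a cutoff radius ``r`` (0 beyond), and the contour term
``W_c`` is a binary gate: 0 whenever the digitized open segment joining i and
j crosses a barrier pixel — an image edge (the intervening contour) or a
concave junction point — and 1 otherwise.  On a binary mask the oriented
edge energy reduces to this crossing test, because foreground and background
are internally uniform and only the contour carries edge response.

Because the digitized segment between i and j depends only on the offset
j - i, the whole construction is vectorized per offset with shifted slices
of the barrier mask, which keeps graph assembly linear in component area.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage, sparse

from .contours import ConcaveContour, EdgeMap
from .preprocess import STRUCTURE_8, LabeledComponents


@dataclass
class AffinityParams:
    """Kernel scale and neighborhood radius of the spatial weight (pixels)."""

    sigma_x: float = 4.0
    radius: float = 10.0

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.radius <= 0:
            raise ValueError("sigma_x and radius must be positive")


@dataclass
class AffinityGraph:
    """Symmetric non-negative pixel affinity matrix of one component.

    ``rows``/``cols`` give the image coordinates of node ``k``; ``weights``
    is CSR with unit diagonal (self-weight convention keeps every degree
    positive).
    """

    rows: np.ndarray
    cols: np.ndarray
    weights: sparse.csr_matrix
    params: AffinityParams

    @property
    def n_nodes(self) -> int:
        return len(self.rows)


def spatial_weight(
    i: tuple[int, int], j: tuple[int, int], sigma_x: float, r: float
) -> float:
    """Gaussian proximity weight with hard cutoff at distance ``r``."""
    d2 = float((i[0] - j[0]) ** 2 + (i[1] - j[1]) ** 2)
    if d2 >= r * r:
        return 0.0
    return float(np.exp(-d2 / (sigma_x * sigma_x)))


@lru_cache(maxsize=4096)
def _open_segment_offsets(dr: int, dc: int) -> tuple[tuple[int, int], ...]:
    """Interior pixels of the digitized segment (0,0)->(dr,dc).

    A pixel (r, c) owns the unit cell [r-1/2, r+1/2] x [c-1/2, c+1/2]; the
    digitized segment is the exact sequence of cells whose interior the
    continuous line passes through (grid-traversal rasterization, computed
    with rational arithmetic; corner touches excluded).  The set is a
    geometric property of the segment, hence symmetric in the endpoints and
    translation invariant.
    """
    from fractions import Fraction

    half = Fraction(1, 2)
    ts = {Fraction(0), Fraction(1)}
    for d in (dr, dc):
        if d:
            for m in range(-abs(d), abs(d) + 1):
                t = Fraction(2 * m + 1, 2 * d)
                if 0 < t < 1:
                    ts.add(t)
    knots = sorted(ts)
    pts: set[tuple[int, int]] = set()
    for t0, t1 in zip(knots[:-1], knots[1:]):
        tm = (t0 + t1) / 2
        r = int((tm * dr) + half) if tm * dr >= 0 else -int((-tm * dr) + half)
        c = int((tm * dc) + half) if tm * dc >= 0 else -int((-tm * dc) + half)
        pts.add((r, c))
    pts.discard((0, 0))
    pts.discard((dr, dc))
    return tuple(sorted(pts))


def segment_crosses(
    mask: np.ndarray, i: tuple[int, int], j: tuple[int, int]
) -> bool:
    """True iff the open digitized segment from i to j hits a True pixel.

    Endpoints are excluded, so 8-adjacent pixels never cross anything.  The
    test is symmetric in (i, j) by construction.
    """
    if i == j:
        raise ValueError("segment endpoints must differ")
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    for dr, dc in _open_segment_offsets(int(j[0] - i[0]), int(j[1] - i[1])):
        r, c = i[0] + dr, i[1] + dc
        if 0 <= r < h and 0 <= c < w and mask[r, c]:
            return True
    return False


def barrier_mask(
    edge: EdgeMap, concave: ConcaveContour, shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Edges plus concave points dilated by one pixel (3x3).

    The dilation makes the junction barrier watertight: a single-pixel point
    is easily stepped over by a rasterized line.
    """
    shape = shape or edge.pixels.shape
    barrier = edge.pixels.copy()
    if concave.count:
        pts = concave.point_mask(shape)
        barrier |= ndimage.binary_dilation(pts, structure=STRUCTURE_8)
    return barrier


def contour_weight(
    i: tuple[int, int],
    j: tuple[int, int],
    edge: EdgeMap,
    concave: ConcaveContour,
) -> int:
    """Binary barrier gate: 0 if the i-j segment crosses edge or concave
    contour (concave points pre-dilated by one pixel), else 1."""
    return 0 if segment_crosses(barrier_mask(edge, concave), i, j) else 1


def _neighbor_offsets(radius: float) -> list[tuple[int, int]]:
    """Half-plane of integer offsets with 0 < ||offset|| < radius."""
    m = int(np.ceil(radius))
    offsets = []
    for dr in range(0, m + 1):
        for dc in range(-m, m + 1):
            if dr == 0 and dc <= 0:
                continue  # keep one representative of each {o, -o} pair
            if dr * dr + dc * dc < radius * radius:
                offsets.append((dr, dc))
    return offsets


def build_affinity(
    components: LabeledComponents,
    label_id: int,
    edge: EdgeMap,
    concave: ConcaveContour,
    params: AffinityParams | None = None,
) -> AffinityGraph:
    """Assemble the sparse affinity matrix for component ``label_id``.

    Only pixel pairs of the component within the cutoff radius are stored;
    each stored weight is the Gaussian spatial term gated by the barrier
    crossing test.  The construction is exactly equivalent to evaluating
    ``spatial_weight * contour_weight`` on every in-range pair.
    """
    params = params or AffinityParams()
    if not 1 <= label_id <= components.count:
        raise ValueError(f"label {label_id} out of range")
    r0, r1, c0, c1 = components.bounding_boxes[label_id - 1]
    pad = int(np.ceil(params.radius))
    h, w = components.labels.shape
    R0, R1 = max(r0 - pad, 0), min(r1 + pad, h)
    C0, C1 = max(c0 - pad, 0), min(c1 + pad, w)

    comp = components.labels[R0:R1, C0:C1] == label_id
    barrier = barrier_mask(edge, concave)[R0:R1, C0:C1]

    node_id = -np.ones(comp.shape, dtype=np.int64)
    rr, cc = np.nonzero(comp)
    n = len(rr)
    node_id[rr, cc] = np.arange(n)

    rows_out: list[np.ndarray] = []
    cols_out: list[np.ndarray] = []
    vals_out: list[np.ndarray] = []
    H, W = comp.shape
    sig2 = params.sigma_x**2

    for dr, dc in _neighbor_offsets(params.radius):
        # slice views of "pixel p" and "pixel p + offset"
        a_r0, a_r1 = max(0, -dr), min(H, H - dr)
        a_c0, a_c1 = max(0, -dc), min(W, W - dc)
        if a_r0 >= a_r1 or a_c0 >= a_c1:
            continue
        src = comp[a_r0:a_r1, a_c0:a_c1]
        dst = comp[a_r0 + dr : a_r1 + dr, a_c0 + dc : a_c1 + dc]
        valid = src & dst
        if not valid.any():
            continue
        crossed = np.zeros_like(valid)
        for mr, mc in _open_segment_offsets(dr, dc):
            # interior pixels lie between the endpoints, so these shifted
            # windows are always inside the padded crop
            crossed |= barrier[a_r0 + mr : a_r1 + mr, a_c0 + mc : a_c1 + mc]
        open_pairs = valid & ~crossed
        if not open_pairs.any():
            continue
        pr, pc = np.nonzero(open_pairs)
        src_nodes = node_id[a_r0 + pr, a_c0 + pc]
        dst_nodes = node_id[a_r0 + pr + dr, a_c0 + pc + dc]
        wgt = np.exp(-(dr * dr + dc * dc) / sig2)
        rows_out.append(src_nodes)
        cols_out.append(dst_nodes)
        vals_out.append(np.full(len(src_nodes), wgt))

    if rows_out:
        ri = np.concatenate(rows_out)
        ci = np.concatenate(cols_out)
        vi = np.concatenate(vals_out)
        # symmetrize and add the unit self-weight
        ri_all = np.concatenate([ri, ci, np.arange(n)])
        ci_all = np.concatenate([ci, ri, np.arange(n)])
        vi_all = np.concatenate([vi, vi, np.ones(n)])
    else:
        ri_all = ci_all = np.arange(n)
        vi_all = np.ones(n)
    W_mat = sparse.coo_matrix((vi_all, (ri_all, ci_all)), shape=(n, n)).tocsr()
    return AffinityGraph(
        rows=rr + R0, cols=cc + C0, weights=W_mat, params=params
    )


def dump_affinity(path: str, graph: AffinityGraph) -> None:
    """Write the matrix in coordinate text format (row, col, weight)."""
    coo = graph.weights.tocoo()
    with open(path, "w") as fh:
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r} {c} {v:.8g}\n")
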