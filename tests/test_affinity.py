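"""Affinity graph: spatial kernel, line-crossing barrier, assembly."""

import numpy as np
import pytest

from cellcut.affinity import (
    AffinityParams,
    barrier_mask,
    build_affinity,
    contour_weight,
    segment_crosses,
    spatial_weight,
)
from cellcut.contours import detect_concave_contour, extract_edges
from cellcut.ncut import CutConfig, ncut_value, recursive_cut
from cellcut.preprocess import BinaryMask, label_components
from tests.conftest import make_disk_mask


def cell_intersection_oracle(p0, p1):
    """Independent rasterization oracle: brute-force test, per candidate
    pixel, of whether the open segment passes through the interior of that
    pixel's unit cell (exact rational interval intersection)."""
    from fractions import Fraction

    (r0, c0), (r1, c1) = p0, p1
    dr, dc = r1 - r0, c1 - c0
    half = Fraction(1, 2)
    pts = set()
    for r in range(min(r0, r1) - 1, max(r0, r1) + 2):
        for c in range(min(c0, c1) - 1, max(c0, c1) + 2):
            lo, hi = Fraction(0), Fraction(1)
            ok = True
            for d, x0, x in ((dr, r0, r), (dc, c0, c)):
                if d == 0:
                    if abs(x0 - x) > half:
                        ok = False
                        break
                else:
                    a = (Fraction(x - x0) - half) / d
                    b = (Fraction(x - x0) + half) / d
                    lo, hi = max(lo, min(a, b)), min(hi, max(a, b))
            if not ok or lo >= hi:
                continue  # empty or corner-touch (degenerate) intersection
            pts.add((r, c))
    pts.discard((r0, c0))
    pts.discard((r1, c1))
    return pts


def crosses_supersampled(mask, i, j, n_samples=400):
    """Continuous-line oracle: dense samples of the open segment, mapped to
    the pixel grid by rounding."""
    hits = set()
    for t in np.linspace(0, 1, n_samples)[1:-1]:
        r = round(i[0] + t * (j[0] - i[0]))
        c = round(i[1] + t * (j[1] - i[1]))
        if (r, c) not in (tuple(i), tuple(j)):
            hits.add((r, c))
    return any(mask[r, c] for r, c in hits)


class TestSpatialWeight:
    def test_zero_distance_gives_one(self):
        assert spatial_weight((5, 5), (5, 5), sigma_x=4, r=10) == 1.0

    def test_cutoff_beyond_radius(self):
        assert spatial_weight((0, 0), (0, 10), sigma_x=4, r=10) == 0.0

    def test_gaussian_value_at_sigma(self):
        w = spatial_weight((0, 0), (0, 4), sigma_x=4, r=10)
        assert w == pytest.approx(np.exp(-1), rel=1e-12)


class TestSegmentCrosses:
    def test_adjacent_pixels_never_cross(self):
        m = np.ones((5, 5), bool)
        assert not segment_crosses(m, (2, 2), (2, 3))
        assert not segment_crosses(m, (2, 2), (3, 3))

    def test_empty_mask_never_crosses(self):
        m = np.zeros((10, 10), bool)
        assert not segment_crosses(m, (1, 1), (8, 7))

    def test_identical_endpoints_rejected(self):
        with pytest.raises(ValueError):
            segment_crosses(np.zeros((3, 3), bool), (1, 1), (1, 1))

    def test_symmetric_in_endpoints(self, rng):
        m = rng.random((15, 15)) > 0.8
        pts = rng.integers(0, 15, size=(40, 4))
        for r0, c0, r1, c1 in pts:
            if (r0, c0) == (r1, c1):
                continue
            assert segment_crosses(m, (r0, c0), (r1, c1)) == segment_crosses(
                m, (r1, c1), (r0, c0)
            )

    def test_agrees_with_independent_rasterizer(self, rng):
        m = rng.random((15, 15)) > 0.85
        pairs = []
        for r0 in range(15):
            for c0 in range(15):
                for r1 in range(15):
                    for c1 in range(15):
                        if (r0 - r1) ** 2 + (c0 - c1) ** 2 <= 36 and (r0, c0) != (r1, c1):
                            pairs.append(((r0, c0), (r1, c1)))
        rng.shuffle(pairs)
        agree_super = 0
        checked = pairs[:600]
        for i, j in checked:
            got = segment_crosses(m, i, j)
            interior = cell_intersection_oracle(i, j)
            assert got == any(m[r, c] for r, c in interior)
            if got == crosses_supersampled(m, i, j):
                agree_super += 1
        assert agree_super / len(checked) >= 0.99


class TestContourWeight:
    @pytest.fixture
    def three_disk_setup(self, three_touching_disks):
        mask = three_touching_disks
        edge = extract_edges(mask)
        conc = detect_concave_contour(mask, edge)
        return mask, edge, conc

    def test_clear_path_within_one_cell_keeps_weight(self, three_disk_setup):
        _, edge, conc = three_disk_setup
        # P and Q inside the same disk, short chord, away from any contour
        assert contour_weight((35, 30), (38, 36), edge, conc) == 1

    def test_path_across_concave_junction_is_zero(self, three_disk_setup):
        mask, edge, conc = three_disk_setup
        # R in disk 1, Q in disk 2: the segment passes through the upper
        # notch of their junction, where the dilated concave points sit
        i, j = (29, 47), (29, 55)
        assert mask.pixels[i] and mask.pixels[j]
        assert contour_weight(i, j, edge, conc) == 0

    def test_path_across_intervening_contour_is_zero(self, three_disk_setup):
        mask, edge, conc = three_disk_setup
        # R inside disk 1, S inside disk 2, above the junction: the straight
        # line crosses the background gap and hence the outer edge map
        i, j = (24, 44), (22, 58)
        assert mask.pixels[i] and mask.pixels[j]
        assert segment_crosses(edge.pixels, i, j)
        assert contour_weight(i, j, edge, conc) == 0


class TestBuildAffinity:
    def build(self, mask, params=None):
        edge = extract_edges(mask)
        conc = detect_concave_contour(mask, edge)
        comps = label_components(mask)
        return build_affinity(comps, 1, edge, conc, params), edge, conc

    def test_symmetric_nonnegative_unit_diagonal(self, touching_pair):
        g, _, _ = self.build(touching_pair)
        W = g.weights
        assert (W != W.T).nnz == 0
        assert (W.data >= 0).all()
        assert np.allclose(W.diagonal(), 1.0)

    def test_matches_dense_bruteforce_on_small_component(self):
        mask = BinaryMask(make_disk_mask((26, 26), (13, 13), 9))
        params = AffinityParams(sigma_x=3.0, radius=6.0)
        g, edge, conc = self.build(mask, params)
        n = g.n_nodes
        assert n <= 400
        dense = np.eye(n)
        bar = barrier_mask(edge, conc)
        for a in range(n):
            for b in range(a + 1, n):
                i = (g.rows[a], g.cols[a])
                j = (g.rows[b], g.cols[b])
                ws = spatial_weight(i, j, params.sigma_x, params.radius)
                if ws == 0:
                    continue
                wc = 0 if segment_crosses(bar, i, j) else 1
                dense[a, b] = dense[b, a] = ws * wc
        assert np.allclose(g.weights.toarray(), dense)

    def test_sparsity_bound(self, touching_pair):
        params = AffinityParams(sigma_x=4.0, radius=8.0)
        g, _, _ = self.build(touching_pair, params)
        offsets = sum(
            1
            for dr in range(-8, 9)
            for dc in range(-8, 9)
            if dr * dr + dc * dc < 64
        )
        assert g.weights.nnz <= g.n_nodes * offsets

    def test_cross_waist_weights_are_zero(self, touching_pair):
        g, edge, conc = self.build(touching_pair)
        W = g.weights.tocsr()
        cols = g.cols
        left = np.nonzero(cols <= 30)[0]
        right = np.nonzero(cols >= 44)[0]
        # pixels deep in either disk: any pair within reach straddles the
        # junction barrier, so its weight must vanish
        block = W[left][:, right]
        assert block.nnz == 0

    def test_single_pixel_component(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        g, _, _ = self.build(BinaryMask(m))
        assert g.n_nodes == 1 and g.weights.shape == (1, 1)
        assert g.weights[0, 0] == 1.0

    def test_rescaling_leaves_ncut_invariant(self, touching_pair, rng):
        g, _, _ = self.build(touching_pair)
        n = g.n_nodes
        A = np.sort(rng.choice(n, size=n // 3, replace=False))
        B = np.setdiff1d(np.arange(n), A)
        v1 = ncut_value(g.weights, A, B)
        v2 = ncut_value(g.weights * 7.5, A, B)
        assert v1 == pytest.approx(v2, rel=1e-9)

    def test_rescaling_leaves_partition_unchanged(self):
        # small enough for the dense eigensolver, where the invariance is exact
        m = make_disk_mask((50, 70), (25, 22), 9)
        m |= make_disk_mask((50, 70), (25, 38), 9)
        g, _, conc = self.build(BinaryMask(m))
        assert g.n_nodes < 600
        p1 = recursive_cut(g.weights, conc.count, CutConfig())
        p2 = recursive_cut(g.weights * 3.0, conc.count, CutConfig())
        assert len(p1.groups) == 2
        assert {frozenset(map(int, g)) for g in p1.groups} == {
            frozenset(map(int, g)) for g in p2.groups
        }
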