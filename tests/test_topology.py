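"""Gauss linking, writhe, crossing diagrams and the second Vassiliev measure.

Two independent oracles back the exact implementations: direct numerical
quadrature of the Gauss integrand for single segment pairs, and
projection-sampled signed crossing counts for whole curves.  Closed-knot
second Vassiliev values are cross-checked against a Polyak-Viro style
basepoint count on the same diagrams.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tautopo.curves import CurveError, PolygonalCurve
from tautopo import topology as top
from tautopo.synthetic import (make_k21_knotoid, make_knot, make_unknot,
                               random_open_curve, K21_CANONICAL_DIRECTION)

MIRROR = np.diag([1.0, 1.0, -1.0])


def quadrature_pair_gauss(a0, a1, b0, b1, n=400):
    """Direct midpoint quadrature of the Gauss integrand over two segments."""
    t = (np.arange(n) + 0.5) / n
    p = a0 + t[:, None] * (a1 - a0)
    q = b0 + t[:, None] * (b1 - b0)
    dp = (a1 - a0) / n
    dq = (b1 - b0) / n
    diff = p[:, None, :] - q[None, :, :]
    r3 = np.linalg.norm(diff, axis=-1) ** 3
    integrand = np.einsum("k,ijk->ij", np.cross(dp, dq), diff) / r3
    return integrand.sum() / (4 * np.pi)


def polyak_viro_v2(diagram, n_edges, basepoint=0.0):
    """Basepoint Gauss-diagram count: sum of eps_c*eps_d over ordered crossing
    pairs whose (under_c, over_d, over_c, under_d) passages occur in that
    order walking from the basepoint.  Independent of the alternating-pair
    half-sum used by diagram_v2."""
    cr = [((c.over_pos - basepoint) % n_edges,
           (c.under_pos - basepoint) % n_edges, c.sign)
          for c in diagram.crossings]
    total = 0
    for (oc, uc, ec), (od, ud, ed) in itertools.permutations(cr, 2):
        if uc < od < oc < ud:
            total += ec * ed
    return total


class TestSegmentPairGauss:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quadrature(self, seed):
        rng = np.random.default_rng(seed)
        a0, a1, b0, b1 = rng.normal(size=(4, 3)) * 2
        exact = top._segment_pair_gauss(a0, a1, b0, b1)
        approx = quadrature_pair_gauss(a0, a1, b0, b1)
        assert exact == pytest.approx(approx, abs=2e-4)

    def test_coplanar_zero(self):
        v = top._segment_pair_gauss(np.array([0., 0, 0]), np.array([1., 0, 0]),
                                    np.array([0., 1, 0]), np.array([1., 2, 0]))
        assert v == 0.0


class TestGaussLinking:
    def test_matches_projection_oracle(self, random_curve_pair):
        c1, c2 = random_curve_pair
        exact = top.gauss_linking(c1, c2)
        est, se = top.mc_linking(c1, c2, 40_000, seed=5)
        assert abs(exact - est) < 3 * se + 1e-12

    def test_hopf_arcs(self):
        th = np.linspace(0, np.radians(359.9), 180)
        a = PolygonalCurve(np.column_stack([np.cos(th), np.sin(th), 0 * th]))
        b = PolygonalCurve(np.column_stack([1 + np.cos(th), 0 * th, np.sin(th)]))
        assert abs(abs(top.gauss_linking(a, b)) - 1.0) < 0.01

    def test_coplanar_curves_zero(self):
        a = PolygonalCurve([[0., 0, 0], [1, 0, 0], [1, 1, 0]])
        b = PolygonalCurve([[2., 0, 0], [3, 1, 0], [2, 2, 0]])
        assert top.gauss_linking(a, b) == 0.0

    def test_symmetric_in_arguments(self, random_curve_pair):
        c1, c2 = random_curve_pair
        assert top.gauss_linking(c1, c2) == pytest.approx(
            top.gauss_linking(c2, c1), abs=1e-12)

    def test_orientation_reversal_negates(self, random_curve_pair):
        c1, c2 = random_curve_pair
        lk = top.gauss_linking(c1, c2)
        assert top.gauss_linking(c1.reversed(), c2) == pytest.approx(-lk, abs=1e-12)
        assert top.gauss_linking(c1.reversed(), c2.reversed()) == pytest.approx(
            lk, abs=1e-12)

    def test_shared_point_rejected(self):
        a = PolygonalCurve([[0., 0, 0], [1, 0, 0]])
        b = PolygonalCurve([[1., 0, 0], [2, 1, 1]])
        with pytest.raises(top.SingularityError):
            top.gauss_linking(a, b)


class TestWrithe:
    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_matches_projection_oracle(self, seed):
        c = random_open_curve(20, seed=seed)
        est, se = top.mc_writhe(c, 40_000, seed=seed + 1)
        assert abs(top.writhe(c) - est) < 3 * se + 1e-12

    def test_planar_zero(self):
        rng = np.random.default_rng(2)
        pts = np.column_stack([rng.normal(size=12), rng.normal(size=12),
                               np.zeros(12)])
        assert top.writhe(PolygonalCurve(pts)) == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(CurveError):
            top.writhe(PolygonalCurve([[0., 0, 0], [1, 1, 1]]))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_mirror_negates_and_rigid_motion_preserves(self, seed):
        c = random_open_curve(12, seed=seed)
        wr = top.writhe(c)
        assert top.writhe(c.transformed(matrix=MIRROR)) == pytest.approx(
            -wr, abs=1e-10)
        rng = np.random.default_rng(seed + 1)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = c.transformed(matrix=q, shift=rng.normal(size=3), scale=2.5)
        assert top.writhe(moved) == pytest.approx(wr, abs=1e-8)

    def test_continuity_under_perturbation(self):
        c = random_open_curve(18, seed=3)
        rng = np.random.default_rng(4)
        pert = PolygonalCurve(c.vertices + 1e-6 * rng.normal(size=c.vertices.shape))
        assert abs(top.writhe(pert) - top.writhe(c)) < 1e-4


class TestCrossingSign:
    def test_reference_convention(self):
        """Over along +x, under along +y, viewed from +z is right-handed."""
        assert top.crossing_sign([1, 0, 0], [0, 1, 0], [0, 0, 1]) == 1
        assert top.crossing_sign([0, 1, 0], [1, 0, 0], [0, 0, 1]) == -1

    def test_orientation_reversal_negates(self):
        s = top.crossing_sign([1, 0, 0], [0, 1, 0], [0, 0, 1])
        assert top.crossing_sign([-1, 0, 0], [0, 1, 0], [0, 0, 1]) == -s

    def test_parallel_rejected(self):
        with pytest.raises(top.DegenerateProjectionError):
            top.crossing_sign([1, 0, 0], [2, 0, 0], [0, 0, 1])

    def test_sign_agrees_with_exact_pair_integral(self):
        """For two crossing straight segments, the diagram sign at the
        crossing direction matches the sign of the exact Gauss integral."""
        over = PolygonalCurve([[-1., 0, 1], [1, 0, 1]])
        under = PolygonalCurve([[0., -1, 0], [0, 1, 0]])
        lk = top.gauss_linking(over, under)
        sgn = top.crossing_sign([2, 0, 0], [0, 2, 0], [0, 0, 1])
        assert np.sign(lk) == sgn


class TestProjectDiagram:
    def test_straight_curve_no_crossings(self):
        c = PolygonalCurve([[0., 0, 0], [1, 0.1, 0], [2, 0, 0.1]])
        d = top.project_diagram(c, direction=(0, 0, 1))
        assert d.crossings == ()

    def test_trefoil_axis_view(self):
        c = make_knot("trefoil", 61)
        direction = np.array([0.01, 0.013, 1.0])
        direction /= np.linalg.norm(direction)
        d = top.project_diagram(c, direction=direction)
        assert len(d.crossings) == 3
        assert len({x.sign for x in d.crossings}) == 1

    def test_two_curve_diagram_halves_to_linking(self, random_curve_pair):
        """Averaged half signed inter-crossing count estimates Lk."""
        c1, c2 = random_curve_pair
        rng = np.random.default_rng(9)
        vals = []
        while len(vals) < 400:
            direction = top.sample_directions(1, rng)[0]
            try:
                d = top.project_diagram(c1, c2, direction)
            except top.DegenerateProjectionError:
                continue
            vals.append(0.5 * d.signed_count())
        mean = np.mean(vals)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(mean - top.gauss_linking(c1, c2)) < 4 * se + 1e-9

    def test_non_unit_direction_rejected(self):
        c = random_open_curve(5, seed=1)
        with pytest.raises(CurveError):
            top.project_diagram(c, direction=(0, 0, 2))


class TestDiagramV2:
    def test_few_crossings_zero(self):
        c = PolygonalCurve([[0., 0, 0], [1, 0.2, 0], [2, 0, 0]])
        d = top.project_diagram(c, direction=(0, 0, 1))
        assert top.diagram_v2(d) == 0.0

    @pytest.mark.parametrize("kind,expected",
                             [("trefoil", 1.0), ("figure8", -1.0),
                              ("5_2", 2.0), ("unknot", 0.0)])
    def test_closed_knot_invariant(self, kind, expected):
        """The per-diagram value equals the knot's second Vassiliev invariant
        in every generic projection, and matches the independent Polyak-Viro
        basepoint count on the same diagram."""
        c = make_knot(kind, 61, self_check=False)
        rng = np.random.default_rng(42)
        seen = 0
        while seen < 10:
            direction = top.sample_directions(1, rng)[0]
            try:
                d = top.project_diagram(c, direction=direction)
            except top.DegenerateProjectionError:
                continue
            val = top.diagram_v2(d)
            assert val == pytest.approx(expected, abs=1e-9)
            assert polyak_viro_v2(d, c.n_edges) == pytest.approx(val, abs=1e-9)
            # basepoint independence of the oracle itself
            assert polyak_viro_v2(d, c.n_edges, basepoint=17.41) == \
                pytest.approx(val, abs=1e-9)
            seen += 1


class TestVassiliev2:
    def test_convex_planar_curve_zero(self):
        th = np.linspace(0, 1.8 * np.pi, 14)
        pts = np.column_stack([np.cos(th), np.sin(th), np.zeros_like(th)])
        r = top.vassiliev2(PolygonalCurve(pts), n_projections=200, seed=1)
        assert r.value == 0.0 and r.stderr == 0.0

    def test_closed_trefoil_consistent(self):
        r = top.vassiliev2(make_knot("trefoil", 45), n_projections=150, seed=2)
        assert r.value == pytest.approx(1.0, abs=1e-9)
        assert r.stderr == 0.0

    def test_k21_canonical_and_sphere_average(self):
        k = make_k21_knotoid()
        d = top.project_diagram(k, direction=K21_CANONICAL_DIRECTION)
        assert top.diagram_v2(d) == 0.5
        r = top.vassiliev2(k, n_projections=800, seed=3)
        assert 0.0 < r.value < 0.5

    def test_seed_determinism(self):
        c = random_open_curve(15, seed=8)
        a = top.vassiliev2(c, n_projections=100, seed=11)
        b = top.vassiliev2(c, n_projections=100, seed=11)
        assert a.value == b.value and a.stderr == b.stderr

    def test_abs_value_mirror_invariant(self):
        c = make_knot("trefoil", 45)
        m = c.transformed(matrix=MIRROR)
        a = top.vassiliev2(c, n_projections=60, seed=4)
        b = top.vassiliev2(m, n_projections=60, seed=4)
        assert abs(a.value) == pytest.approx(abs(b.value), abs=1e-9)


class TestFragmentLinking:
    def test_blocks_match_direct_linking(self):
        c = random_open_curve(30, seed=77)
        fl = top.FragmentLinking(c)
        rng = np.random.default_rng(1)
        for _ in range(10):
            i0, i1 = sorted(rng.choice(15, 2, replace=False))
            j0, j1 = sorted(rng.choice(np.arange(16, 30), 2, replace=False))
            if i1 - i0 < 1 or j1 - j0 < 1:
                continue
            direct = top.gauss_linking(
                PolygonalCurve(c.vertices[i0:i1 + 1]),
                PolygonalCurve(c.vertices[j0:j1 + 1]))
            assert fl.linking(i0, i1, j0, j1) == pytest.approx(direct, abs=1e-10)
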