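"""Gauss linking integral, writhe, crossing diagrams and the second Vassiliev
measure for open and closed polygonal curves.

Conventions
-----------
* The linking number ``Lk`` of two oriented curves is the Gauss double
  integral, equal to the average over all projection directions of half the
  signed inter-crossing count of the diagram.
* The writhe ``Wr`` of one curve is the self-linking analogue, equal to the
  average signed self-crossing count over projections.
* Both are computed exactly, as a finite sum of per-segment-pair signed solid
  angles; projection-sampled estimators (`mc_linking`, `mc_writhe`) are
  provided as an independent route.
* The second Vassiliev measure ``v2`` is the sphere average of the per-diagram
  value: half the sum over *alternating* pairs of interleaved crossings of the
  product of their signs.  For closed curves the per-diagram value is already
  the (integer) second Vassiliev invariant; for open curves it depends on the
  direction and the sphere average is estimated by Monte Carlo.  Endpoints of
  open curves are left free (knotoid convention) -- no closure is ever added.
* Crossing signs follow the right-handed convention: over-strand along +x,
  under-strand along +y, viewed from +z, is a positive crossing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .curves import PolygonalCurve, CurveError

__all__ = [
    "gauss_linking", "writhe", "crossing_sign", "project_diagram",
    "diagram_v2", "vassiliev2", "Vassiliev2Result", "Crossing",
    "CrossingDiagram", "DegenerateProjectionError", "SingularityError",
    "mc_linking", "mc_writhe", "sample_directions", "pairwise_gauss_matrix",
    "FragmentLinking",
]

#: Relative tolerance below which a projected configuration is declared
#: non-generic (parallel projected edges, grazing intersections, depth ties)
#: and the direction is resampled.
GENERIC_EPS = 1e-12


class SingularityError(ValueError):
    """Curves share a point; the Gauss integrand is singular."""


class DegenerateProjectionError(RuntimeError):
    """Projection is non-generic; the caller should resample the direction."""


# ---------------------------------------------------------------------------
# Exact segment-pair Gauss integral
# ---------------------------------------------------------------------------

def _segment_pair_gauss(a0, a1, b0, b1):
    """Gauss double integral (1/4pi normalization) over segment pairs.

    All arguments are (..., 3) arrays of segment endpoints: segments a0->a1 on
    the first curve and b0->b1 on the second.  Returns the (...,) array of
    per-pair contributions: the signed solid angle subtended by the pair
    divided by 4pi.  Coplanar pairs contribute exactly 0.
    """
    r13 = b0 - a0
    r14 = b1 - a0
    r23 = b0 - a1
    r24 = b1 - a1

    n1 = np.cross(r13, r14)
    n2 = np.cross(r14, r24)
    n3 = np.cross(r24, r23)
    n4 = np.cross(r23, r13)

    def _unit(n):
        norm = np.linalg.norm(n, axis=-1, keepdims=True)
        return np.divide(n, norm, out=np.zeros_like(n), where=norm > 0)

    n1, n2, n3, n4 = _unit(n1), _unit(n2), _unit(n3), _unit(n4)

    def _asin_dot(x, y):
        return np.arcsin(np.clip(np.einsum("...i,...i->...", x, y), -1.0, 1.0))

    omega = (_asin_dot(n1, n2) + _asin_dot(n2, n3)
             + _asin_dot(n3, n4) + _asin_dot(n4, n1))
    sign = np.sign(np.einsum("...i,...i->...", np.cross(b1 - b0, a1 - a0), r13))
    return omega * sign / (4.0 * np.pi)


def _check_disjoint(c1: PolygonalCurve, c2: PolygonalCurve) -> None:
    d = c1.vertices[:, None, :] - c2.vertices[None, :, :]
    if np.any(np.einsum("ijk,ijk->ij", d, d) == 0.0):
        raise SingularityError("curves share a vertex; linking integral singular")


def gauss_linking(c1: PolygonalCurve, c2: PolygonalCurve) -> float:
    """Gauss linking integral of two disjoint oriented polygonal curves.

    Exact finite sum of per-segment-pair signed solid angles; equals the
    projection average of half the signed inter-crossing count.
    """
    _check_disjoint(c1, c2)
    a0, a1 = c1.edges()
    b0, b1 = c2.edges()
    g = _segment_pair_gauss(a0[:, None, :], a1[:, None, :],
                            b0[None, :, :], b1[None, :, :])
    return float(g.sum())


def writhe(c: PolygonalCurve) -> float:
    """Writhe of one oriented polygonal curve.

    Exact sum over non-adjacent segment pairs, scaled so that ``Wr`` equals the
    projection average of the signed self-crossing count.  Any planar curve has
    writhe exactly 0.
    """
    if len(c) < 3:
        raise CurveError("writhe needs at least 3 vertices")
    e0, e1 = c.edges()
    n = len(e0)
    i, j = np.triu_indices(n, k=2)
    if c.closed:
        keep = ~((i == 0) & (j == n - 1))
        i, j = i[keep], j[keep]
    if len(i) == 0:
        return 0.0
    g = _segment_pair_gauss(e0[i], e1[i], e0[j], e1[j])
    # Wr has 1/2pi normalization over the ordered off-diagonal domain, i.e.
    # twice the unordered 1/4pi sum.
    return float(2.0 * g.sum())


def pairwise_gauss_matrix(c: PolygonalCurve) -> np.ndarray:
    """(n_edges, n_edges) matrix of per-pair Gauss contributions of one curve.

    Entry (i, j) is the 1/4pi-normalized Gauss integral over edges i and j;
    the diagonal and adjacent pairs are 0.  Summing a block gives the linking
    number between the corresponding vertex-disjoint sub-curves, which makes
    whole linking matrices cheap via prefix sums (:class:`FragmentLinking`).
    """
    e0, e1 = c.edges()
    n = len(e0)
    G = np.zeros((n, n))
    i, j = np.triu_indices(n, k=2)
    if c.closed:
        keep = ~((i == 0) & (j == n - 1))
        i, j = i[keep], j[keep]
    g = _segment_pair_gauss(e0[i], e1[i], e0[j], e1[j])
    G[i, j] = g
    G[j, i] = g
    return G


class FragmentLinking:
    """O(1) linking numbers between vertex ranges of one open curve.

    Precomputes the pairwise edge Gauss matrix and its 2-D prefix sum; the
    linking number between the sub-curves spanning vertex index ranges
    [i0, i1] and [j0, j1] (inclusive, disjoint) is then a constant-time block
    sum.
    """

    def __init__(self, c: PolygonalCurve):
        if c.closed:
            raise CurveError("FragmentLinking applies to open curves")
        G = pairwise_gauss_matrix(c)
        self._S = np.zeros((G.shape[0] + 1, G.shape[1] + 1))
        self._S[1:, 1:] = np.cumsum(np.cumsum(G, axis=0), axis=1)
        self.n_vertices = len(c)

    def _block(self, r0, r1, c0, c1):
        S = self._S
        return S[r1 + 1, c1 + 1] - S[r0, c1 + 1] - S[r1 + 1, c0] + S[r0, c0]

    def linking(self, i0: int, i1: int, j0: int, j1: int) -> float:
        """Lk between vertices [i0, i1] and [j0, j1] (0-based, inclusive)."""
        if not (0 <= i0 < i1 < self.n_vertices and 0 <= j0 < j1 < self.n_vertices):
            raise CurveError("fragment needs >= 2 vertices inside the curve")
        # vertices [a, b] span edges [a, b-1]
        return float(self._block(i0, i1 - 1, j0, j1 - 1))


# ---------------------------------------------------------------------------
# Crossing diagrams
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Crossing:
    """One transversal double point of a projected diagram.

    ``over_edge``/``under_edge`` index edges of the projected configuration;
    for two-curve diagrams, edges of the second curve are offset by the edge
    count of the first.  ``over_pos``/``under_pos`` are the arc-length-order
    parameters (edge index + in-edge fraction) of the two preimage points.
    """

    over_edge: int
    under_edge: int
    sign: int
    over_pos: float
    under_pos: float


@dataclass(frozen=True)
class CrossingDiagram:
    """All crossings of a generic projection of one or two curves."""

    direction: np.ndarray
    crossings: tuple[Crossing, ...]
    two_curves: bool = False
    n_edges_first: int = 0

    def signed_count(self) -> int:
        return int(sum(c.sign for c in self.crossings))


def crossing_sign(over_vec, under_vec, direction) -> int:
    """Sign of a crossing from the 3-D strand direction vectors.

    +1 (right-handed) when the over-strand, under-strand and viewing direction
    form a positively oriented frame: over along +x and under along +y viewed
    from +z is positive.  Raises :class:`DegenerateProjectionError` when the
    projected strands are parallel.
    """
    o = np.asarray(over_vec, float)
    u = np.asarray(under_vec, float)
    d = np.asarray(direction, float)
    s = float(np.cross(o, u) @ d)
    scale = np.linalg.norm(o) * np.linalg.norm(u) * np.linalg.norm(d)
    if abs(s) <= GENERIC_EPS * scale:
        raise DegenerateProjectionError("projected strands are parallel")
    return 1 if s > 0 else -1


def _plane_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    a = np.array([1.0, 0.0, 0.0])
    if abs(d @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, a)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def _diagram_arrays(curves, direction, eps=GENERIC_EPS):
    """Crossing data of the projection of one or two curves.

    Returns (pos_i, pos_j, sign, over_is_i, edge_i, edge_j) arrays where i/j
    index the global edge list (second curve offset).  Raises
    DegenerateProjectionError for non-generic projections.
    """
    direction = np.asarray(direction, float)
    nrm = np.linalg.norm(direction)
    if not np.isclose(nrm, 1.0, atol=1e-9):
        raise CurveError("projection direction must be unit-norm")
    u, v = _plane_basis(direction)

    starts, ends, offsets = [], [], []
    off = 0
    for c in curves:
        e0, e1 = c.edges()
        starts.append(e0)
        ends.append(e1)
        offsets.append(off)
        off += len(e0)
    e0 = np.concatenate(starts)
    e1 = np.concatenate(ends)
    n_first = len(starts[0])

    p0 = np.stack([e0 @ u, e0 @ v], axis=1)
    p1 = np.stack([e1 @ u, e1 @ v], axis=1)
    depth0 = e0 @ direction
    depth1 = e1 @ direction
    scale = max(np.ptp(p0), np.ptp(p1), 1.0)

    n = len(e0)
    if len(curves) == 1:
        i, j = np.triu_indices(n, k=2)
        if curves[0].closed:
            keep = ~((i == 0) & (j == n - 1))
            i, j = i[keep], j[keep]
    else:
        i, j = np.meshgrid(np.arange(n_first), np.arange(n_first, n),
                           indexing="ij")
        i, j = i.ravel(), j.ravel()

    def _cross2(a, b):
        return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]

    d_i = p1[i] - p0[i]
    d_j = p1[j] - p0[j]
    denom = _cross2(d_i, d_j)
    w = p0[j] - p0[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = _cross2(w, d_j) / denom       # parameter on edge i
        s = _cross2(w, d_i) / denom       # parameter on edge j
    parallel = np.abs(denom) <= eps * scale * scale
    hit = (~parallel) & (t > 0) & (t < 1) & (s > 0) & (s < 1)
    # grazing intersections (parameter at an endpoint) are non-generic
    margin = 1e-9
    if np.any((~parallel)
              & (np.minimum(np.abs(t), np.abs(1 - t)) < margin)
              & (s > -margin) & (s < 1 + margin)):
        raise DegenerateProjectionError("crossing at an edge endpoint")
    if np.any((~parallel)
              & (np.minimum(np.abs(s), np.abs(1 - s)) < margin)
              & (t > -margin) & (t < 1 + margin)):
        raise DegenerateProjectionError("crossing at an edge endpoint")
    # collinear projected edges are degenerate only if their images overlap;
    # disjoint collinear images (e.g. segments on one 3-D line) never cross
    collinear = parallel & (np.abs(_cross2(w, d_i)) <= eps * scale * scale)
    if np.any(collinear):
        ci = np.flatnonzero(collinear)
        for k in ci:
            axis = d_i[k] / np.linalg.norm(d_i[k])
            a_lo, a_hi = sorted((p0[i[k]] @ axis, p1[i[k]] @ axis))
            b_lo, b_hi = sorted((p0[j[k]] @ axis, p1[j[k]] @ axis))
            if min(a_hi, b_hi) - max(a_lo, b_lo) > -eps * scale:
                raise DegenerateProjectionError("projected edges overlap")

    i, j, t, s = i[hit], j[hit], t[hit], s[hit]
    denom = denom[hit]
    if len(i) == 0:
        empty = np.empty(0)
        return empty, empty, empty.astype(int), empty.astype(bool), i, j, n_first

    zi = depth0[i] + t * (depth1[i] - depth0[i])
    zj = depth0[j] + s * (depth1[j] - depth0[j])
    if np.any(np.abs(zi - zj) <= eps * scale):
        raise DegenerateProjectionError("depth tie at a crossing")
    over_is_i = zi > zj

    cross_z = denom   # 2-D cross of projected tangents, ordered (i, j)
    # sign((tan_over x tan_under) . xi) equals sign of the 2-D cross product
    # of the projected tangents, ordered over-first.
    sgn = np.where(over_is_i, np.sign(cross_z), -np.sign(cross_z)).astype(int)

    pos_i = i + t
    pos_j = j + s
    return pos_i, pos_j, sgn, over_is_i, i, j, n_first


def project_diagram(c1: PolygonalCurve,
                    c2: PolygonalCurve | None = None,
                    direction: Sequence[float] = (0.0, 0.0, 1.0)) -> CrossingDiagram:
    """Crossing diagram of the projection of one or two curves.

    Self-diagrams exclude adjacent edges; two-curve diagrams contain only
    inter-curve crossings.  Over/under is decided by depth along ``direction``
    (the strand closer to the viewer at +direction is over).  Non-generic
    projections raise :class:`DegenerateProjectionError`.
    """
    curves = (c1,) if c2 is None else (c1, c2)
    direction = np.asarray(direction, float)
    pos_i, pos_j, sgn, over_is_i, i, j, n_first = _diagram_arrays(curves, direction)
    crossings = []
    for k in range(len(sgn)):
        if over_is_i[k]:
            crossings.append(Crossing(int(i[k]), int(j[k]), int(sgn[k]),
                                      float(pos_i[k]), float(pos_j[k])))
        else:
            crossings.append(Crossing(int(j[k]), int(i[k]), int(sgn[k]),
                                      float(pos_j[k]), float(pos_i[k])))
    return CrossingDiagram(direction=direction, crossings=tuple(crossings),
                           two_curves=c2 is not None, n_edges_first=n_first)


# ---------------------------------------------------------------------------
# Second Vassiliev measure
# ---------------------------------------------------------------------------

def _v2_from_arrays(pos_i, pos_j, sgn, over_is_i) -> float:
    """Half the sum over alternating interleaved crossing pairs of the product
    of signs, given per-crossing preimage positions along the curve."""
    m = len(sgn)
    if m < 2:
        return 0.0
    a = np.minimum(pos_i, pos_j)           # earlier preimage of each crossing
    b = np.maximum(pos_i, pos_j)
    # is the earlier preimage on the over-strand?
    first_is_over = np.where(pos_i < pos_j, over_is_i, ~over_is_i)
    # pairs (p, q): interleaved iff a_p < a_q < b_p < b_q (either order)
    A1, A2 = a[:, None], a[None, :]
    B1, B2 = b[:, None], b[None, :]
    interleaved = (A1 < A2) & (A2 < B1) & (B1 < B2)
    # alternating: of the four points j1<j2<j3<j4, j1 (=a_p) and j2 (=a_q)
    # lie on opposite strand roles (one over, one under)
    alternating = first_is_over[:, None] != first_is_over[None, :]
    prod = sgn[:, None] * sgn[None, :]
    total = prod[interleaved & alternating].sum()
    # each unordered pair counted once since interleaved fixes the order p<q
    return 0.5 * float(total)


def diagram_v2(d: CrossingDiagram) -> float:
    """Per-diagram second Vassiliev value of a single-curve diagram.

    Half the sum over ordered four-tuples of points along the curve forming
    two interleaved crossings with alternating over/under pattern of the
    product of the two crossing signs.  For a generic diagram of a closed
    curve this is the integer second Vassiliev invariant.
    """
    if d.two_curves:
        raise CurveError("diagram_v2 applies to single-curve diagrams")
    if len(d.crossings) < 2:
        return 0.0
    pos_i = np.array([c.over_pos for c in d.crossings])
    pos_j = np.array([c.under_pos for c in d.crossings])
    sgn = np.array([c.sign for c in d.crossings])
    over_is_i = np.ones(len(sgn), dtype=bool)
    return _v2_from_arrays(pos_i, pos_j, sgn, over_is_i)


def sample_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """n unit vectors sampled uniformly on the sphere."""
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


@dataclass(frozen=True)
class Vassiliev2Result:
    """Monte-Carlo estimate of the second Vassiliev measure.

    ``value`` is the mean per-diagram value over ``n_projections`` uniformly
    sampled directions, ``stderr`` its Monte-Carlo standard error.  The seed,
    the per-projection values and the sampled directions are retained for
    reproducibility and for knotoid-perspective queries.
    """

    value: float
    stderr: float
    n_projections: int
    seed: int
    n_degenerate: int = 0
    per_projection: np.ndarray | None = field(default=None, repr=False)
    directions: np.ndarray | None = field(default=None, repr=False)

    def __float__(self) -> float:
        return self.value


def vassiliev2(c: PolygonalCurve, n_projections: int = 1000,
               seed: int = 0, keep_values: bool = False) -> Vassiliev2Result:
    """Second Vassiliev measure: sphere average of the per-diagram value.

    Directions are sampled uniformly on the sphere with the given seed;
    degenerate projections are resampled (and counted).  Returns the mean, its
    Monte-Carlo standard error and, optionally, the per-projection values.
    """
    if n_projections < 1:
        raise CurveError("n_projections must be >= 1")
    rng = np.random.default_rng(seed)
    values = np.empty(n_projections)
    dirs = np.empty((n_projections, 3))
    n_degenerate = 0
    filled = 0
    while filled < n_projections:
        batch = sample_directions(n_projections - filled, rng)
        for d in batch:
            try:
                pos_i, pos_j, sgn, over_is_i, *_ = _diagram_arrays((c,), d)
            except DegenerateProjectionError:
                n_degenerate += 1
                continue
            values[filled] = _v2_from_arrays(pos_i, pos_j, sgn, over_is_i)
            dirs[filled] = d
            filled += 1
    stderr = float(values.std(ddof=1) / np.sqrt(n_projections)) \
        if n_projections > 1 else np.inf
    return Vassiliev2Result(
        value=float(values.mean()), stderr=stderr,
        n_projections=n_projections, seed=seed, n_degenerate=n_degenerate,
        per_projection=values.copy() if keep_values else None,
        directions=dirs.copy() if keep_values else None)


# ---------------------------------------------------------------------------
# Projection-sampled estimators (independent route to Lk and Wr)
# ---------------------------------------------------------------------------

def _signed_crossing_counts(e0, e1, pairs_i, pairs_j, directions):
    """Signed crossing count per direction for the given edge pairs.

    Vectorized over directions x pairs.  The sign of a crossing between edges
    i and j is sign((t_i x t_j) . (p_i - p_j)) at the double point, i.e. the
    2-D orientation of the projected tangents times the sign of the depth
    difference; this form is symmetric in the strand labels.
    """
    n_dir = len(directions)
    out = np.zeros(n_dir)
    # orthonormal bases per direction
    a = np.tile(np.array([1.0, 0.0, 0.0]), (n_dir, 1))
    swap = np.abs(directions[:, 0]) > 0.9
    a[swap] = [0.0, 1.0, 0.0]
    u = np.cross(directions, a)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(directions, u)

    # per-pair 3-D quantities, gathered once: edge vectors and offsets
    Ai = (e1 - e0)[pairs_i]            # (P, 3)
    Aj = (e1 - e0)[pairs_j]
    W = e0[pairs_j] - e0[pairs_i]
    # cache-sized chunks: large temporaries thrash memory bandwidth
    n_pairs = max(len(pairs_i), 1)
    chunk = max(16, int(1.5e5 // n_pairs))
    for lo in range(0, n_dir, chunk):
        U = u[lo:lo + chunk].T; V = v[lo:lo + chunk].T
        D = directions[lo:lo + chunk].T
        diu = Ai @ U; div = Ai @ V          # (P, D) via BLAS
        dju = Aj @ U; djv = Aj @ V
        wu = W @ U; wv = W @ V
        denom = diu * djv
        denom -= div * dju
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (wu * djv - wv * dju) / denom
            s = (wu * div - wv * diu) / denom
            hit = (np.abs(denom) > 0) & (t > 0) & (t < 1) & (s > 0) & (s < 1)
            # depth difference at the double point: -W.xi + t*Ai.xi - s*Aj.xi
            dz = t * (Ai @ D)
            dz -= s * (Aj @ D)
            dz -= W @ D
            sgn = np.sign(denom) * np.sign(dz)
        out[lo:lo + chunk] = np.where(hit, sgn, 0.0).sum(axis=0)
    return out


def mc_linking(c1: PolygonalCurve, c2: PolygonalCurve,
               n_directions: int = 100_000, seed: int = 0):
    """Monte-Carlo projection estimate of Lk: mean over sampled directions of
    half the signed inter-crossing count.  Returns (estimate, stderr)."""
    rng = np.random.default_rng(seed)
    dirs = sample_directions(n_directions, rng)
    a0, a1 = c1.edges()
    b0, b1 = c2.edges()
    e0 = np.concatenate([a0, b0])
    e1 = np.concatenate([a1, b1])
    i, j = np.meshgrid(np.arange(len(a0)), len(a0) + np.arange(len(b0)),
                       indexing="ij")
    counts = 0.5 * _signed_crossing_counts(e0, e1, i.ravel(), j.ravel(), dirs)
    return float(counts.mean()), float(counts.std(ddof=1) / np.sqrt(n_directions))


def mc_writhe(c: PolygonalCurve, n_directions: int = 100_000, seed: int = 0):
    """Monte-Carlo projection estimate of Wr: mean signed self-crossing count
    over sampled directions.  Returns (estimate, stderr)."""
    rng = np.random.default_rng(seed)
    dirs = sample_directions(n_directions, rng)
    e0, e1 = c.edges()
    n = len(e0)
    i, j = np.triu_indices(n, k=2)
    if c.closed:
        keep = ~((i == 0) & (j == n - 1))
        i, j = i[keep], j[keep]
    counts = _signed_crossing_counts(e0, e1, i, j, dirs)
    return float(counts.mean()), float(counts.std(ddof=1) / np.sqrt(n_directions))
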