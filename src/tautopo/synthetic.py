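"""Generators of curves and structure files with known topology.

Everything the test-suite and the worked examples need can be generated here:
helices with prescribed handedness, closed polygonal knots (trefoil, figure-8,
5_2) that self-verify their type, the standard two-crossing K2_1 knotoid, and
synthetic cross-beta fibril PDB files (stacked, twisted rungs of a fold curve
with side-chain pseudo-atoms placed by a known rule).

All generators are deterministic for a given parameter set and seed.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .curves import PolygonalCurve
from . import topology

__all__ = [
    "make_helix", "make_knot", "make_unknot", "make_k21_knotoid",
    "K21_CANONICAL_DIRECTION", "make_braid_closure", "default_fold_curve",
    "make_synthetic_fibril", "random_open_curve",
]

#: The standard 3-strand braid word for the 5_2 knot (s1^3 s2 s1^-1 s2);
#: its closure self-checks via the second Vassiliev invariant a2(5_2) = 2.
FIVE_TWO_BRAID = (1, 1, 1, 2, -1, 2)

#: Projection direction along which :func:`make_k21_knotoid` realizes the
#: standard two-crossing K2_1 knotoid diagram.
K21_CANONICAL_DIRECTION = np.array([0.0, 0.0, 1.0])


def make_helix(turns: float, radius: float = 2.3, pitch: float = 5.4,
               points_per_turn: int = 20, handedness: str = "right") -> PolygonalCurve:
    """Open discretized circular helix.

    ``pitch`` is the rise per full turn (Angstrom); ``handedness`` is
    ``"right"`` or ``"left"``.
    """
    if turns <= 0 or radius <= 0:
        raise ValueError("turns and radius must be positive")
    if handedness not in ("right", "left"):
        raise ValueError("handedness must be 'right' or 'left'")
    n = max(2, int(math.ceil(turns * points_per_turn)) + 1)
    theta = np.linspace(0.0, 2.0 * np.pi * turns, n)
    sgn = 1.0 if handedness == "right" else -1.0
    pts = np.column_stack([
        radius * np.cos(theta),
        sgn * radius * np.sin(theta),
        pitch * theta / (2.0 * np.pi),
    ])
    return PolygonalCurve(pts, label=f"helix:{handedness}:{turns}")


def make_unknot(n_vertices: int = 32, radius: float = 5.0) -> PolygonalCurve:
    """Closed planar polygon (round unknot)."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta),
                           np.zeros(n_vertices)])
    return PolygonalCurve(pts, closed=True, label="unknot")


def _trig_knot(n_vertices: int, fx, fy, fz, label: str) -> PolygonalCurve:
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    pts = np.column_stack([fx(t), fy(t), fz(t)])
    return PolygonalCurve(pts, closed=True, label=label)


def make_braid_closure(word: Sequence[int], n_strands: int,
                       height: float = 0.7) -> PolygonalCurve:
    """Closed polygonal curve realizing the trace closure of a braid word.

    ``word`` lists Artin generators: letter ``+i`` swaps strand positions
    ``i-1``/``i`` (1-based ``i``) with the strand moving left-to-right passing
    over; ``-i`` passes it under.  The braid runs upward in the xy-plane with
    over/under realized by +-``height`` displacements in z; closure arcs
    return from each top position to the same bottom position at distinct
    depths behind the diagram.  The closure permutation must be a single
    cycle (one component).
    """
    if not word:
        raise ValueError("empty braid word")
    if any(abs(l) < 1 or abs(l) >= n_strands for l in word):
        raise ValueError("braid letters must satisfy 1 <= |letter| < n_strands")
    h = float(height)
    T = len(word)
    perm = list(range(n_strands))          # perm[pos] = strand at position pos
    paths: dict[int, list[tuple[float, float, float]]] = {
        s: [(float(s), 0.0, 0.0)] for s in range(n_strands)}
    pos_of = {s: s for s in range(n_strands)}
    for t, letter in enumerate(word):
        i = abs(letter) - 1
        s_l, s_r = perm[i], perm[i + 1]
        z_l = h if letter > 0 else -h      # left-to-right strand over iff +
        paths[s_l].append((i + 0.5, t + 0.5, z_l))
        paths[s_r].append((i + 0.5, t + 0.5, -z_l))
        paths[s_l].append((i + 1.0, t + 1.0, 0.0))
        paths[s_r].append((float(i), t + 1.0, 0.0))
        perm[i], perm[i + 1] = s_r, s_l
        pos_of[s_l], pos_of[s_r] = i + 1, i
    for s in range(n_strands):             # bring every strand to the top
        paths[s].append((float(pos_of[s]), float(T), 0.0))

    # single component iff the map strand -> its top position is an n-cycle
    cycle = [0]
    while pos_of[cycle[-1]] != cycle[0]:
        cycle.append(pos_of[cycle[-1]])
    if len(cycle) != n_strands:
        raise ValueError("braid closure has more than one component")

    verts: list[tuple[float, float, float]] = []
    pos = 0
    for _ in range(n_strands):
        # strand s starts at bottom position s
        strand = pos
        pts = paths[strand]
        verts.extend(pts if not verts else pts[1:] if pts[0] == verts[-1] else pts)
        top_pos = pos_of[strand]
        depth = -(1.5 + 1.2 * top_pos) * max(h, 0.5)
        verts.extend([
            (float(top_pos), T + 0.6, depth),
            (n_strands + 0.6, T + 0.6, depth),
            (n_strands + 0.6, -0.6, depth),
            (float(top_pos), -0.6, depth),
        ])
        pos = top_pos
        if pos != 0:
            verts.append((float(pos), 0.0, 0.0))
    arr = np.asarray(verts)
    # drop exactly-repeated consecutive vertices, if any
    keep = np.ones(len(arr), bool)
    keep[1:] = np.linalg.norm(np.diff(arr, axis=0), axis=1) > 1e-12
    if np.linalg.norm(arr[0] - arr[-1]) <= 1e-12:
        keep[-1] = False
    return PolygonalCurve(arr[keep], closed=True,
                          label=f"braid:{list(word)}")


_KNOT_BUILDERS: dict[str, Callable[[int], PolygonalCurve]] = {
    "trefoil": lambda n: _trig_knot(
        n,
        lambda t: (2.0 + np.cos(3 * t)) * np.cos(2 * t),
        lambda t: (2.0 + np.cos(3 * t)) * np.sin(2 * t),
        lambda t: -np.sin(3 * t),
        "trefoil"),
    "figure8": lambda n: _trig_knot(
        n,
        lambda t: (2.0 + np.cos(2 * t)) * np.cos(3 * t),
        lambda t: (2.0 + np.cos(2 * t)) * np.sin(3 * t),
        lambda t: np.sin(4 * t),
        "figure8"),
    "5_2": lambda n: make_braid_closure(FIVE_TWO_BRAID, 3),
    "unknot": lambda n: make_unknot(n),
}

#: Expected per-diagram second Vassiliev invariant of each generated knot,
#: used by the generator self-check.
KNOT_V2 = {"trefoil": 1.0, "figure8": -1.0, "5_2": 2.0, "unknot": 0.0}


def make_knot(kind: str, n_vertices: int = 60, self_check: bool = True,
              check_seed: int = 7) -> PolygonalCurve:
    """Closed polygonal realization of a standard knot.

    ``kind`` is one of ``trefoil``, ``figure8``, ``5_2`` or ``unknot``.  A
    too-coarse discretization could change the knot type, so by default the
    generator self-checks: the per-diagram second Vassiliev value must equal
    the expected invariant and be constant across 10 random generic
    projections.
    """
    if kind not in _KNOT_BUILDERS:
        raise ValueError(f"unknown knot kind {kind!r}")
    min_vertices = {"trefoil": 9, "figure8": 12, "5_2": 15, "unknot": 3}
    if kind in ("trefoil", "figure8", "unknot") and n_vertices < min_vertices[kind]:
        raise ValueError(f"{kind} needs >= {min_vertices[kind]} vertices")
    c = _KNOT_BUILDERS[kind](n_vertices)
    if self_check:
        rng = np.random.default_rng(check_seed)
        expected = KNOT_V2[kind]
        got = 0
        while got < 10:
            d = topology.sample_directions(1, rng)[0]
            try:
                val = topology.diagram_v2(topology.project_diagram(c, direction=d))
            except topology.DegenerateProjectionError:
                continue
            if not math.isclose(val, expected, abs_tol=1e-9):
                raise RuntimeError(
                    f"{kind} discretization failed self-check: diagram value "
                    f"{val} != {expected}")
            got += 1
    return c


def make_k21_knotoid() -> PolygonalCurve:
    """Open polygonal curve realizing the K2_1 knotoid.

    Projected along :data:`K21_CANONICAL_DIRECTION` (+z) it yields the
    standard two-crossing K2_1 diagram: one interleaved alternating pair of
    equal-sign crossings, so the per-diagram second Vassiliev value of the
    canonical projection is exactly 0.5.
    """
    verts = np.array([
        [-3.0, 0.0, 0.0],
        [1.0, 0.0, 0.0],
        [1.0, 2.0, 0.0],
        [-1.0, 2.0, 1.0],
        [-1.0, -1.0, 1.0],
        [2.0, -1.0, 0.0],
        [0.5, 1.5, -1.0],
    ])
    return PolygonalCurve(verts, label="K2_1")


def random_open_curve(n_vertices: int, seed: int, scale: float = 1.0) -> PolygonalCurve:
    """Seeded random open polygonal curve (Gaussian steps), for fixtures."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_vertices - 1, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    pts = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)]) * scale
    return PolygonalCurve(pts, label=f"random:{seed}")


# ---------------------------------------------------------------------------
# Synthetic fibrils
# ---------------------------------------------------------------------------

def default_fold_curve(n_residues: int = 71, spacing: float = 3.8) -> PolygonalCurve:
    """A planar C-shaped fold in the xy-plane with CA-like vertex spacing,
    emulating the flat cross-beta fold of one fibril rung."""
    theta = np.linspace(-0.75 * np.pi, 0.75 * np.pi, n_residues)
    r = spacing * (n_residues - 1) / (1.5 * np.pi)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta),
                           np.zeros(n_residues)])
    return PolygonalCurve(pts, label="C-fold")


def _local_frames(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex orthonormal (normal, binormal) pair transverse to the chain."""
    tang = np.gradient(vertices, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    ref = np.array([0.0, 0.0, 1.0])
    n = np.cross(tang, ref)
    bad = np.linalg.norm(n, axis=1) < 1e-8
    n[bad] = np.cross(tang[bad], [1.0, 0.0, 0.0])
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    b = np.cross(tang, n)
    b /= np.linalg.norm(b, axis=1, keepdims=True)
    return n, b


def sidechain_turns_rule(n_turns: float, handedness: str = "right"
                         ) -> Callable[[np.ndarray], np.ndarray]:
    """Side-chain direction rule: a frame rotating a fixed total number of
    full turns about the backbone from one end to the other, so the push-off
    winds ``n_turns`` times around the chain (construction ground truth for
    ribbon-linking recovery)."""
    sgn = 1.0 if handedness == "right" else -1.0

    def rule(vertices: np.ndarray) -> np.ndarray:
        m = len(vertices)
        nrm, bin_ = _local_frames(vertices)
        phi = sgn * 2.0 * np.pi * n_turns * np.arange(m) / (m - 1)
        return np.cos(phi)[:, None] * nrm + np.sin(phi)[:, None] * bin_

    return rule


def planar_sidechain_rule(vertices: np.ndarray) -> np.ndarray:
    """All side chains point along +z (no twist about the backbone)."""
    d = np.zeros_like(vertices)
    d[:, 2] = 1.0
    return d


def make_synthetic_fibril(path, n_rungs: int = 3, rise: float = 4.7,
                          twist_deg: float = -1.0,
                          fold_curve: PolygonalCurve | None = None,
                          sidechain_rule=None,
                          first_residue: int = 1,
                          glycine_at: Sequence[int] = (),
                          seed: int = 0,
                          write_manifest: bool = False) -> Path:
    """Write a synthetic fibril as a PDB file.

    Each rung is one chain: the fold curve as CA atoms plus two side-chain
    pseudo-atoms per residue (CB at 1.5 A and CG at 4.2 A from the CA along
    the direction given by ``sidechain_rule``), so the farthest-heavy-atom
    push-off rule selects CG.  Residues listed in ``glycine_at`` (author
    numbering) are written as glycine with no side-chain atoms.  Successive
    rungs are related by a rise along +z and a twist about the z axis through
    the fold centroid, emulating cross-beta stacking (default 4.7 A rise,
    -1 degree twist per rung).
    """
    if n_rungs < 1:
        raise ValueError("need at least one rung")
    fold = fold_curve if fold_curve is not None else default_fold_curve()
    rule = sidechain_rule if sidechain_rule is not None else planar_sidechain_rule
    ca = fold.vertices
    dirs = rule(ca)
    centroid = ca.mean(axis=0)
    glycine_at = set(int(g) for g in glycine_at)

    import gemmi
    st = gemmi.Structure()
    st.name = "synthetic fibril"
    model = gemmi.Model("1")
    chain_ids = [chr(ord("A") + k) for k in range(n_rungs)]
    ang = math.radians(twist_deg)
    for k, cid in enumerate(chain_ids):
        cth, sth = math.cos(k * ang), math.sin(k * ang)
        rot = np.array([[cth, -sth, 0.0], [sth, cth, 0.0], [0.0, 0.0, 1.0]])
        shift = centroid + np.array([0.0, 0.0, k * rise])
        chain = gemmi.Chain(cid)
        for idx in range(len(ca)):
            resnum = first_residue + idx
            is_gly = resnum in glycine_at
            res = gemmi.Residue()
            res.name = "GLY" if is_gly else "UNK"
            res.seqid = gemmi.SeqId(resnum, " ")
            positions = [("CA", ca[idx])]
            if not is_gly:
                positions.append(("CB", ca[idx] + 1.5 * dirs[idx]))
                positions.append(("CG", ca[idx] + 4.2 * dirs[idx]))
            for name, pos in positions:
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element("C")
                p = rot @ (pos - centroid) + shift
                atom.pos = gemmi.Position(*p)
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    st.write_pdb(str(path))
    if write_manifest:
        manifest = {
            "n_rungs": n_rungs, "rise": rise, "twist_deg": twist_deg,
            "n_residues": len(ca), "first_residue": first_residue,
            "glycine_at": sorted(glycine_at), "seed": seed,
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))
    return path
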