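"""Fragment-level topology: repeat-pairwise linking, sign tuples, the
residue-resolved linking matrix and its rendered fingerprint, and knotoid
perspective detection.

The linking matrix of a filament with first residue K and last residue N has,
for i < j, the entry a[i, j] = Lk(p_{K,i-1}, p_{i,j}) (the fragment from i to
j against the part of the chain before it) and a[j, i] = Lk(p_{i,j},
p_{j+1,N}) (the same fragment against the part after it), where p_{k,l} is
the sub-curve from residue k to residue l inclusive.  Rendered as a signed
colour map this is the filament's linking fingerprint.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .curves import CurveError, FilamentModel, PolygonalCurve, subcurve
from .topology import FragmentLinking, Vassiliev2Result, gauss_linking, vassiliev2

__all__ = [
    "REPEAT_PAIRS", "MAIN_PAIRS", "EXTRA_PAIRS", "RepeatLinkTable",
    "SignTuple", "repeat_linking", "sign_tuple", "tuple_distance",
    "LinkingMatrix", "linking_matrix", "render_fingerprint", "KnotoidFlag",
    "knotoid_flag",
]

#: The repeat/C-terminal pairs reported for every filament (R1-R2 is not
#: reported; R1 pairs are ND for all 4R folds).
MAIN_PAIRS: tuple[tuple[str, str], ...] = (
    ("R2", "R3"), ("R2", "R4"), ("R2", "C"),
    ("R3", "R4"), ("R3", "C"), ("R4", "C"),
)
#: Extra pairs defined only when R1 is part of the ordered core (3R folds).
EXTRA_PAIRS: tuple[tuple[str, str], ...] = (
    ("R1", "R3"), ("R1", "R4"), ("R1", "C"),
)
REPEAT_PAIRS = EXTRA_PAIRS + MAIN_PAIRS


@dataclass(frozen=True)
class RepeatLinkTable:
    """Linking numbers between repeat-region sub-curves of one filament.

    ``values`` maps each pair in :data:`REPEAT_PAIRS` to the Gauss linking
    number of the two CA sub-curves, or NaN (ND) when either region is not
    resolved.  The relation is symmetric, so only one orientation is stored.
    """

    filament_id: str
    values: dict[tuple[str, str], float]

    def __getitem__(self, pair: tuple[str, str]) -> float:
        if pair in self.values:
            return self.values[pair]
        return self.values[(pair[1], pair[0])]

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["pair", "linking"])
            for (a, b), v in self.values.items():
                w.writerow([f"{a}-{b}", "ND" if np.isnan(v) else f"{v:.6g}"])


def repeat_linking(f: FilamentModel) -> RepeatLinkTable:
    """Gauss linking number between the CA sub-curves of each repeat pair.

    Pairs involving a region that is absent from the ordered core (or resolved
    with fewer than 2 residues) are ND.
    """
    values: dict[tuple[str, str], float] = {}
    curves: dict[str, PolygonalCurve | None] = {}
    for r in f.repeats:
        if r.name == "pre-R1":
            continue
        lo = max(r.start, f.first_residue)
        hi = min(r.end, f.last_residue)
        try:
            curves[r.name] = subcurve(f, lo, hi)
        except CurveError:
            curves[r.name] = None
    for a, b in REPEAT_PAIRS:
        ca, cb = curves.get(a), curves.get(b)
        values[(a, b)] = (gauss_linking(ca, cb)
                         if ca is not None and cb is not None else float("nan"))
    return RepeatLinkTable(filament_id=f.backbone.label, values=values)


@dataclass(frozen=True)
class SignTuple:
    """Signs of the repeat-pair linking numbers of one filament.

    ``main`` holds the six signs (sigma_lk(R2,R3), sigma_lk(R2,R4),
    sigma_lk(R2,C), sigma_lk(R3,R4), sigma_lk(R3,C), sigma_lk(R4,C));
    ``extra`` the optional three R1 signs (sigma_lk(R1,R3), sigma_lk(R1,R4),
    sigma_lk(R1,C)).  Entries are +1, -1 or None (ND); an exactly-zero
    linking value maps to ND.
    """

    main: tuple[int | None, ...]
    extra: tuple[int | None, ...]

    def __str__(self) -> str:
        sym = {1: "+", -1: "-", None: "ND"}
        s = "(" + ",".join(sym[x] for x in self.main) + ")"
        if any(x is not None for x in self.extra):
            s += "+(" + ",".join(sym[x] for x in self.extra) + ")"
        return s


def sign_tuple(t: RepeatLinkTable) -> SignTuple:
    """Elementwise sign extraction from a repeat linking table."""
    def sig(v: float) -> int | None:
        if np.isnan(v) or v == 0.0:
            return None
        return 1 if v > 0 else -1

    return SignTuple(
        main=tuple(sig(t[p]) for p in MAIN_PAIRS),
        extra=tuple(sig(t[p]) for p in EXTRA_PAIRS),
    )


def tuple_distance(a: SignTuple, b: SignTuple) -> int:
    """Hamming distance between sign tuples (ND-padded).

    ND against a sign counts as a difference; ND against ND as equal.
    """
    d = 0
    for x, y in zip(a.main + a.extra, b.main + b.extra):
        d += int(x != y)
    return d


@dataclass(frozen=True)
class LinkingMatrix:
    """Residue-indexed fragment linking matrix of one filament.

    ``matrix[r, c]`` for r < c is the fragment-vs-preceding linking
    a_{i,j}; for r > c the fragment-vs-following linking a_{j,i}.  Entries
    whose defining fragment has fewer than 2 vertices are NaN, as is the
    diagonal.  ``residues`` labels the rows/columns (author numbering of the
    retained, possibly strided, vertices).
    """

    filament_id: str
    residues: np.ndarray
    matrix: np.ndarray

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["residue"] + [str(r) for r in self.residues])
            for r, row in zip(self.residues, self.matrix):
                w.writerow([str(r)] + [("ND" if np.isnan(v) else f"{v:.6g}")
                                       for v in row])


def linking_matrix(f: FilamentModel, stride: int = 1) -> LinkingMatrix:
    """The linking matrix of a filament (one row/column per retained residue).

    Each defined entry equals a direct Gauss linking evaluation on the two
    fragments; computation uses a 2-D prefix sum over the pairwise edge Gauss
    matrix, so the full matrix costs little more than one writhe evaluation.
    ``stride`` keeps every stride-th residue (for quick previews).
    """
    if f.n_residues < 4:
        raise CurveError("linking matrix needs at least 4 residues")
    fl = FragmentLinking(f.backbone)
    n = f.n_residues
    S = fl._S
    idx = np.arange(0, n, stride)
    m = len(idx)
    out = np.full((m, m), np.nan)

    def block(r0, r1, c0, c1):
        return S[r1 + 1, c1 + 1] - S[r0, c1 + 1] - S[r1 + 1, c0] + S[r0, c0]

    for a in range(m):
        vi = idx[a]
        for b in range(a + 1, m):
            vj = idx[b]
            # fragment residues vi..vj spans edges vi..vj-1
            if vi >= 2:        # preceding part has >= 2 vertices
                out[a, b] = block(0, vi - 2, vi, vj - 1)
            if vj <= n - 3:    # following part has >= 2 vertices
                out[b, a] = block(vi, vj - 1, vj + 1, n - 2)
    return LinkingMatrix(filament_id=f.backbone.label,
                         residues=f.residue_numbers[idx].copy(), matrix=out)


def render_fingerprint(m: LinkingMatrix, out_path) -> Path:
    """Render a linking matrix as a signed colour map (the linking
    fingerprint): diverging colormap centred at 0, ND cells neutral grey,
    axes labelled by residue number."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = np.nanmax(np.abs(m.matrix)) if np.any(~np.isnan(m.matrix)) else 1.0
    vmax = vmax if vmax > 0 else 1.0
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("0.85")
    fig, ax = plt.subplots(figsize=(6.4, 5.6))
    im = ax.imshow(np.ma.masked_invalid(m.matrix), cmap=cmap,
                   vmin=-vmax, vmax=vmax, origin="upper",
                   extent=(m.residues[0] - 0.5, m.residues[-1] + 0.5,
                           m.residues[-1] + 0.5, m.residues[0] - 0.5))
    ax.set_xlabel("residue")
    ax.set_ylabel("residue")
    ax.set_title(f"linking fingerprint {m.filament_id}")
    fig.colorbar(im, ax=ax, label="Lk")
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


@dataclass(frozen=True)
class KnotoidFlag:
    """Outcome of knotoid-perspective detection for one open curve."""

    is_knotoid: bool
    fraction: float
    threshold: float
    example_directions: np.ndarray


def knotoid_flag(f: FilamentModel | PolygonalCurve,
                 threshold: float = 0.01,
                 result: Vassiliev2Result | None = None,
                 n_projections: int = 2000, seed: int = 0) -> KnotoidFlag:
    """Detect non-trivial knotoid perspectives of an open curve.

    A projection qualifies when its per-diagram second Vassiliev value is
    >= 0.5 (the value of the simplest non-trivial knotoid K2_1); the curve is
    flagged when the fraction of qualifying projections exceeds ``threshold``.
    Pass a precomputed :class:`Vassiliev2Result` (with per-projection values
    retained) to reuse an existing estimate.
    """
    curve = f.backbone if isinstance(f, FilamentModel) else f
    if result is None:
        result = vassiliev2(curve, n_projections=n_projections, seed=seed,
                            keep_values=True)
    if result.per_projection is None or result.directions is None:
        raise ValueError("vassiliev2 result must retain per-projection values")
    qualifying = result.per_projection >= 0.5
    frac = float(qualifying.mean())
    examples = result.directions[qualifying][:5]
    return KnotoidFlag(is_knotoid=frac > threshold, fraction=frac,
                       threshold=threshold, example_directions=examples)
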