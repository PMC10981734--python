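"""Polygonal-curve and filament containers.

Protein backbones are treated as open, oriented polygonal curves through the
consecutive C-alpha atoms, ordered from the N- to the C-terminus.  A
:class:`FilamentModel` pairs such a curve with author residue numbering, the
tau microtubule-binding-repeat annotation, and (optionally) a side-chain
push-off curve with one vertex per backbone vertex.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "PolygonalCurve",
    "ResidueRange",
    "FilamentModel",
    "REPEAT_NAMES",
    "repeat_range_table",
    "annotate_repeats",
    "subcurve",
]

#: Region labels used throughout: the four microtubule-binding repeats and the
#: C-terminal region that follows them.
REPEAT_NAMES = ("R1", "R2", "R3", "R4", "C")

#: Default repeat boundaries in author (2N4R isoform) residue numbering.
#: R1-R4 are the 31/32-residue microtubule-binding repeats; "C" is everything
#: C-terminal of R4 that is resolved in a given fibril core.
DEFAULT_REPEAT_TABLE: dict[str, tuple[int, int]] = {
    "R1": (244, 274),
    "R2": (275, 305),
    "R3": (306, 336),
    "R4": (337, 368),
    "C": (369, 10_000),
}


class CurveError(ValueError):
    """Invalid polygonal-curve construction or usage."""


class ResidueRangeError(KeyError):
    """A residue lies outside the resolved range of a filament."""


@dataclass(frozen=True)
class PolygonalCurve:
    """An oriented polygonal curve in 3-space.

    Parameters
    ----------
    vertices : (n, 3) array_like
        Ordered vertex coordinates in Angstrom.  Orientation is the storage
        order; for proteins this is N-terminus to C-terminus.
    closed : bool
        If True the last vertex connects back to the first (no duplicated
        vertex).  Protein backbones are open.
    label : str
        Free-text identifier carried through analyses.
    """

    vertices: np.ndarray
    closed: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise CurveError(f"vertices must be (n, 3), got {v.shape}")
        if len(v) < 2:
            raise CurveError("a polygonal curve needs at least 2 vertices")
        if not np.all(np.isfinite(v)):
            raise CurveError("vertex coordinates must be finite")
        seg = np.diff(v, axis=0)
        if np.any(np.einsum("ij,ij->i", seg, seg) == 0.0):
            raise CurveError("consecutive vertices coincide")
        if self.closed and np.all(v[0] == v[-1]):
            raise CurveError("closed curves must not duplicate the first vertex")
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.vertices) if self.closed else len(self.vertices) - 1

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge start/end points as two (n_edges, 3) arrays."""
        v = self.vertices
        if self.closed:
            return v, np.roll(v, -1, axis=0)
        return v[:-1], v[1:]

    def reversed(self) -> "PolygonalCurve":
        """The same curve with opposite orientation."""
        return replace(self, vertices=self.vertices[::-1].copy())

    def transformed(self, matrix: np.ndarray | None = None,
                    shift: np.ndarray | None = None,
                    scale: float = 1.0) -> "PolygonalCurve":
        v = self.vertices * float(scale)
        if matrix is not None:
            v = v @ np.asarray(matrix, dtype=float).T
        if shift is not None:
            v = v + np.asarray(shift, dtype=float)
        return replace(self, vertices=v)


@dataclass(frozen=True)
class ResidueRange:
    """An inclusive author-numbered residue interval labelled by region."""

    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CurveError(f"range start {self.start} > end {self.end}")
        if self.name not in REPEAT_NAMES + ("pre-R1",):
            raise CurveError(f"unknown region name {self.name!r}")

    def __contains__(self, residue: int) -> bool:
        return self.start <= int(residue) <= self.end


def repeat_range_table(
    overrides: Mapping[str, tuple[int, int]] | None = None,
) -> dict[str, ResidueRange]:
    """The repeat-boundary table R1..R4 plus the C-terminal region.

    Boundaries default to :data:`DEFAULT_REPEAT_TABLE` (R1 244-274, R2 275-305,
    R3 306-336, R4 337-368, C 369 onward) and may be overridden per run.
    """
    table = dict(DEFAULT_REPEAT_TABLE)
    if overrides:
        table.update({k: (int(a), int(b)) for k, (a, b) in overrides.items()})
    return {name: ResidueRange(a, b, name) for name, (a, b) in table.items()}


@dataclass(frozen=True)
class FilamentModel:
    """A filament backbone with residue numbering and repeat annotation.

    ``residue_numbers`` carries the author numbering of the deposited model
    (strictly increasing, one entry per backbone vertex); numbering gaps are
    permitted and recorded, but the curve joins consecutive vertices across
    them.  ``pushoff``, when present, is the side-chain push-off curve with
    exactly one vertex per backbone vertex.
    """

    backbone: PolygonalCurve
    residue_numbers: np.ndarray
    repeats: tuple[ResidueRange, ...] = ()
    pushoff: PolygonalCurve | None = None
    accession: str = ""
    chain_id: str = ""

    def __post_init__(self) -> None:
        nums = np.asarray(self.residue_numbers, dtype=int)
        if nums.ndim != 1 or len(nums) != len(self.backbone):
            raise CurveError("residue_numbers must match backbone vertex count")
        if np.any(np.diff(nums) <= 0):
            raise CurveError("residue_numbers must be strictly increasing")
        if self.pushoff is not None and len(self.pushoff) != len(self.backbone):
            raise CurveError("pushoff must have one vertex per backbone vertex")
        spans = sorted((r.start, r.end) for r in self.repeats)
        for (a0, b0), (a1, b1) in zip(spans, spans[1:]):
            if a1 <= b0:
                raise CurveError("repeat ranges overlap")
        object.__setattr__(self, "residue_numbers", nums)
        object.__setattr__(self, "repeats", tuple(self.repeats))

    # -- residue bookkeeping -------------------------------------------------

    @property
    def n_residues(self) -> int:
        return len(self.backbone)

    @property
    def first_residue(self) -> int:
        return int(self.residue_numbers[0])

    @property
    def last_residue(self) -> int:
        return int(self.residue_numbers[-1])

    def index_of(self, residue: int) -> int:
        idx = np.searchsorted(self.residue_numbers, residue)
        if idx >= len(self.residue_numbers) or self.residue_numbers[idx] != residue:
            raise ResidueRangeError(
                f"residue {residue} not resolved in {self.accession or 'filament'}"
                f" ({self.first_residue}-{self.last_residue})")
        return int(idx)

    def vertex_mask(self, start: int, end: int) -> np.ndarray:
        """Boolean mask of vertices whose residue number lies in [start, end]."""
        return (self.residue_numbers >= start) & (self.residue_numbers <= end)

    def region(self, name: str) -> ResidueRange | None:
        for r in self.repeats:
            if r.name == name:
                return r
        return None

    def region_resolved(self, name: str) -> bool:
        r = self.region(name)
        return r is not None and bool(np.any(self.vertex_mask(r.start, r.end)))

    # -- serialization -------------------------------------------------------

    def to_json(self) -> str:
        rec = {
            "accession": self.accession,
            "chain_id": self.chain_id,
            "residue_numbers": self.residue_numbers.tolist(),
            "backbone": self.backbone.vertices.tolist(),
            "pushoff": None if self.pushoff is None
                       else self.pushoff.vertices.tolist(),
            "repeats": [[r.start, r.end, r.name] for r in self.repeats],
            "label": self.backbone.label,
        }
        return json.dumps(rec)

    @classmethod
    def from_json(cls, text: str) -> "FilamentModel":
        rec = json.loads(text)
        backbone = PolygonalCurve(np.asarray(rec["backbone"]), label=rec.get("label", ""))
        push = rec.get("pushoff")
        return cls(
            backbone=backbone,
            residue_numbers=np.asarray(rec["residue_numbers"], dtype=int),
            repeats=tuple(ResidueRange(a, b, n) for a, b, n in rec["repeats"]),
            pushoff=None if push is None else PolygonalCurve(np.asarray(push)),
            accession=rec.get("accession", ""),
            chain_id=rec.get("chain_id", ""),
        )


def annotate_repeats(
    f: FilamentModel,
    table: Mapping[str, ResidueRange] | None = None,
) -> FilamentModel:
    """Attach repeat annotation: the intersection of the boundary table with the
    resolved residues.  Regions with no resolved residue are simply absent
    (reported as ND downstream).  Resolved residues before R1 are labelled
    ``pre-R1`` so that the annotation is total."""
    table = table if table is not None else repeat_range_table()
    lo, hi = f.first_residue, f.last_residue
    ranges: list[ResidueRange] = []
    r1_start = table["R1"].start
    if lo < r1_start:
        ranges.append(ResidueRange(lo, min(hi, r1_start - 1), "pre-R1"))
    for name in REPEAT_NAMES:
        r = table[name]
        a, b = max(r.start, lo), min(r.end, hi)
        if a <= b and np.any(f.vertex_mask(a, b)):
            ranges.append(ResidueRange(a, b, name))
    return replace(f, repeats=tuple(ranges))


def subcurve(f: FilamentModel, k: int, l: int) -> PolygonalCurve:
    """The part of the filament from residue ``k`` to residue ``l`` inclusive.

    Raises
    ------
    ResidueRangeError
        If either endpoint is outside the resolved residue range (no silent
        truncation).
    CurveError
        If the sub-chain has fewer than 2 vertices (a single residue is not a
        usable curve for topology operations).
    """
    if k > l:
        raise CurveError(f"subcurve start {k} > end {l}")
    for res in (k, l):
        if res < f.first_residue or res > f.last_residue:
            raise ResidueRangeError(
                f"residue {res} outside resolved range "
                f"{f.first_residue}-{f.last_residue}")
    mask = f.vertex_mask(k, l)
    pts = f.backbone.vertices[mask]
    if len(pts) < 2:
        raise CurveError(f"subcurve {k}-{l} has {len(pts)} vertex; need >= 2")
    return PolygonalCurve(pts, label=f"{f.accession}:{f.chain_id}:{k}-{l}")


def sub_pushoff(f: FilamentModel, k: int, l: int) -> PolygonalCurve:
    """The push-off restricted to residues ``k``..``l`` (same mask as
    :func:`subcurve`)."""
    if f.pushoff is None:
        raise CurveError("filament has no push-off curve")
    mask = f.vertex_mask(k, l)
    pts = f.pushoff.vertices[mask]
    if len(pts) < 2:
        raise CurveError(f"push-off subcurve {k}-{l} too short")
    return PolygonalCurve(pts, label=f"{f.accession}:{f.chain_id}:push:{k}-{l}")
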