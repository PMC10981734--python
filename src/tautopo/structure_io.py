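"""Structure reading and filament extraction.

Reads PDB/mmCIF files (via gemmi), extracts per-chain CA backbones as
:class:`~tautopo.curves.FilamentModel` objects, builds side-chain push-off
curves, and identifies neighboring rungs in stacked fibril assemblies.

Only the first model is used; hydrogens are dropped and, for alternate
locations, the highest-occupancy conformer is kept (ties broken by first
occurrence).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
from scipy.spatial import cKDTree

from .curves import (CurveError, FilamentModel, PolygonalCurve,
                     annotate_repeats, repeat_range_table)
from .topology import gauss_linking

__all__ = [
    "AtomRecord", "StackedAssembly", "read_structure", "extract_backbone",
    "build_pushoff", "find_neighbors", "stacked_linking", "load_filament",
    "load_assembly", "fetch_structure",
]

#: Atom names considered backbone; everything else heavy is R-group.
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: Default minimal CA-CA distance (Angstrom) under which two chains are
#: considered neighbors (adjacent rungs stack at ~4.7 A).
NEIGHBOR_CUTOFF = 6.0


class StructureError(ValueError):
    """Unreadable or empty structure file."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of the first model after altloc filtering."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: tuple[float, float, float]
    occupancy: float


def read_structure(path) -> dict[str, list[AtomRecord]]:
    """All chains of the first model as ordered heavy-atom records.

    Returns a mapping chain id -> atom records in file order.  Hydrogens are
    removed; for alternate locations the highest-occupancy copy of each atom
    is kept.
    """
    import gemmi
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path} contains no model")
    st.remove_hydrogens()
    model = st[0]
    chains: dict[str, list[AtomRecord]] = {}
    for chain in model:
        records: list[AtomRecord] = []
        for res in chain:
            best: dict[str, object] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in res:
                a = best.get(atom.name)
                if a is not atom:
                    continue
                records.append(AtomRecord(
                    chain_id=chain.name,
                    residue_number=res.seqid.num,
                    residue_name=res.name,
                    atom_name=atom.name,
                    element=atom.element.name,
                    position=(atom.pos.x, atom.pos.y, atom.pos.z),
                    occupancy=atom.occ,
                ))
        if records:
            chains[chain.name] = records
    if not chains:
        raise StructureError(f"{path} has no heavy atoms in the first model")
    return chains


def extract_backbone(chain: Sequence[AtomRecord],
                     residue_range: tuple[int, int] | None = None,
                     accession: str = "",
                     annotate: bool = True) -> FilamentModel:
    """CA backbone of one chain as an annotated filament.

    Vertices are CA positions in residue order; numbering gaps are recorded in
    ``residue_numbers`` while the curve joins consecutive vertices across
    them.  Residues without a CA atom are skipped with a warning.
    """
    cas: dict[int, AtomRecord] = {}
    seen: set[int] = set()
    for rec in chain:
        if residue_range is not None and not (
                residue_range[0] <= rec.residue_number <= residue_range[1]):
            continue
        seen.add(rec.residue_number)
        if rec.atom_name == "CA" and rec.residue_number not in cas:
            cas[rec.residue_number] = rec
    missing = seen - set(cas)
    if missing:
        warnings.warn(f"residues without CA skipped: {sorted(missing)}")
    if len(cas) < 2:
        raise StructureError("fewer than 2 CA atoms in the requested range")
    nums = np.array(sorted(cas), dtype=int)
    pts = np.array([cas[n].position for n in nums])
    chain_id = chain[0].chain_id if chain else ""
    f = FilamentModel(
        backbone=PolygonalCurve(pts, label=f"{accession}:{chain_id}"),
        residue_numbers=nums,
        accession=accession,
        chain_id=chain_id,
    )
    return annotate_repeats(f) if annotate else f


def build_pushoff(chain: Sequence[AtomRecord], f: FilamentModel,
                  atom_rank: int = 1) -> PolygonalCurve:
    """Side-chain push-off: one vertex per backbone residue.

    For each residue the R-group heavy atom with the ``atom_rank``-th largest
    distance from that residue's CA is chosen (rank 1 = farthest; higher ranks
    support robustness re-analysis).  Residues with fewer than ``atom_rank``
    R-group heavy atoms (notably glycine) get a vertex linearly interpolated
    between the flanking residues' push-off vertices; at the termini the CA
    position nudged toward the chain interior is used, which keeps one vertex
    per residue without coincident backbone/push-off points.
    """
    if atom_rank < 1:
        raise ValueError("atom_rank must be >= 1")
    by_res: dict[int, list[AtomRecord]] = {}
    for rec in chain:
        if rec.atom_name not in BACKBONE_ATOMS:
            by_res.setdefault(rec.residue_number, []).append(rec)
    ca = f.backbone.vertices
    n = len(ca)
    push = np.full((n, 3), np.nan)
    for k, resnum in enumerate(f.residue_numbers):
        candidates = by_res.get(int(resnum), [])
        if len(candidates) >= atom_rank:
            d = [np.linalg.norm(np.array(r.position) - ca[k]) for r in candidates]
            order = np.argsort(d)[::-1]
            push[k] = candidates[order[atom_rank - 1]].position
    # fill gaps by interpolation between flanking defined vertices
    defined = np.flatnonzero(~np.isnan(push[:, 0]))
    if len(defined) == 0:
        raise StructureError("no side-chain heavy atoms in chain")
    for k in np.flatnonzero(np.isnan(push[:, 0])):
        left = defined[defined < k]
        right = defined[defined > k]
        if len(left) and len(right):
            i, j = left[-1], right[0]
            t = (k - i) / (j - i)
            push[k] = (1 - t) * push[i] + t * push[j]
        else:
            # terminal run: copy the CA nudged toward the nearest defined
            # push-off vertex so curves never coincide
            j = right[0] if len(right) else left[-1]
            push[k] = ca[k] + 0.05 * (push[j] - ca[j])
    return PolygonalCurve(push, label=f.backbone.label + ":pushoff")


@dataclass(frozen=True)
class StackedAssembly:
    """Stacked filament rungs (one FilamentModel per chain) with their
    adjacency, as in a fibril where every rung touches the rungs above and
    below and possibly a paired protofilament."""

    filaments: tuple[FilamentModel, ...]
    neighbor_pairs: tuple[tuple[int, int], ...]

    def neighbors_of(self, i: int) -> list[int]:
        out = [b for a, b in self.neighbor_pairs if a == i]
        out += [a for a, b in self.neighbor_pairs if b == i]
        return sorted(set(out))


def find_neighbors(filaments: Sequence[FilamentModel],
                   cutoff: float = NEIGHBOR_CUTOFF) -> tuple[tuple[int, int], ...]:
    """Index pairs of filaments whose minimal CA-CA distance is below
    ``cutoff`` (default 6 A, capturing the ~4.7 A cross-beta stacking but not
    next-nearest rungs at ~9.4 A)."""
    trees = [cKDTree(f.backbone.vertices) for f in filaments]
    pairs = []
    for i in range(len(filaments)):
        for j in range(i + 1, len(filaments)):
            d = trees[i].query(filaments[j].backbone.vertices, k=1)[0].min()
            if d < cutoff:
                pairs.append((i, j))
    return tuple(pairs)


def load_assembly(path, accession: str = "",
                  cutoff: float = NEIGHBOR_CUTOFF) -> StackedAssembly:
    """Read a structure file and assemble all chains into a stacked assembly."""
    chains = read_structure(path)
    filaments = tuple(extract_backbone(ch, accession=accession)
                      for ch in chains.values())
    return StackedAssembly(filaments, find_neighbors(filaments, cutoff))


def stacked_linking(assembly: StackedAssembly, i: int) -> float:
    """Mean linking number of filament ``i`` with its neighboring filaments.

    Returns NaN (ND) when the filament has no identified neighbor.
    """
    nbrs = assembly.neighbors_of(i)
    if not nbrs:
        return float("nan")
    fi = assembly.filaments[i].backbone
    return float(np.mean([gauss_linking(fi, assembly.filaments[j].backbone)
                          for j in nbrs]))


def load_filament(path, chain: str | None = None,
                  accession: str = "", atom_rank: int = 1,
                  residue_range: tuple[int, int] | None = None) -> FilamentModel:
    """Read one chain as an annotated filament with its push-off attached.

    When ``chain`` is None the first chain (alphabetically) whose resolved
    span covers the widest residue range is used.
    """
    chains = read_structure(path)
    if chain is None:
        def span(records):
            nums = [r.residue_number for r in records if r.atom_name == "CA"]
            return (max(nums) - min(nums)) if nums else -1
        widest = max(span(v) for v in chains.values())
        chain = sorted(k for k, v in chains.items() if span(v) == widest)[0]
    elif chain not in chains:
        raise StructureError(f"chain {chain!r} not in {sorted(chains)}")
    records = chains[chain]
    f = extract_backbone(records, residue_range=residue_range,
                         accession=accession)
    push = build_pushoff(records, f, atom_rank=atom_rank)
    from dataclasses import replace
    return replace(f, pushoff=push)


def fetch_structure(accession: str, cache_dir) -> Path:
    """Download a PDB entry (mmCIF) into ``cache_dir`` unless already cached.

    Requires network access; analyses in this package otherwise run fully
    offline on local files.
    """
    from urllib.request import urlretrieve
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    target = cache / f"{accession.lower()}.cif"
    if not target.exists():
        urlretrieve(f"https://files.rcsb.org/download/{accession.lower()}.cif",
                    target)
    return target
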