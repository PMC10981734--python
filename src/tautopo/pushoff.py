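"""Ribbon analysis of a CA backbone against its side-chain push-off.

The backbone and its push-off bound an open ribbon; their Gauss linking
number measures the total winding of the side chains about the backbone, and
with the ribbon relation Tw = Lk - Wr the linking number approximates the
ribbon twist whenever the backbone writhe is small (as it is for the flat
fibril folds).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .curves import (CurveError, FilamentModel, PolygonalCurve, REPEAT_NAMES,
                     sub_pushoff, subcurve)
from .topology import gauss_linking, writhe

__all__ = ["ribbon_linking", "repeat_ribbon_linking", "twist",
           "RibbonSummary", "ribbon_summary"]


def ribbon_linking(backbone: PolygonalCurve, push: PolygonalCurve) -> float:
    """Gauss linking number of a backbone with its push-off.

    Requires matching vertex counts (one push-off vertex per residue) and
    disjoint curves.
    """
    if len(backbone) != len(push):
        raise CurveError("backbone and push-off must have equal vertex counts")
    return gauss_linking(backbone, push)


def repeat_ribbon_linking(f: FilamentModel, region: str) -> float:
    """Backbone/push-off linking restricted to one repeat region.

    Both curves are truncated to exactly the residues inside the region
    interval.  An unresolved region reports 0 (the region contributes no
    winding to this filament).
    """
    if f.pushoff is None:
        raise CurveError("filament has no push-off curve")
    r = f.region(region)
    if r is None:
        return 0.0
    lo, hi = max(r.start, f.first_residue), min(r.end, f.last_residue)
    try:
        back = subcurve(f, lo, hi)
        push = sub_pushoff(f, lo, hi)
    except CurveError:
        return 0.0
    return ribbon_linking(back, push)


def twist(lk: float, wr: float) -> float:
    """Ribbon twist from the relation Tw = Lk - Wr."""
    return lk - wr


@dataclass(frozen=True)
class RibbonSummary:
    """Whole-filament and per-region backbone/push-off linking of a filament.

    ``lk`` is the whole-filament linking, ``lk_per_n`` its value divided by
    the filament residue count; ``region_lk[name]`` the linking restricted to
    each region, with two normalizations: by the region's residue count
    (``region_lk_per_region``) and by the filament length
    (``region_lk_per_n``).  ``tw`` is Lk - Wr of the backbone.
    """

    filament_id: str
    n_residues: int
    lk: float
    lk_per_n: float
    wr: float
    tw: float
    region_lk: dict[str, float]
    region_lk_per_region: dict[str, float]
    region_lk_per_n: dict[str, float]

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["quantity", "value"])
            w.writerow(["N", self.n_residues])
            w.writerow(["Lk", f"{self.lk:.6g}"])
            w.writerow(["Lk/N", f"{self.lk_per_n:.6g}"])
            w.writerow(["Wr", f"{self.wr:.6g}"])
            w.writerow(["Tw", f"{self.tw:.6g}"])
            for name in REPEAT_NAMES:
                w.writerow([f"lk_{name}", f"{self.region_lk[name]:.6g}"])
                w.writerow([f"lk_{name}/N_region",
                            f"{self.region_lk_per_region[name]:.6g}"])
                w.writerow([f"lk_{name}/N", f"{self.region_lk_per_n[name]:.6g}"])


def ribbon_summary(f: FilamentModel) -> RibbonSummary:
    """Full ribbon analysis of one filament (whole and per region)."""
    if f.pushoff is None:
        raise CurveError("filament has no push-off curve")
    lk = ribbon_linking(f.backbone, f.pushoff)
    wr = writhe(f.backbone)
    n = f.n_residues
    region_lk: dict[str, float] = {}
    region_per_region: dict[str, float] = {}
    region_per_n: dict[str, float] = {}
    for name in REPEAT_NAMES:
        v = repeat_ribbon_linking(f, name)
        region_lk[name] = v
        r = f.region(name)
        if r is None:
            region_per_region[name] = 0.0
        else:
            n_region = int(np.count_nonzero(f.vertex_mask(r.start, r.end)))
            region_per_region[name] = v / n_region if n_region else 0.0
        region_per_n[name] = v / n
    return RibbonSummary(
        filament_id=f.backbone.label, n_residues=n,
        lk=lk, lk_per_n=lk / n, wr=wr, tw=twist(lk, wr),
        region_lk=region_lk, region_lk_per_region=region_per_region,
        region_lk_per_n=region_per_n)
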