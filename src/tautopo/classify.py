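"""Global-feature assembly, clustering and the hierarchical classification
report.

Each filament is summarized by three global features -- normalized writhe
Wr/N, normalized stacked-filament linking Lk_s/N, and the absolute second
Vassiliev measure |v2| (not normalized, as it is insensitive to stored
length) -- and classified at three levels: writhe handedness, repeat-pair
sign tuples, and K-means clusters of the feature vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curves import FilamentModel
from .fingerprints import (RepeatLinkTable, SignTuple, sign_tuple,
                           tuple_distance)
from .structure_io import StackedAssembly, stacked_linking
from .topology import vassiliev2, writhe

__all__ = ["TopologySummary", "ClusterResult", "summarize", "kmeans_features",
           "handedness", "classification_report", "summaries_frame"]


@dataclass(frozen=True)
class TopologySummary:
    """Global topological metrics of one filament.

    ``wr_per_n`` and ``lks_per_n`` are raw values divided by the residue
    count N; ``v2`` carries its Monte-Carlo standard error and provenance
    (seed, number of projections).  ``lks`` is NaN when the filament has no
    stacked neighbor.
    """

    filament_id: str
    n_residues: int
    wr: float
    wr_per_n: float
    lks: float
    lks_per_n: float
    v2: float
    abs_v2: float
    v2_stderr: float
    v2_seed: int
    v2_projections: int

    def features(self) -> np.ndarray:
        """Feature vector (Wr/N, Lk_s/N, |v2|) used for clustering."""
        return np.array([self.wr_per_n, self.lks_per_n, self.abs_v2])


def summarize(f: FilamentModel, assembly: StackedAssembly | None = None,
              filament_index: int | None = None,
              n_projections: int = 2000, seed: int = 0) -> TopologySummary:
    """All global metrics of one filament.

    ``assembly``/``filament_index`` locate the filament among its stacked
    neighbors for Lk_s; without an assembly the stacked linking is ND (NaN).
    """
    n = f.n_residues
    wr = writhe(f.backbone)
    if assembly is not None:
        if filament_index is None:
            filament_index = next(
                i for i, g in enumerate(assembly.filaments)
                if g.chain_id == f.chain_id and g.accession == f.accession)
        lks = stacked_linking(assembly, filament_index)
    else:
        lks = float("nan")
    res = vassiliev2(f.backbone, n_projections=n_projections, seed=seed)
    return TopologySummary(
        filament_id=f.backbone.label, n_residues=n,
        wr=wr, wr_per_n=wr / n,
        lks=lks, lks_per_n=lks / n,
        v2=res.value, abs_v2=abs(res.value), v2_stderr=res.stderr,
        v2_seed=seed, v2_projections=n_projections)


def summaries_frame(summaries: Sequence[TopologySummary]) -> pd.DataFrame:
    """Summaries as a DataFrame (one row per filament)."""
    return pd.DataFrame([{
        "filament": s.filament_id, "N": s.n_residues,
        "Wr": s.wr, "Wr/N": s.wr_per_n, "Lk_s": s.lks, "Lk_s/N": s.lks_per_n,
        "v2": s.v2, "|v2|": s.abs_v2, "v2_stderr": s.v2_stderr,
        "seed": s.v2_seed, "n_projections": s.v2_projections,
    } for s in summaries]).set_index("filament")


@dataclass(frozen=True)
class ClusterResult:
    """K-means partition of filament feature vectors.

    ``quality`` is the silhouette score of the partition (the metric used
    here for cluster quality; no claim is made about other quality measures).
    """

    k: int
    labels: dict[str, int]
    quality: float
    seed: int

    def cluster_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for fid, lab in self.labels.items():
            out.setdefault(lab, []).append(fid)
        return {lab: sorted(v) for lab, v in out.items()}


def kmeans_features(features: pd.DataFrame | Mapping[str, np.ndarray],
                    k: int, seed: int = 0, n_init: int = 10,
                    standardize: bool = True) -> ClusterResult:
    """K-means on (Wr/N, Lk_s/N, |v2|) feature vectors.

    ``features`` is a DataFrame with one row per filament (three numeric
    columns) or a mapping filament id -> 3-vector.  Features are z-scored by
    default: the three metrics share a 1e-3 scale but very different spreads,
    and without standardization the writhe axis dominates the partition
    (``standardize=False`` disables it).  Labels are deterministic for a
    given seed; cluster numbering is canonicalized by first appearance.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    if isinstance(features, pd.DataFrame):
        ids = list(features.index)
        X = features.select_dtypes("number").to_numpy(float)
    else:
        ids = list(features)
        X = np.array([np.asarray(features[i], float) for i in ids])
    if k < 1 or k > len(ids):
        raise ValueError(f"k={k} outside 1..{len(ids)}")
    if standardize:
        std = X.std(axis=0)
        std[std == 0] = 1.0          # constant features carry no information
        X = (X - X.mean(axis=0)) / std
    if k == len(ids):
        raw = np.arange(len(ids))
    else:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        raw = km.fit_predict(X)
    # canonical labels: order of first appearance
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for fid, lab in zip(ids, raw):
        if lab not in remap:
            remap[lab] = len(remap)
        labels[fid] = remap[lab]
    if 1 < k < len(ids):
        quality = float(silhouette_score(X, raw))
    else:
        quality = float("nan")
    return ClusterResult(k=k, labels=labels, quality=quality, seed=seed)


def handedness(summary: TopologySummary | float) -> str:
    """Global conformational handedness from the writhe sign.

    Negative writhe indicates a left-handed conformation, positive a
    right-handed one; exactly zero is ND.
    """
    wr = summary.wr if isinstance(summary, TopologySummary) else float(summary)
    if wr < 0:
        return "left"
    if wr > 0:
        return "right"
    return "ND"


def classification_report(summaries: Sequence[TopologySummary],
                          tables: Mapping[str, RepeatLinkTable] | None = None,
                          tuples: Mapping[str, SignTuple] | None = None,
                          clusters: ClusterResult | None = None) -> dict:
    """Hierarchical topological classification of a filament set.

    Level 1 groups filaments by writhe handedness; level 2 subdivides each
    handedness group by identical repeat-pair sign tuples.  The report also
    carries pairwise tuple distances and, when given, K-means cluster labels.
    Output is a JSON-serializable dict, invariant under input ordering.
    """
    summaries = sorted(summaries, key=lambda s: s.filament_id)
    if tuples is None and tables is not None:
        tuples = {fid: sign_tuple(t) for fid, t in tables.items()}
    report: dict = {"n_filaments": len(summaries), "levels": {}}

    level1: dict[str, list[str]] = {}
    for s in summaries:
        level1.setdefault(handedness(s), []).append(s.filament_id)
    report["levels"]["1_handedness"] = {k: sorted(v)
                                        for k, v in sorted(level1.items())}

    if tuples is not None:
        level2: dict[str, dict[str, list[str]]] = {}
        for hand, members in level1.items():
            groups: dict[str, list[str]] = {}
            for fid in members:
                key = str(tuples[fid]) if fid in tuples else "?"
                groups.setdefault(key, []).append(fid)
            level2[hand] = {k: sorted(v) for k, v in sorted(groups.items())}
        report["levels"]["2_sign_tuples"] = dict(sorted(level2.items()))
        ids = sorted(tuples)
        report["tuple_distances"] = {
            f"{a}|{b}": tuple_distance(tuples[a], tuples[b])
            for ai, a in enumerate(ids) for b in ids[ai + 1:]}

    if clusters is not None:
        report["clusters"] = {
            "k": clusters.k,
            "quality_metric": "silhouette",
            "quality": clusters.quality,
            "members": {str(k): v for k, v in
                        sorted(clusters.cluster_members().items())},
        }
    report["metrics"] = {
        s.filament_id: {"N": s.n_residues, "Wr/N": s.wr_per_n,
                        "Lk_s/N": s.lks_per_n, "|v2|": s.abs_v2,
                        "v2_stderr": s.v2_stderr}
        for s in summaries}
    return report


def report_markdown(report: dict) -> str:
    """Markdown rendering of a classification report."""
    lines = [f"# Topological classification ({report['n_filaments']} filaments)", ""]
    lines.append("## Level 1: handedness (writhe sign)")
    for hand, members in report["levels"]["1_handedness"].items():
        lines.append(f"- **{hand}**: {', '.join(members)}")
    if "2_sign_tuples" in report["levels"]:
        lines.append("")
        lines.append("## Level 2: repeat-pair sign tuples")
        for hand, groups in report["levels"]["2_sign_tuples"].items():
            lines.append(f"- {hand}:")
            for tup, members in groups.items():
                lines.append(f"  - `{tup}`: {', '.join(members)}")
    if "clusters" in report:
        c = report["clusters"]
        lines.append("")
        lines.append(f"## K-means (k={c['k']}, silhouette={c['quality']:.3g})")
        for lab, members in c["members"].items():
            lines.append(f"- cluster {lab}: {', '.join(members)}")
    return "\n".join(lines) + "\n"
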