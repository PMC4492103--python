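"""Cluster annotation and summary: high-value compounds, overlap statistics,
size statistics, and network export.

A high-value compound (HVC) is one with a potent response (IC50 or EC50
strictly below 10 µM in any assay), a MeSH annotation, or a MeSH
Pharmacological Action annotation (the last is by construction a subset of
the MeSH-annotated compounds). Cluster overlap between two similarity
measures for one UID is

    O(i, j) = 100 * N_cmpd(i, j) / N_cmpd(i)

where N_cmpd(i) counts compounds occurring in any non-singleton cluster of
measure i for that UID and N_cmpd(i, j) those occurring under both measures;
O is not symmetric in general.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .chem_io import ActivityRecord, CompoundFlags, PotencyType
from .clustering import Cluster
from .thresholds import Measure

logger = logging.getLogger("sarclust")

HVC_POTENCY_CUTOFF_UM = 10.0


@dataclass
class HvcFlags:
    compound_id: int
    high_potency: bool = False
    has_mesh: bool = False
    has_pharm_action: bool = False

    @property
    def any_hvc(self) -> bool:
        return self.high_potency or self.has_mesh or self.has_pharm_action


def annotate_hvc(
    records: Iterable[ActivityRecord],
    compound_flags: Optional[Mapping[int, CompoundFlags]] = None,
    potency_cutoff_um: float = HVC_POTENCY_CUTOFF_UM,
) -> dict[int, HvcFlags]:
    """Per-compound HVC flags. Potency is strict: exactly 10 µM is not high
    potency. A pharm-action flag without a MeSH flag forces MeSH true (the
    pharm-action vocabulary is a subset of MeSH), with a warning."""
    flags: dict[int, HvcFlags] = {}
    for rec in records:
        fl = flags.setdefault(rec.compound_id, HvcFlags(rec.compound_id))
        if (
            rec.potency_type in (PotencyType.IC50, PotencyType.EC50)
            and rec.potency_um is not None
            and rec.potency_um < potency_cutoff_um
        ):
            fl.high_potency = True
    for cid, cf in (compound_flags or {}).items():
        fl = flags.setdefault(cid, HvcFlags(cid))
        fl.has_mesh = cf.has_mesh
        fl.has_pharm_action = cf.has_pharm_action
        if cf.has_pharm_action and not cf.has_mesh:
            logger.warning(
                "compound %d: pharm-action without MeSH; forcing MeSH true", cid
            )
            fl.has_mesh = True
    return flags


def hvc_per_cluster(
    clusters: Sequence[Cluster], flags: Mapping[int, HvcFlags]
) -> pd.DataFrame:
    """Counts of each HVC kind (and 'any') per cluster."""
    rows = []
    for ordinal, cl in enumerate(clusters, start=1):
        members = set(cl.members_compounds)
        fl = [flags[c] for c in members if c in flags]
        rows.append(
            {
                "cluster_ordinal": ordinal,
                "size": len(members),
                "n_high_potency": sum(f.high_potency for f in fl),
                "n_mesh": sum(f.has_mesh for f in fl),
                "n_pharm_action": sum(f.has_pharm_action for f in fl),
                "n_any_hvc": sum(f.any_hvc for f in fl),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cluster_ordinal", "size", "n_high_potency", "n_mesh",
                 "n_pharm_action", "n_any_hvc"],
    )


@dataclass
class OverlapStat:
    uid: int
    measure_i: Measure
    measure_j: Measure
    n_cmpd_i: int
    n_cmpd_ij: int

    @property
    def o_percent(self) -> float:
        return 100.0 * self.n_cmpd_ij / self.n_cmpd_i


def _covered_compounds(clusters: Iterable[Cluster]) -> set[int]:
    out: set[int] = set()
    for cl in clusters:
        out.update(cl.members_compounds)
    return out


def cluster_overlap(
    clusters_i: Sequence[Cluster],
    clusters_j: Sequence[Cluster],
    uid: int,
    measure_i: Optional[Measure] = None,
    measure_j: Optional[Measure] = None,
) -> Optional[OverlapStat]:
    """O(i, j) for one UID; None (logged) when measure i covers no compounds.
    Expects singleton-filtered clusters."""
    ci = _covered_compounds(clusters_i)
    cj = _covered_compounds(clusters_j)
    if not ci:
        logger.info("UID %s: no compounds covered by measure i; skipped", uid)
        return None
    return OverlapStat(
        uid,
        measure_i if measure_i is not None else (clusters_i[0].measure if clusters_i else None),
        measure_j if measure_j is not None else (clusters_j[0].measure if clusters_j else None),
        len(ci),
        len(ci & cj),
    )


def mean_overlap(
    clusters_by_uid: Mapping[int, Mapping[Measure, Sequence[Cluster]]]
) -> pd.DataFrame:
    """Unweighted mean O(i, j) over UIDs, as a measures x measures table.
    UIDs where measure i covers nothing are skipped for row i."""
    measures = list(Measure)
    acc = {(i, j): [] for i in measures for j in measures}
    for uid, per_measure in clusters_by_uid.items():
        for mi in measures:
            stat_i = per_measure.get(mi, [])
            covered_i = _covered_compounds(stat_i)
            if not covered_i:
                continue
            for mj in measures:
                covered_j = _covered_compounds(per_measure.get(mj, []))
                acc[(mi, mj)].append(100.0 * len(covered_i & covered_j) / len(covered_i))
    data = [
        [float(np.mean(acc[(mi, mj)])) if acc[(mi, mj)] else np.nan for mj in measures]
        for mi in measures
    ]
    labels = [m.value for m in measures]
    return pd.DataFrame(data, index=labels, columns=labels)


def summarize_clusters(clusters: Sequence[Cluster]) -> pd.DataFrame:
    """Mean and sd (n-1 denominator) of cluster-size and multiplicity
    statistics: compounds/cluster, conformers/cluster (3-D only, NaN for 2-D),
    clusters/compound across all UIDs, clusters/UID. Expects
    singleton-filtered clusters of one context and measure."""

    def _stats(values):
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            return (np.nan, np.nan)
        sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
        return (float(np.mean(values)), sd)

    sizes = [cl.n_compounds for cl in clusters]
    conf_sizes = [
        len(cl.members_conformers) for cl in clusters if cl.is_conformer_level
    ]
    per_compound: dict[int, int] = {}
    per_uid: dict[object, int] = {}
    for cl in clusters:
        for cid in set(cl.members_compounds):
            per_compound[cid] = per_compound.get(cid, 0) + 1
        per_uid[cl.uid] = per_uid.get(cl.uid, 0) + 1

    rows = {
        "compounds_per_cluster": _stats(sizes),
        "conformers_per_cluster": _stats(conf_sizes) if conf_sizes else (np.nan, np.nan),
        "clusters_per_compound": _stats(list(per_compound.values())),
        "clusters_per_uid": _stats(list(per_uid.values())),
    }
    return pd.DataFrame(rows, index=["mean", "sd"]).T


def export_network(
    clusters: Sequence[Cluster],
    distance: Callable,
    d_thresh: float,
    level: str = "compound",
    path=None,
    fmt: str = "graphml",
    hvc_flags: Optional[Mapping[int, HvcFlags]] = None,
    potency_um: Optional[Mapping[int, float]] = None,
) -> nx.Graph:
    """Export clusters as a similarity network.

    Nodes are cluster members (compounds drawn as squares, conformers as round
    nodes — recorded in the ``role`` attribute). Edges are added only within
    clusters: between conformers when their distance is <= d_thresh, and
    between compounds when at least one conformer pair arising from the two
    compounds is <= d_thresh (for 2-D clusters, when the compound distance
    is). Nodes in different clusters get no edge even if they are close. HVC
    flags and potency values attach to compound nodes for coloring.
    """
    if level not in ("compound", "conformer"):
        raise ValueError("level must be 'compound' or 'conformer'")
    graph = nx.Graph()

    def node_id(item) -> str:
        return f"{item[0]}:{item[1]}" if isinstance(item, tuple) else str(item)

    for ordinal, cl in enumerate(clusters, start=1):
        if level == "conformer":
            if not cl.is_conformer_level:
                raise ValueError("conformer-level export needs conformer clusters")
            members = list(cl.members_conformers)
        else:
            members = list(dict.fromkeys(cl.members_compounds))
        for m in members:
            nid = node_id(m)
            cid = m[0] if isinstance(m, tuple) else m
            attrs = {"role": "conformer" if isinstance(m, tuple) else "compound",
                     "compound_id": int(cid)}
            if hvc_flags is not None and cid in hvc_flags:
                fl = hvc_flags[cid]
                attrs.update(
                    high_potency=bool(fl.high_potency),
                    has_mesh=bool(fl.has_mesh),
                    has_pharm_action=bool(fl.has_pharm_action),
                )
            if potency_um is not None and cid in potency_um:
                attrs["potency_um"] = float(potency_um[cid])
            if nid in graph:
                graph.nodes[nid]["clusters"] = (
                    graph.nodes[nid]["clusters"] + f";{ordinal}"
                )
                graph.nodes[nid].update(attrs)
            else:
                graph.add_node(nid, clusters=str(ordinal), **attrs)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if level == "compound" and cl.is_conformer_level:
                    pairs = [
                        (x, y)
                        for x in cl.members_conformers if x[0] == a
                        for y in cl.members_conformers if y[0] == b
                    ]
                    close = any(distance(x, y) <= d_thresh for x, y in pairs)
                else:
                    close = distance(a, b) <= d_thresh
                if close:
                    graph.add_edge(node_id(a), node_id(b), cluster=ordinal)

    if path is not None:
        if fmt == "graphml":
            nx.write_graphml(graph, str(path))
        elif fmt == "sif":
            with open(path, "w", encoding="utf-8") as fh:
                for u, v in graph.edges():
                    fh.write(f"{u}\tsim\t{v}\n")
        else:
            raise ValueError(f"unknown network format {fmt!r}")
    return graph
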