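"""Taylor–Butina exclusion clustering and the conformer→compound collapse.

The leader algorithm repeatedly picks the unassigned item with the most
unassigned neighbors inside the exclusion radius (distance <= d_thresh) as a
cluster representative, assigns it together with those neighbors, and stops
when no item has neighbors left; the remainder become singletons. 2-D
clustering runs directly on compounds, so a compound lands in at most one
cluster per UID. 3-D clustering runs on the <= N_max diverse conformers per
compound; the conformer clusters are then collapsed to compound clusters,
which lets one compound occur in several clusters of the same UID via
different conformers. Clusters whose distinct-compound count is below two
(including multi-conformer single-compound clusters) are singletons and are
removed from outputs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .chem_io import Conformer, Fingerprint
from .contexts import Context
from .similarity import OptMode, ScoreCache, conformer_pair_score, select_diverse_conformers, tanimoto_2d
from .thresholds import DEFAULT_THRESHOLDS, Measure

logger = logging.getLogger("sarclust")


@dataclass
class Cluster:
    """One SAR cluster: an ordered set of compounds (plus their conformers for
    3-D clusters) with the representative chosen at formation."""

    members_compounds: tuple[int, ...]
    members_conformers: tuple[tuple[int, int], ...] = ()
    representative: object = None
    context: Optional[Context] = None
    measure: Optional[Measure] = None
    uid: Optional[int] = None

    @property
    def n_compounds(self) -> int:
        return len(set(self.members_compounds))

    @property
    def is_conformer_level(self) -> bool:
        return len(self.members_conformers) > 0

    @property
    def items(self) -> tuple:
        """The clustered items: conformer ids for 3-D, compound ids for 2-D."""
        return self.members_conformers if self.is_conformer_level else tuple(
            self.members_compounds
        )


def subtype_registry() -> list[tuple[Context, Measure]]:
    """All cluster subtypes the pipeline produces: every bioactivity context
    crossed with every structural similarity measure (3 x 5 = 15)."""
    return [(ctx, m) for ctx in Context for m in Measure]


def _as_cluster(items: Sequence, representative) -> Cluster:
    if items and isinstance(items[0], tuple):
        conformers = tuple(items)
        compounds = tuple(dict.fromkeys(cid for cid, _ in conformers))
        return Cluster(compounds, conformers, representative)
    return Cluster(tuple(items), (), representative)


def taylor_butina(
    items: Sequence,
    distance: Callable,
    d_thresh: float,
    strict_boundary: bool = False,
    check: bool = True,
) -> list[Cluster]:
    """Leader-algorithm exclusion clustering; returns clusters incl. singletons.

    ``items`` are distinct, mutually comparable ids (ints, or (compound,
    conformer) tuples); ``distance`` is a symmetric pairwise provider with
    values in [0, 1]. Membership is distance <= d_thresh (strict ``<`` with
    ``strict_boundary``). Ties in neighbor count go to the smallest id. The
    output clusters are disjoint and cover all items. A sampled symmetry and
    range check on the provider raises on violation.
    """
    items = list(items)
    if len(set(items)) != len(items):
        raise ValueError("items must be distinct")
    n = len(items)
    if n == 0:
        return []
    items = sorted(items)  # ascending ids: argmax ties -> smallest id

    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(distance(items[i], items[j]))
            dmat[i, j] = dmat[j, i] = d
    if check and n >= 2:
        rng = np.random.default_rng(0)
        k = min(20, n * (n - 1) // 2)
        for _ in range(k):
            i, j = rng.choice(n, size=2, replace=False)
            back = float(distance(items[j], items[i]))
            if not (0.0 <= back <= 1.0) or not (0.0 <= dmat[i, j] <= 1.0):
                raise ValueError("distance out of [0, 1]")
            if abs(back - dmat[i, j]) > 1e-9:
                raise ValueError(
                    f"asymmetric distance between {items[i]} and {items[j]}"
                )

    if strict_boundary:
        adjacency = dmat < d_thresh
    else:
        adjacency = dmat <= d_thresh
    np.fill_diagonal(adjacency, False)

    unassigned = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while True:
        counts = np.where(unassigned, (adjacency & unassigned[None, :]).sum(axis=1), -1)
        rep = int(np.argmax(counts))  # first max = smallest id (sorted order)
        if counts[rep] <= 0:
            break
        member_ix = np.flatnonzero(adjacency[rep] & unassigned)
        group = sorted([rep] + list(member_ix))
        unassigned[group] = False
        clusters.append(_as_cluster([items[i] for i in group], items[rep]))
    for i in np.flatnonzero(unassigned):
        clusters.append(_as_cluster([items[i]], items[i]))
    return clusters


def collapse_conformer_clusters(clusters: Sequence[Cluster]) -> list[Cluster]:
    """Replace conformers with their compounds, deduplicated, preserving
    cluster identity: distinct conformer clusters stay distinct even when
    their compound sets coincide or nest, so a compound can occur in several
    compound clusters via different conformers."""
    out = []
    for cl in clusters:
        if not cl.is_conformer_level:
            out.append(cl)
            continue
        compounds = tuple(dict.fromkeys(cid for cid, _ in cl.members_conformers))
        rep = cl.representative
        rep_compound = rep[0] if isinstance(rep, tuple) else rep
        out.append(
            Cluster(compounds, cl.members_conformers, rep_compound,
                    cl.context, cl.measure, cl.uid)
        )
    return out


def remove_singletons(clusters: Sequence[Cluster]) -> list[Cluster]:
    """Drop clusters with fewer than two distinct compounds (a 3-D cluster of
    several conformers of one compound is still a singleton)."""
    kept = [cl for cl in clusters if cl.n_compounds >= 2]
    removed = len(clusters) - len(kept)
    if removed:
        logger.info("removed %d singleton cluster(s)", removed)
    return kept


def measure_distance(
    measure: Measure,
    fingerprints: Optional[Mapping[int, Fingerprint]] = None,
    conformer_lookup: Optional[Mapping[tuple[int, int], Conformer]] = None,
    cache: Optional[ScoreCache] = None,
) -> Callable:
    """Distance provider for one measure: 1 - similarity, with ComboT scores
    divided by 2 first so every distance lives in [0, 1]."""
    if measure is Measure.TANIMOTO_2D:
        if fingerprints is None:
            raise ValueError("2-D distance needs fingerprints")

        def dist2d(a: int, b: int) -> float:
            return 1.0 - tanimoto_2d(fingerprints[a], fingerprints[b])

        return dist2d

    if conformer_lookup is None:
        raise ValueError("3-D distance needs conformers")
    mode = measure.opt_mode

    def dist3d(a: tuple[int, int], b: tuple[int, int]) -> float:
        st, ct, combo = conformer_pair_score(
            conformer_lookup[a], conformer_lookup[b], mode, cache
        )
        sim = measure.score_from(st, ct, combo) / measure.norm
        return min(max(1.0 - sim, 0.0), 1.0)

    return dist3d


def cluster_context(
    uid: int,
    compounds: Sequence[int],
    measure: Measure | str,
    thresholds: Optional[Mapping[Measure, float]] = None,
    fingerprints: Optional[Mapping[int, Fingerprint]] = None,
    conformers: Optional[Mapping[int, Sequence[Conformer]]] = None,
    cache: Optional[ScoreCache] = None,
    n_max: int = 10,
    context: Optional[Context] = None,
    strict_boundary: bool = False,
) -> list[Cluster]:
    """Cluster the non-inactive compounds of one UID under one measure.

    2-D: items are the compounds themselves; results are singleton-filtered,
    and each compound appears in at most one cluster. 3-D: items are the
    <= n_max diverse conformers of each compound; conformer clusters are
    collapsed to compound clusters and then singleton-filtered.
    """
    measure = Measure(measure)
    thresholds = thresholds or DEFAULT_THRESHOLDS
    d_thresh = thresholds[measure]
    compounds = sorted(set(compounds))
    if len(compounds) < 2:
        logger.info("UID %s: fewer than two compounds, no clusters", uid)
        return []

    if measure is Measure.TANIMOTO_2D:
        dist = measure_distance(measure, fingerprints=fingerprints)
        raw = taylor_butina(compounds, dist, d_thresh, strict_boundary)
        clusters = raw
    else:
        if conformers is None:
            raise ValueError("3-D clustering needs conformers")
        lookup: dict[tuple[int, int], Conformer] = {}
        items: list[tuple[int, int]] = []
        for cid in compounds:
            for conf in select_diverse_conformers(conformers[cid], n_max):
                key = (conf.compound_id, conf.conformer_index)
                lookup[key] = conf
                items.append(key)
        dist = measure_distance(measure, conformer_lookup=lookup, cache=cache)
        raw = taylor_butina(items, dist, d_thresh, strict_boundary)
        clusters = collapse_conformer_clusters(raw)

    for cl in clusters:
        cl.context, cl.measure, cl.uid = context, measure, uid
    return remove_singletons(clusters)
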