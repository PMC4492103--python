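"""Deterministic synthetic data generator for the whole pipeline.

The generator plants a known group structure ("scaffolds") so that clustering
results can be checked against ground truth without downloading anything:

* each scaffold is a parametric 3-D heavy-atom template with a distinctive
  overall shape (extended chain, compact drum, planar ring, L-shape) and a
  scaffold-specific pharmacophoric element planted on a few atoms, so both
  shape and color similarity separate scaffolds;
* compounds of one scaffold are jittered copies with one atom substitution
  (structurally similar, hence meant to co-cluster);
* conformers are rigid rotations/translations of each compound with a small
  torsion-like perturbation (so the superposition optimizer has real work);
* fingerprints are synthetic: each scaffold owns a disjoint bit block, each
  compound perturbs its scaffold pattern by two bits, so intra-scaffold
  2-D Tanimoto stays well above the clustering threshold and inter-scaffold
  similarity is zero;
* the activity table marks scaffold members non-inactive in their scaffold's
  assays, with an inactive/unspecified admixture at the requested rates; the
  first assay is a screening panel that tests every compound, so at least one
  UID co-tests all scaffolds;
* annotation tables wire assays to proteins (with one duplicated sequence to
  exercise protein-identity grouping) and proteins to pathways; a fraction of
  compounds get sub-10 µM potencies and MeSH / pharmacological-action flags.

Fixture molecules are geometric, valence-relaxed point molecules: 3-D scoring
needs geometry, not chemistry. A few real SMILES are packaged separately for
fingerprint and feature-typing tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem_io import (
    ActivityRecord,
    AnnotationTables,
    CompoundFlags,
    Conformer,
    Fingerprint,
    Outcome,
    PotencyType,
    write_activity_table,
    write_annotations,
    write_conformers,
    write_fingerprints,
)
from .similarity import FeatureAtom, FeatureType

#: Real molecules for fingerprint / feature-typing tests.
TEST_SMILES = {
    "benzene": "c1ccccc1",
    "acetate": "CC(=O)[O-]",
    "ethane": "CC",
    "sulfamide": "NS(=O)(=O)N",
    "toluene": "Cc1ccccc1",
    "methylamine": "CN",
}

#: Element -> planted feature type for fixture (bond-less) molecules.
PLANTED_FEATURE_ELEMENTS = {
    "N": FeatureType.DONOR,
    "O": FeatureType.ACCEPTOR,
    "P": FeatureType.CATION,
    "S": FeatureType.ANION,
}

_FEATURE_CYCLE = ["N", "O", "P", "S"]
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FixtureSpec:
    """Shape of one synthetic dataset; all outputs reproducible from seed."""

    seed: int = 17
    n_scaffolds: int = 2
    compounds_per_scaffold: int = 4
    conformers_per_compound: int = 3
    n_assays: int = 4
    assays_per_scaffold: int = 1
    fraction_inactive: float = 0.15
    n_gis: int = 2
    gis_per_bsid: int = 2
    hvc_fraction: float = 0.25
    noise_jitter_A: float = 0.05

    def __post_init__(self) -> None:
        for name in ("n_scaffolds", "compounds_per_scaffold",
                     "conformers_per_compound", "n_assays",
                     "assays_per_scaffold", "n_gis", "gis_per_bsid"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 1 <= self.conformers_per_compound <= 20:
            raise ValueError("conformers_per_compound must be in 1..20")
        for name in ("fraction_inactive", "hvc_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class FixtureData:
    """In-memory fixture: everything the pipeline consumes, plus the planted
    scaffold labels for recovery checks."""

    conformers: list[Conformer]
    fingerprints: list[Fingerprint]
    records: list[ActivityRecord]
    annotations: AnnotationTables
    labels: dict[int, int] = field(default_factory=dict)
    n_bits: int = 0

    def conformers_by_compound(self) -> dict[int, list[Conformer]]:
        out: dict[int, list[Conformer]] = {}
        for conf in self.conformers:
            out.setdefault(conf.compound_id, []).append(conf)
        return out

    def fingerprints_by_compound(self) -> dict[int, Fingerprint]:
        return {fp.compound_id: fp for fp in self.fingerprints}


def assign_planted_features(conformer: Conformer) -> Conformer:
    """Fill feature atoms of a fixture conformer from its planted elements
    (N→donor, O→acceptor, P→cation, S→anion); carbons carry no feature."""
    feats = []
    for el, pos in zip(conformer.elements, conformer.coords):
        ftype = PLANTED_FEATURE_ELEMENTS.get(el)
        if ftype is not None:
            feats.append(FeatureAtom(ftype, pos))
    conformer.feature_atoms = feats
    return conformer


def _scaffold_template(k: int) -> tuple[list[str], np.ndarray]:
    """Heavy-atom template for scaffold ``k``: one of four distinctive shapes,
    with the scaffold's pharmacophoric element planted on three atoms."""
    shape = k % 4
    scale = 1.0 + 0.12 * (k // 4)  # keep extra scaffolds distinguishable
    if shape == 0:  # extended zigzag chain
        n = 12
        coords = np.array(
            [[1.4 * i, 0.5 * (-1) ** i, 0.0] for i in range(n)]
        )
    elif shape == 1:  # compact two-ring drum
        ring = np.array(
            [[1.6 * np.cos(t), 1.6 * np.sin(t), 0.0]
             for t in np.linspace(0, 2 * np.pi, 7)[:-1]]
        )
        top = ring + [0.0, 0.0, 1.2]
        bottom = (ring @ _rot_z(np.pi / 6).T) - [0.0, 0.0, 1.2]
        coords = np.vstack([top, bottom])
        n = len(coords)
    elif shape == 2:  # planar ring
        n = 10
        coords = np.array(
            [[2.6 * np.cos(t), 2.6 * np.sin(t), 0.0]
             for t in np.linspace(0, 2 * np.pi, n + 1)[:-1]]
        )
    else:  # L-shape
        arm1 = np.array([[1.4 * i, 0.0, 0.0] for i in range(6)])
        arm2 = np.array([[0.0, 1.4 * (i + 1), 0.0] for i in range(6)])
        coords = np.vstack([arm1, arm2])
        n = len(coords)
    coords = coords * scale
    elements = ["C"] * n
    fel = _FEATURE_CYCLE[k % len(_FEATURE_CYCLE)]
    for idx in (0, n // 2, n - 1):
        elements[idx] = fel
    return elements, coords


def _rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _torsion_perturb(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Bend the last third of the atom list about an internal axis by a small
    angle — a cheap stand-in for a torsional degree of freedom."""
    coords = coords.copy()
    pivot = 2 * len(coords) // 3
    if pivot < 2 or pivot >= len(coords) - 1:
        return coords
    axis = coords[pivot] - coords[pivot - 1]
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        return coords
    axis = axis / norm
    angle = rng.uniform(-0.12, 0.12)  # radians, ~7 degrees max
    c, s = np.cos(angle), np.sin(angle)
    k = axis
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    rot = np.eye(3) + s * kx + (1 - c) * (kx @ kx)
    origin = coords[pivot]
    coords[pivot:] = (coords[pivot:] - origin) @ rot.T + origin
    return coords


def generate_fixture(spec: FixtureSpec) -> FixtureData:
    """Generate the full synthetic dataset described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n_bits = 64 * spec.n_scaffolds
    conformers: list[Conformer] = []
    fingerprints: list[Fingerprint] = []
    labels: dict[int, int] = {}

    scaffold_fp = []
    for s in range(spec.n_scaffolds):
        bits = np.zeros(n_bits, dtype=np.uint8)
        block = rng.permutation(64)[:40] + 64 * s
        bits[block] = 1
        scaffold_fp.append(bits)

    cid = 0
    for s in range(spec.n_scaffolds):
        elements, template = _scaffold_template(s)
        for _ in range(spec.compounds_per_scaffold):
            cid += 1
            labels[cid] = s
            base = template + rng.normal(
                scale=spec.noise_jitter_A, size=template.shape
            )
            elems = list(elements)
            # 1-atom substitution: toggle one non-anchor position between C
            # and the scaffold's feature element
            sub = int(rng.integers(1, len(elems) - 1))
            fel = _FEATURE_CYCLE[s % len(_FEATURE_CYCLE)]
            elems[sub] = fel if elems[sub] == "C" else "C"
            for j in range(1, spec.conformers_per_compound + 1):
                coords = _torsion_perturb(base, rng)
                coords = coords @ _random_rotation(rng).T
                coords = coords + rng.uniform(-5, 5, size=3)
                coords = coords + rng.normal(scale=0.02, size=coords.shape)
                conf = Conformer(cid, j, list(elems), coords)
                assign_planted_features(conf)
                conformers.append(conf)
            bits = scaffold_fp[s].copy()
            on = np.flatnonzero(bits[64 * s: 64 * s + 64]) + 64 * s
            off = np.flatnonzero(bits[64 * s: 64 * s + 64] == 0) + 64 * s
            bits[rng.choice(on, size=2, replace=False)] = 0
            bits[rng.choice(off, size=2, replace=False)] = 1
            fingerprints.append(Fingerprint(cid, bits))

    n_compounds = cid
    all_cids = list(range(1, n_compounds + 1))

    # activity: assay 9001 is the all-compound screening panel; assay 9001+j
    # (j >= 1) tests scaffold (j-1) % n_scaffolds
    records: list[ActivityRecord] = []

    def sample_outcome(force_non_inactive: bool) -> Outcome:
        if spec.fraction_inactive >= 1.0:
            return Outcome.INACTIVE
        if not force_non_inactive and rng.random() < spec.fraction_inactive:
            return Outcome.INACTIVE
        r = rng.random()
        if r < 0.6:
            return Outcome.ACTIVE
        if r < 0.9:
            return Outcome.UNSPECIFIED
        return Outcome.INCONCLUSIVE

    for c in all_cids:
        records.append(ActivityRecord(c, 9001, sample_outcome(True)))
    for j in range(1, spec.n_assays):
        aid = 9001 + j
        s = (j - 1) % spec.n_scaffolds
        members = [c for c in all_cids if labels[c] == s]
        for i, c in enumerate(members):
            records.append(ActivityRecord(c, aid, sample_outcome(i == 0)))

    # annotations: assays -> GIs (round robin), GIs -> BSIDs (grouped),
    # one duplicated protein sequence to exercise PIG merging
    gis = [501 + i for i in range(spec.n_gis)]
    assay_to_gi = {
        9001 + j: frozenset({gis[j % spec.n_gis]}) for j in range(spec.n_assays)
    }
    sequences = {
        gi: "".join(rng.choice(list(_AA), size=30)) for gi in gis
    }
    if spec.n_gis >= 2:
        sequences[gis[1]] = sequences[gis[0]]
    gi_to_bsid = {
        gi: frozenset({7001 + i // spec.gis_per_bsid}) for i, gi in enumerate(gis)
    }

    compound_flags: dict[int, CompoundFlags] = {}
    n_hvc = int(round(spec.hvc_fraction * n_compounds))
    hvc_cids = sorted(rng.choice(all_cids, size=n_hvc, replace=False)) if n_hvc else []
    for i, c in enumerate(hvc_cids):
        if spec.fraction_inactive < 1.0:  # keep the all-inactive case degenerate
            records.append(
                ActivityRecord(
                    int(c), 9001, Outcome.ACTIVE,
                    PotencyType.IC50 if i % 2 == 0 else PotencyType.EC50,
                    float(rng.uniform(0.05, 9.5)),
                )
            )
        has_mesh = i % 2 == 0
        compound_flags[int(c)] = CompoundFlags(
            has_mesh=has_mesh, has_pharm_action=has_mesh and i % 4 == 0
        )

    annotations = AnnotationTables(
        assay_to_gi=assay_to_gi,
        gi_to_sequence=sequences,
        gi_to_bsid=gi_to_bsid,
        compound_flags=compound_flags,
    )
    return FixtureData(conformers, fingerprints, records, annotations,
                       labels, n_bits)


def write_fixture(spec: FixtureSpec, outdir) -> FixtureData:
    """Generate a fixture and write it to disk (SDF + tables); byte-identical
    for identical spec and seed."""
    data = generate_fixture(spec)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_conformers(data.conformers, outdir / "conformers.sdf")
    write_fingerprints(data.fingerprints, outdir / "fingerprints.tsv")
    write_activity_table(data.records, outdir / "activity.tsv")
    write_annotations(data.annotations, outdir)
    with open(outdir / "labels.tsv", "w", encoding="utf-8") as fh:
        fh.write("compound_id\tscaffold\n")
        for cid in sorted(data.labels):
            fh.write(f"{cid}\t{data.labels[cid]}\n")
    return data


def two_conformer_family_fixture(
    seed: int = 11, n_compounds: int = 3
) -> FixtureData:
    """Compounds whose conformers fall into two geometric families (folded vs
    extended). 3-D clustering should put each family in its own conformer
    cluster, so after collapse every compound occurs in two compound clusters,
    while 2-D clustering (near-identical fingerprints) yields exactly one."""
    rng = np.random.default_rng(seed)
    elements = ["C"] * 10
    elements[0] = elements[9] = "N"
    extended = np.array([[1.4 * i, 0.5 * (-1) ** i, 0.0] for i in range(10)])
    folded = np.array(
        [[2.2 * np.cos(t), 2.2 * np.sin(t), 0.3 * (-1) ** i]
         for i, t in enumerate(np.linspace(0, 2 * np.pi, 11)[:-1])]
    )
    conformers: list[Conformer] = []
    fingerprints: list[Fingerprint] = []
    base_bits = np.zeros(64, dtype=np.uint8)
    base_bits[rng.permutation(64)[:40]] = 1
    records: list[ActivityRecord] = []
    for cid in range(1, n_compounds + 1):
        for j, template in ((1, extended), (2, folded)):
            coords = template + rng.normal(scale=0.05, size=template.shape)
            coords = coords @ _random_rotation(rng).T + rng.uniform(-4, 4, 3)
            conf = Conformer(cid, j, list(elements), coords)
            assign_planted_features(conf)
            conformers.append(conf)
        bits = base_bits.copy()
        flip = rng.choice(64, size=1)
        bits[flip] = 1 - bits[flip]
        fingerprints.append(Fingerprint(cid, bits))
        records.append(ActivityRecord(cid, 9001, Outcome.ACTIVE))
    return FixtureData(conformers, fingerprints, records, AnnotationTables(),
                       {c: 0 for c in range(1, n_compounds + 1)}, 64)


#: Outcome counts (active, inactive, inconclusive, unspecified) per assay of a
#: synthetic 13-assay single-protein panel shaped like a receptor studied
#: across three publications: eight reporter/blot assays, four dose-series
#: assays, one transactivation assay.
AHR_LIKE_ASSAY_COUNTS: dict[int, tuple[int, int, int, int]] = {
    431863: (0, 0, 0, 7),
    431864: (0, 1, 0, 0),
    431865: (0, 1, 0, 0),
    431866: (0, 1, 0, 0),
    431867: (0, 1, 0, 0),
    431868: (2, 0, 0, 0),
    431869: (2, 0, 0, 0),
    431870: (2, 0, 0, 0),
    490160: (0, 0, 0, 15),
    490161: (0, 0, 0, 10),
    490162: (0, 0, 0, 4),
    490163: (0, 0, 0, 3),
    631103: (1, 0, 0, 4),
}

AHR_LIKE_GI = 29337198

# assay -> (compound pool start, pool offset of first tested cid)
_AHR_POOLS = {
    431863: 101, 431864: 101, 431865: 101, 431866: 101, 431867: 101,
    431868: 101, 431869: 101, 431870: 101,
    490160: 201, 490161: 201, 490162: 201, 490163: 201,
    631103: 301,
}


def records_from_outcome_counts(
    assay_id: int,
    active: int = 0,
    inactive: int = 0,
    inconclusive: int = 0,
    unspecified: int = 0,
    start_cid: int = 1,
) -> list[ActivityRecord]:
    """Expand per-assay outcome counts into individual activity records
    (compound ids assigned sequentially from ``start_cid``)."""
    records = []
    cid = start_cid
    for outcome, count in (
        (Outcome.ACTIVE, active),
        (Outcome.INACTIVE, inactive),
        (Outcome.INCONCLUSIVE, inconclusive),
        (Outcome.UNSPECIFIED, unspecified),
    ):
        for _ in range(count):
            records.append(ActivityRecord(cid, assay_id, outcome))
            cid += 1
    return records


def ahr_like_fixture() -> tuple[list[ActivityRecord], AnnotationTables]:
    """Synthetic trans-assay protein panel: 13 assays, all targeting one
    protein sequence (one GI, hence one PIG), with mixed active/unspecified
    outcomes, to exercise protein-centric aggregation across assays. One
    compound (the reference agonist) is tested in two publication groups."""
    records: list[ActivityRecord] = []
    for aid, (act, inact, inc, unsp) in AHR_LIKE_ASSAY_COUNTS.items():
        records.extend(
            records_from_outcome_counts(
                aid, act, inact, inc, unsp, start_cid=_AHR_POOLS[aid]
            )
        )
    # reference agonist shared between the first and last publication group
    records.append(ActivityRecord(101, 631103, Outcome.ACTIVE))
    annotations = AnnotationTables(
        assay_to_gi={aid: frozenset({AHR_LIKE_GI}) for aid in AHR_LIKE_ASSAY_COUNTS},
        gi_to_sequence={AHR_LIKE_GI: "MSSNAN" + "K" * 24},
        gi_to_bsid={},
    )
    return records, annotations
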