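"""Readers and writers for the external formats of the SAR-clustering pipeline.

Structures travel as multi-record SDF (one record per conformer, compound id
and local conformer index carried as SD properties, PubChem-style);
fingerprints as a two-column hex text table; activity outcomes and annotation
maps as delimited tables; clusters as a delimited table with one row per
cluster. All writers emit UTF-8, tab-delimited by default.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Geometry import Point3D

logger = logging.getLogger("sarclust")
RDLogger.DisableLog("rdApp.warning")

DEFAULT_CID_PROP = "PUBCHEM_COMPOUND_CID"
DEFAULT_CONFORMER_PROP = "PUBCHEM_CONFORMER_ID"


class Outcome(str, Enum):
    """Depositor-assigned activity outcome of a compound in one assay."""

    ACTIVE = "active"
    INACTIVE = "inactive"
    INCONCLUSIVE = "inconclusive"
    UNSPECIFIED = "unspecified"


class PotencyType(str, Enum):
    IC50 = "IC50"
    EC50 = "EC50"


@dataclass
class Conformer:
    """One 3-D instance of a compound: heavy atoms only, coordinates in Å.

    ``feature_atoms`` (pharmacophoric color atoms) start empty and are filled
    by :func:`sarclust.similarity.assign_feature_atoms` or by a fixture
    generator.
    """

    compound_id: int
    conformer_index: int
    elements: list[str]
    coords: np.ndarray
    feature_atoms: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.compound_id < 1 or self.conformer_index < 1:
            raise ValueError("compound_id and conformer_index must be positive")
        if len(self.elements) == 0:
            raise ValueError("empty molecule: a conformer needs >=1 heavy atom")
        if len(self.elements) != len(self.coords):
            raise ValueError("elements and coords must have the same length")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass
class Fingerprint:
    """Fixed-length binary substructure-key vector for one compound."""

    compound_id: int
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1:
            raise ValueError("bits must be a 1-D vector")
        if not np.all((self.bits == 0) | (self.bits == 1)):
            raise ValueError("bits must be binary")

    @property
    def n_bits(self) -> int:
        return int(self.bits.size)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


@dataclass
class ActivityRecord:
    """Outcome of testing one compound in one assay, with optional potency."""

    compound_id: int
    assay_id: int
    outcome: Outcome
    potency_type: Optional[PotencyType] = None
    potency_um: Optional[float] = None

    def __post_init__(self) -> None:
        self.outcome = Outcome(self.outcome)
        if self.potency_type is not None:
            self.potency_type = PotencyType(self.potency_type)
        if (self.potency_um is None) != (self.potency_type is None):
            raise ValueError("potency_um and potency_type must come together")
        if self.potency_um is not None and self.potency_um <= 0:
            raise ValueError("potency_um must be positive")


@dataclass
class CompoundFlags:
    has_mesh: bool = False
    has_pharm_action: bool = False


@dataclass
class AnnotationTables:
    """Assay→protein→pathway wiring plus per-compound annotation flags.

    ``assay_to_gi`` maps an assay id (AID) to the protein sequence ids (GIs)
    of its targets; ``gi_to_sequence`` / ``gi_to_pig`` support protein
    identity group (PIG) disambiguation; ``gi_to_bsid`` maps proteins to
    pathway ids (BSIDs); ``compound_flags`` carries MeSH / Pharmacological
    Action annotations used for high-value-compound tagging.
    """

    assay_to_gi: dict[int, frozenset[int]] = field(default_factory=dict)
    gi_to_sequence: Optional[dict[int, str]] = None
    gi_to_pig: Optional[dict[int, int]] = None
    gi_to_bsid: dict[int, frozenset[int]] = field(default_factory=dict)
    compound_flags: dict[int, CompoundFlags] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Conformer (SDF) I/O
# ---------------------------------------------------------------------------

def read_conformers(
    path,
    cid_prop: str = DEFAULT_CID_PROP,
    conformer_prop: str = DEFAULT_CONFORMER_PROP,
    sequential_ids: bool = False,
) -> list[Conformer]:
    """Read a multi-record SDF into Conformers (hydrogens discarded).

    Each record must carry the compound id and local conformer index as SD
    properties unless ``sequential_ids`` is set, in which case record ``k``
    becomes compound ``k`` / conformer 1. Records are returned grouped by
    compound id and ordered by conformer index.
    """
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    out: list[Conformer] = []
    seen: set[tuple[int, int]] = set()
    for ordinal, mol in enumerate(supplier, start=1):
        if mol is None:
            raise ValueError(f"malformed SDF record #{ordinal}")
        if mol.HasProp(cid_prop) and mol.HasProp(conformer_prop):
            cid = int(mol.GetProp(cid_prop))
            cix = int(mol.GetProp(conformer_prop))
        elif sequential_ids:
            cid, cix = ordinal, 1
        else:
            raise ValueError(
                f"SDF record #{ordinal} lacks '{cid_prop}'/'{conformer_prop}' "
                "properties (pass sequential_ids=True to number records)"
            )
        if mol.GetNumConformers() == 0:
            raise ValueError(f"SDF record #{ordinal} has no coordinates")
        pos = mol.GetConformer().GetPositions()
        elements, coords = [], []
        for atom in mol.GetAtoms():
            if atom.GetAtomicNum() > 1:
                elements.append(atom.GetSymbol())
                coords.append(pos[atom.GetIdx()])
        if not elements:
            raise ValueError(f"empty molecule in SDF record #{ordinal}")
        if (cid, cix) in seen:
            raise ValueError(
                f"duplicate (compound {cid}, conformer {cix}) at record #{ordinal}"
            )
        seen.add((cid, cix))
        out.append(Conformer(cid, cix, elements, np.array(coords)))
    out.sort(key=lambda c: (c.compound_id, c.conformer_index))
    return out


def write_conformers(
    conformers: Iterable[Conformer],
    path,
    cid_prop: str = DEFAULT_CID_PROP,
    conformer_prop: str = DEFAULT_CONFORMER_PROP,
) -> None:
    """Write Conformers as a bond-less heavy-atom V2000 SDF (4-decimal Å)."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for conf in conformers:
            rw = Chem.RWMol()
            for el in conf.elements:
                atom = Chem.Atom(el)
                atom.SetNoImplicit(True)
                rw.AddAtom(atom)
            c3d = Chem.Conformer(conf.n_atoms)
            for i, xyz in enumerate(conf.coords):
                c3d.SetAtomPosition(i, Point3D(*map(float, xyz)))
            mol = rw.GetMol()
            mol.AddConformer(c3d)
            mol.UpdatePropertyCache(strict=False)
            mol.SetProp("_Name", f"CID{conf.compound_id}_{conf.conformer_index}")
            mol.SetProp(cid_prop, str(conf.compound_id))
            mol.SetProp(conformer_prop, str(conf.conformer_index))
            writer.write(mol)
    finally:
        writer.close()


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES into an RDKit molecule (connection table carrier)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return mol


def read_molecules(path) -> list[Chem.Mol]:
    """Read sanitized RDKit molecules (with connection tables) from an SDF."""
    mols = []
    for ordinal, mol in enumerate(Chem.SDMolSupplier(str(path), removeHs=False), 1):
        if mol is None:
            raise ValueError(f"malformed SDF record #{ordinal}")
        mols.append(mol)
    return mols


# ---------------------------------------------------------------------------
# Fingerprint I/O and computation
# ---------------------------------------------------------------------------

def read_fingerprints(path, n_bits: Optional[int] = None) -> list[Fingerprint]:
    """Read 'compound_id<TAB>hex' rows into Fingerprints.

    Hex is decoded most-significant-bit first within each byte, so row
    ``"5\\tf0"`` with an 8-bit key set yields bits 0–3 set. All rows must
    decode to the same length; ``n_bits`` trims byte-padding for key sets
    whose length is not a multiple of 8.
    """
    fps: list[Fingerprint] = []
    length: Optional[int] = None
    with open(path, "r", encoding="utf-8") as fh:
        for row_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"fingerprint row {row_no}: expected 2 columns")
            cid_s, hexs = parts
            if len(hexs) % 2 != 0:
                raise ValueError(f"fingerprint row {row_no}: odd-length hex string")
            try:
                raw = bytes.fromhex(hexs)
            except ValueError as exc:
                raise ValueError(f"fingerprint row {row_no}: {exc}") from exc
            bits = np.unpackbits(np.frombuffer(raw, dtype=np.uint8), bitorder="big")
            if n_bits is not None:
                if len(bits) < n_bits or len(bits) - n_bits >= 8:
                    raise ValueError(
                        f"fingerprint row {row_no}: decoded length {len(bits)} "
                        f"inconsistent with n_bits={n_bits}"
                    )
                bits = bits[:n_bits]
            if length is None:
                length = len(bits)
            elif len(bits) != length:
                raise ValueError(
                    f"fingerprint row {row_no}: length {len(bits)} != {length} "
                    "of earlier rows"
                )
            fps.append(Fingerprint(int(cid_s), bits))
    return fps


def write_fingerprints(fps: Iterable[Fingerprint], path) -> None:
    """Write Fingerprints as 'compound_id<TAB>hex' (MSB-first, zero-padded)."""
    with open(path, "w", encoding="utf-8") as fh:
        for fp in fps:
            packed = np.packbits(fp.bits, bitorder="big")
            fh.write(f"{fp.compound_id}\t{packed.tobytes().hex()}\n")


class KeySet:
    """Ordered dictionary of substructure keys (SMARTS + match-count threshold).

    Bit ``k`` of a fingerprint is set iff the molecule contains at least
    ``count_k`` distinct embeddings of pattern ``k``. Patterns are compiled at
    construction so a bad SMARTS fails at load time, not match time.
    """

    def __init__(self, keys: Sequence[tuple[str, int]]):
        self.smarts = [s for s, _ in keys]
        self.counts = [int(c) for _, c in keys]
        self.patterns = []
        for s, _ in keys:
            patt = Chem.MolFromSmarts(s)
            if patt is None:
                raise ValueError(f"unparsable SMARTS key: {s!r}")
            self.patterns.append(patt)

    def __len__(self) -> int:
        return len(self.patterns)


# Compact default key dictionary: element/charge/ring/functional-group keys
# ordered roughly as substructure-key sets in the field are (element counts
# first, rings, then functional groups). 64 keys so fingerprints pack to hex
# without padding. Any other key set (or precomputed fingerprints) may be
# supplied instead.
_DEFAULT_KEYS: list[tuple[str, int]] = [
    ("[#6]", 1), ("[#6]", 2), ("[#6]", 4), ("[#6]", 8),
    ("[#6]", 16), ("[#6]", 24), ("[#6]", 32), ("[#7]", 1),
    ("[#7]", 2), ("[#7]", 4), ("[#8]", 1), ("[#8]", 2),
    ("[#8]", 4), ("[#16]", 1), ("[#16]", 2), ("[#15]", 1),
    ("[F,Cl,Br,I]", 1), ("[F,Cl,Br,I]", 2), ("[F]", 1), ("[Cl]", 1),
    ("[Br]", 1), ("[I]", 1), ("[+]", 1), ("[-]", 1),
    ("[#1]", 1), ("[CH3]", 1), ("[CH3]", 2), ("[CH2]", 2),
    ("a", 1), ("a", 6), ("a", 10), ("c1ccccc1", 1),
    ("c1ccccc1", 2), ("[r3]", 1), ("[r4]", 1), ("[r5]", 1),
    ("[r6]", 1), ("[r7]", 1), ("[R2]", 1), ("n", 1),
    ("o", 1), ("s", 1), ("C=O", 1), ("C=O", 2),
    ("[CX3](=O)[OX2H1]", 1), ("[CX3](=O)[O-]", 1), ("[CX3](=O)[OX2][#6]", 1), ("[CX3](=O)[NX3]", 1),
    ("[OX2H]", 1), ("[OX2H]", 2), ("[OX2]([#6])[#6]", 1), ("[NX3;H2]", 1),
    ("[NX3;H1]", 1), ("[NX3;H0]([#6])([#6])[#6]", 1), ("C#N", 1), ("[SX2H]", 1),
    ("S(=O)(=O)", 1), ("S(=O)(=O)N", 1), ("[NX3][CX3]=[NX3+]", 1), ("N=N", 1),
    ("[N+](=O)[O-]", 1), ("C=C", 1), ("C#C", 1), ("[#6]~[#7]~[#6]", 1),
]

_default_key_set: Optional[KeySet] = None


def default_key_set() -> KeySet:
    global _default_key_set
    if _default_key_set is None:
        _default_key_set = KeySet(_DEFAULT_KEYS)
    return _default_key_set


def compute_fingerprint(
    mol: Chem.Mol, key_set: Optional[KeySet] = None, compound_id: int = 1
) -> Fingerprint:
    """Evaluate a substructure-key fingerprint on a connection table.

    Deterministic for a fixed key set; invariant under atom renumbering
    because substructure match counting does not depend on atom order.
    """
    if key_set is None:
        key_set = default_key_set()
    molh = Chem.AddHs(mol)
    bits = np.zeros(len(key_set), dtype=np.uint8)
    for k, (patt, count) in enumerate(zip(key_set.patterns, key_set.counts)):
        matches = molh.GetSubstructMatches(patt, uniquify=True, maxMatches=10000)
        if len(matches) >= count:
            bits[k] = 1
    return Fingerprint(compound_id, bits)


# ---------------------------------------------------------------------------
# Activity and annotation tables
# ---------------------------------------------------------------------------

def _sniff_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.readline()
    return "\t" if "\t" in head else ","


def read_activity_table(path, delimiter: Optional[str] = None) -> list[ActivityRecord]:
    """Read a delimited activity table (header: compound_id, assay_id, outcome,
    optional potency_type, potency_um). Outcomes match case-insensitively;
    duplicate (compound, assay) rows are all kept (a compound may have several
    potency rows) with a logged notice."""
    delimiter = delimiter or _sniff_delimiter(path)
    records: list[ActivityRecord] = []
    seen_pairs: set[tuple[int, int]] = set()
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            return []
        cols = {c.strip().lower(): c for c in reader.fieldnames}
        for need in ("compound_id", "assay_id", "outcome"):
            if need not in cols:
                raise ValueError(f"activity table missing column '{need}'")
        for row_no, row in enumerate(reader, start=2):
            raw = row[cols["outcome"]].strip().lower()
            try:
                outcome = Outcome(raw)
            except ValueError:
                raise ValueError(
                    f"activity table row {row_no}: unknown outcome {raw!r}"
                ) from None
            ptype = None
            pval = None
            if "potency_type" in cols and row.get(cols["potency_type"], "").strip():
                ptype = PotencyType(row[cols["potency_type"]].strip().upper())
                pval = float(row[cols["potency_um"]])
            rec = ActivityRecord(
                int(row[cols["compound_id"]]), int(row[cols["assay_id"]]),
                outcome, ptype, pval,
            )
            pair = (rec.compound_id, rec.assay_id)
            if pair in seen_pairs:
                logger.info("duplicate (compound %d, assay %d) row kept", *pair)
            seen_pairs.add(pair)
            records.append(rec)
    return records


def write_activity_table(records: Iterable[ActivityRecord], path, delimiter="\t"):
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["compound_id", "assay_id", "outcome", "potency_type", "potency_um"])
        for r in records:
            w.writerow([
                r.compound_id, r.assay_id, r.outcome.value,
                r.potency_type.value if r.potency_type else "",
                repr(r.potency_um) if r.potency_um is not None else "",
            ])


def _read_int_pairs(path, delimiter: Optional[str] = None) -> list[tuple[int, int]]:
    delimiter = delimiter or _sniff_delimiter(path)
    pairs = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split(delimiter)[:2]
            try:
                pairs.append((int(a), int(b)))
            except ValueError:
                if not pairs:  # header line
                    continue
                raise
    return pairs


def read_gi_sequences(path) -> dict[int, str]:
    """Read GI→protein-sequence, from FASTA (GI parsed from the header, either
    a leading integer or an NCBI-style ``gi|NNN|`` token) or a 2-column TSV."""
    text_head = open(path, "r", encoding="utf-8").readline()
    if text_head.startswith(">"):
        from Bio import SeqIO

        out = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            token = rec.id
            if token.lower().startswith("gi|"):
                gi = int(token.split("|")[1])
            else:
                gi = int(token)
            out[gi] = str(rec.seq)
        return out
    return {gi: seq for gi, seq in _read_str_pairs(path)}


def _read_str_pairs(path):
    delimiter = _sniff_delimiter(path)
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split(delimiter)[:2]
            try:
                yield int(a), b
            except ValueError:
                continue  # header


def read_annotations(
    assay_gi_path=None,
    gi_sequence_path=None,
    gi_pig_path=None,
    gi_bsid_path=None,
    compound_flags_path=None,
) -> AnnotationTables:
    """Assemble AnnotationTables from the individual mapping files."""
    tables = AnnotationTables()
    if assay_gi_path:
        for aid, gi in _read_int_pairs(assay_gi_path):
            tables.assay_to_gi.setdefault(aid, set())
            tables.assay_to_gi[aid] = frozenset(tables.assay_to_gi[aid] | {gi})
    if gi_sequence_path:
        tables.gi_to_sequence = read_gi_sequences(gi_sequence_path)
    if gi_pig_path:
        tables.gi_to_pig = dict(_read_int_pairs(gi_pig_path))
    if gi_bsid_path:
        for gi, bsid in _read_int_pairs(gi_bsid_path):
            tables.gi_to_bsid.setdefault(gi, set())
            tables.gi_to_bsid[gi] = frozenset(tables.gi_to_bsid[gi] | {bsid})
    if compound_flags_path:
        delimiter = _sniff_delimiter(compound_flags_path)
        with open(compound_flags_path, "r", encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh, delimiter=delimiter):
                cid = int(row["compound_id"])
                tables.compound_flags[cid] = CompoundFlags(
                    has_mesh=row.get("has_mesh", "0").strip() in ("1", "true", "True"),
                    has_pharm_action=row.get("has_pharm_action", "0").strip()
                    in ("1", "true", "True"),
                )
    return tables


def write_annotations(tables: AnnotationTables, outdir, delimiter="\t") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "assay_gi.tsv", "w", encoding="utf-8") as fh:
        fh.write("assay_id" + delimiter + "gi\n")
        for aid in sorted(tables.assay_to_gi):
            for gi in sorted(tables.assay_to_gi[aid]):
                fh.write(f"{aid}{delimiter}{gi}\n")
    if tables.gi_to_sequence is not None:
        with open(outdir / "gi_seq.fasta", "w", encoding="utf-8") as fh:
            for gi in sorted(tables.gi_to_sequence):
                fh.write(f">{gi}\n{tables.gi_to_sequence[gi]}\n")
    with open(outdir / "gi_bsid.tsv", "w", encoding="utf-8") as fh:
        fh.write("gi" + delimiter + "bsid\n")
        for gi in sorted(tables.gi_to_bsid):
            for bsid in sorted(tables.gi_to_bsid[gi]):
                fh.write(f"{gi}{delimiter}{bsid}\n")
    with open(outdir / "compound_flags.tsv", "w", encoding="utf-8") as fh:
        fh.write(delimiter.join(["compound_id", "has_mesh", "has_pharm_action"]) + "\n")
        for cid in sorted(tables.compound_flags):
            fl = tables.compound_flags[cid]
            fh.write(
                f"{cid}{delimiter}{int(fl.has_mesh)}{delimiter}{int(fl.has_pharm_action)}\n"
            )


# ---------------------------------------------------------------------------
# Cluster table I/O
# ---------------------------------------------------------------------------

def _item_str(item) -> str:
    if isinstance(item, tuple):
        return f"{item[0]}:{item[1]}"
    return str(item)


def _item_parse(s: str):
    if ":" in s:
        a, b = s.split(":")
        return (int(a), int(b))
    return int(s)


def write_clusters(clusters, path, delimiter="\t") -> None:
    """Write clusters, one row each: context, measure, uid, ordinal,
    representative, member compound ids, member conformer ids (3-D only)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(
            ["context", "measure", "uid", "cluster_ordinal",
             "representative", "compounds", "conformers"]
        )
        for ordinal, cl in enumerate(clusters, start=1):
            w.writerow([
                cl.context.value if cl.context is not None else "",
                cl.measure.value if cl.measure is not None else "",
                cl.uid if cl.uid is not None else "",
                ordinal,
                _item_str(cl.representative),
                ";".join(str(c) for c in cl.members_compounds),
                ";".join(_item_str(c) for c in cl.members_conformers),
            ])


def read_clusters(path, delimiter: Optional[str] = None):
    """Inverse of :func:`write_clusters`."""
    from .clustering import Cluster
    from .contexts import Context
    from .thresholds import Measure

    delimiter = delimiter or _sniff_delimiter(path)
    clusters = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter=delimiter):
            conformers = tuple(
                _item_parse(t) for t in row["conformers"].split(";") if t
            )
            clusters.append(
                Cluster(
                    members_compounds=tuple(
                        int(t) for t in row["compounds"].split(";") if t
                    ),
                    members_conformers=conformers,
                    representative=_item_parse(row["representative"]),
                    context=Context(row["context"]) if row["context"] else None,
                    measure=Measure(row["measure"]) if row["measure"] else None,
                    uid=int(row["uid"]) if row["uid"] else None,
                )
            )
    return clusters
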