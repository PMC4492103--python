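"""Per-UID non-inactive compound sets for the three bioactivity contexts.

A compound belongs to the set for a UID when it has at least one non-inactive
activity record linked to that UID — directly for assays (UID = AID), via the
assay→protein mapping for proteins (UID = protein identity group, PIG), and
via the protein→pathway mapping for pathways (UID = BSID). "Non-inactive"
covers active, inconclusive and unspecified outcomes: depositors often leave
genuinely active compounds unspecified, so only an explicit "inactive" call
excludes a compound. At the compound level the three contexts are nested:
pathway ⊆ protein ⊆ assay.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

from .chem_io import ActivityRecord, AnnotationTables, Outcome

logger = logging.getLogger("sarclust")


class Context(str, Enum):
    ASSAY = "assay"
    PROTEIN = "protein"
    PATHWAY = "pathway"


@dataclass(frozen=True)
class ContextSet:
    """The non-inactive compounds associated with one UID in one context.

    For the protein context ``uid`` is the PIG id and ``gis`` lists the member
    sequence ids so per-GI views remain available.
    """

    context: Context
    uid: int
    compound_ids: frozenset[int]
    gis: Optional[frozenset[int]] = None


def non_inactive_filter(records: Iterable[ActivityRecord]) -> bool:
    """True iff any record's outcome is active, inconclusive or unspecified.

    Existential rule: a compound declared inactive in one row and non-inactive
    in another (duplicate rows happen) counts as non-inactive.
    """
    return any(rec.outcome is not Outcome.INACTIVE for rec in records)


def build_pig(gi_to_sequence: dict[int, str]) -> dict[int, int]:
    """Assign protein identity groups: identical sequences (case-normalized,
    regardless of organism) share one PIG. PIG id = 1-based rank of the
    sequence in sorted order, which is deterministic and input-order stable."""
    normalized: dict[int, str] = {}
    for gi, seq in gi_to_sequence.items():
        seq = seq.strip().upper()
        if not seq:
            raise ValueError(f"empty protein sequence for GI {gi}")
        normalized[gi] = seq
    ranks = {seq: i + 1 for i, seq in enumerate(sorted(set(normalized.values())))}
    return {gi: ranks[seq] for gi, seq in normalized.items()}


def _non_inactive_by_assay(records: Iterable[ActivityRecord]) -> dict[int, set[int]]:
    out: dict[int, set[int]] = {}
    for rec in records:
        if rec.outcome is not Outcome.INACTIVE:
            out.setdefault(rec.assay_id, set()).add(rec.compound_id)
    return out


def build_context_sets(
    records: Iterable[ActivityRecord],
    annotations: Optional[AnnotationTables] = None,
    context: Context | str = Context.ASSAY,
) -> list[ContextSet]:
    """Build the per-UID compound sets for one bioactivity context.

    Assays lacking a protein mapping contribute to the assay context only;
    proteins lacking a pathway mapping contribute to assay and protein
    contexts only, so compound coverage is nested across contexts.
    """
    context = Context(context)
    records = list(records)
    per_assay = _non_inactive_by_assay(records)

    if context is Context.ASSAY:
        return [
            ContextSet(context, aid, frozenset(cids))
            for aid, cids in sorted(per_assay.items())
        ]

    if annotations is None:
        raise ValueError(f"{context.value} context requires annotation tables")

    if context is Context.PROTEIN:
        gi_to_pig = annotations.gi_to_pig
        if gi_to_pig is None:
            if annotations.gi_to_sequence is None:
                raise ValueError(
                    "protein context requires gi_to_pig or gi_to_sequence"
                )
            gi_to_pig = build_pig(annotations.gi_to_sequence)
        pig_compounds: dict[int, set[int]] = {}
        pig_gis: dict[int, set[int]] = {}
        for aid, cids in per_assay.items():
            for gi in annotations.assay_to_gi.get(aid, ()):  # unmapped: assay-only
                if gi not in gi_to_pig:
                    logger.info("GI %d has no PIG assignment; skipped", gi)
                    continue
                pig = gi_to_pig[gi]
                pig_compounds.setdefault(pig, set()).update(cids)
                pig_gis.setdefault(pig, set()).add(gi)
        return [
            ContextSet(context, pig, frozenset(cids), frozenset(pig_gis[pig]))
            for pig, cids in sorted(pig_compounds.items())
        ]

    # pathway context: AID -> GI -> BSID
    bsid_compounds: dict[int, set[int]] = {}
    for aid, cids in per_assay.items():
        for gi in annotations.assay_to_gi.get(aid, ()):
            for bsid in annotations.gi_to_bsid.get(gi, ()):
                bsid_compounds.setdefault(bsid, set()).update(cids)
    return [
        ContextSet(context, bsid, frozenset(cids))
        for bsid, cids in sorted(bsid_compounds.items())
    ]


def audit_context_set(
    cset: ContextSet,
    records: Iterable[ActivityRecord],
    annotations: Optional[AnnotationTables] = None,
) -> bool:
    """Check that every member compound traces to >=1 non-inactive record
    linked to the set's UID."""
    rebuilt = build_context_sets(records, annotations, cset.context)
    by_uid = {cs.uid: cs.compound_ids for cs in rebuilt}
    return cset.compound_ids <= by_uid.get(cset.uid, frozenset())
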