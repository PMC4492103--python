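import numpy as np
import pytest
from rdkit import Chem

import sarclust as sc


# ---------------------------------------------------------------------------
# SDF conformers
# ---------------------------------------------------------------------------

def _toy_conformers():
    return [
        sc.Conformer(7, 1, ["C", "N", "O"],
                     [[0.0, 0.0, 0.0], [1.5, 0.1, -0.2], [2.9, -0.4, 0.3]]),
        sc.Conformer(7, 2, ["C", "N", "O"],
                     [[0.0, 0.0, 0.0], [1.4, 0.3, 0.1], [2.8, 0.2, -0.5]]),
        sc.Conformer(9, 1, ["C", "C"], [[0.0, 0.0, 0.0], [1.54, 0.0, 0.0]]),
    ]


def test_sdf_round_trip_groups_and_preserves_coordinates(tmp_path):
    path = tmp_path / "confs.sdf"
    original = _toy_conformers()
    sc.write_conformers(original, path)
    back = sc.read_conformers(path)
    assert [(c.compound_id, c.conformer_index) for c in back] == [
        (7, 1), (7, 2), (9, 1)
    ]
    for a, b in zip(original, back):
        assert a.elements == b.elements
        np.testing.assert_allclose(a.coords, b.coords, atol=1e-4)  # SDF precision


def test_sdf_missing_id_properties(tmp_path):
    path = tmp_path / "noprops.sdf"
    sc.write_conformers([_toy_conformers()[0]], path, cid_prop="OTHER_PROP")
    with pytest.raises(ValueError, match="record #1"):
        sc.read_conformers(path)
    seq = sc.read_conformers(path, sequential_ids=True)
    assert [(c.compound_id, c.conformer_index) for c in seq] == [(1, 1)]


def test_sdf_empty_molecule_rejected(tmp_path):
    record = (
        "\n  none\n\n  0  0  0  0  0  0  0  0  0  0999 V2000\nM  END\n"
        "> <PUBCHEM_COMPOUND_CID>\n5\n\n> <PUBCHEM_CONFORMER_ID>\n1\n\n$$$$\n"
    )
    path = tmp_path / "empty.sdf"
    path.write_text(record)
    with pytest.raises(ValueError, match="empty molecule"):
        sc.read_conformers(path)


def test_sdf_malformed_record_names_ordinal(tmp_path):
    good = tmp_path / "good.sdf"
    sc.write_conformers([_toy_conformers()[0]], good)
    bad = tmp_path / "bad.sdf"
    bad.write_text(
        good.read_text()
        + "\n  bad\n\n ZZ  0  0  0  0  0  0  0  0  0999 V2000\nM  END\n$$$$\n"
    )
    with pytest.raises(ValueError, match="record #2"):
        sc.read_conformers(bad)


def test_hydrogens_stripped_on_read(tmp_path):
    # a methanol-like record with explicit hydrogens
    mol = Chem.AddHs(sc.mol_from_smiles("CO"))
    from rdkit.Chem import AllChem

    AllChem.EmbedMolecule(mol, randomSeed=1)
    mol.SetProp("PUBCHEM_COMPOUND_CID", "3")
    mol.SetProp("PUBCHEM_CONFORMER_ID", "1")
    path = tmp_path / "h.sdf"
    with Chem.SDWriter(str(path)) as writer:
        writer.write(mol)
    confs = sc.read_conformers(path)
    assert confs[0].elements == ["C", "O"]


def test_conformer_invariants():
    with pytest.raises(ValueError, match="empty molecule"):
        sc.Conformer(1, 1, [], np.zeros((0, 3)))
    with pytest.raises(ValueError, match="same length"):
        sc.Conformer(1, 1, ["C"], [[0, 0, 0], [1, 0, 0]])
    with pytest.raises(ValueError, match="positive"):
        sc.Conformer(0, 1, ["C"], [[0, 0, 0]])


# ---------------------------------------------------------------------------
# Fingerprints
# ---------------------------------------------------------------------------

def test_fingerprint_hex_decoding_msb_first(tmp_path):
    path = tmp_path / "fp.tsv"
    path.write_text("5\tf0\n")
    (fp,) = sc.read_fingerprints(path)
    assert fp.compound_id == 5
    assert fp.bits.tolist() == [1, 1, 1, 1, 0, 0, 0, 0]
    assert fp.popcount == 4


def test_fingerprint_table_errors_and_empty(tmp_path):
    empty = tmp_path / "empty.tsv"
    empty.write_text("")
    assert sc.read_fingerprints(empty) == []
    odd = tmp_path / "odd.tsv"
    odd.write_text("5\tf0f\n")
    with pytest.raises(ValueError, match="row 1"):
        sc.read_fingerprints(odd)
    mixed = tmp_path / "mixed.tsv"
    mixed.write_text("5\tf0\n6\tf0f0\n")
    with pytest.raises(ValueError, match="row 2"):
        sc.read_fingerprints(mixed)


def test_fingerprint_round_trip_bit_exact(tmp_path, rng):
    fps = [
        sc.Fingerprint(i, (rng.random(64) < 0.3).astype(np.uint8))
        for i in range(1, 6)
    ]
    path = tmp_path / "fps.tsv"
    sc.write_fingerprints(fps, path)
    back = sc.read_fingerprints(path)
    assert [fp.compound_id for fp in back] == [1, 2, 3, 4, 5]
    for a, b in zip(fps, back):
        assert np.array_equal(a.bits, b.bits)


def test_compute_fingerprint_ring_keys_and_determinism():
    keys = sc.KeySet([("c1ccccc1", 1), ("[#7]", 1), ("[r3]", 1)])
    benzene = sc.compute_fingerprint(sc.mol_from_smiles("c1ccccc1"), keys)
    assert benzene.bits.tolist() == [1, 0, 0]
    methane = sc.compute_fingerprint(sc.mol_from_smiles("C"), keys)
    assert methane.bits.tolist() == [0, 0, 0]
    again = sc.compute_fingerprint(sc.mol_from_smiles("c1ccccc1"), keys)
    assert np.array_equal(benzene.bits, again.bits)


def test_compute_fingerprint_atom_renumbering_invariant():
    mol = sc.mol_from_smiles("CC(=O)Nc1ccc(O)cc1")
    order = list(range(mol.GetNumAtoms()))[::-1]
    renumbered = Chem.RenumberAtoms(mol, order)
    fp1 = sc.compute_fingerprint(mol)
    fp2 = sc.compute_fingerprint(renumbered)
    assert np.array_equal(fp1.bits, fp2.bits)


def test_bad_smarts_key_fails_at_load_time():
    with pytest.raises(ValueError, match="SMARTS"):
        sc.KeySet([("c1ccccc1", 1), ("[[[", 1)])


# ---------------------------------------------------------------------------
# Activity table
# ---------------------------------------------------------------------------

def test_activity_table_parsing_case_insensitive(tmp_path):
    path = tmp_path / "act.csv"
    path.write_text(
        "compound_id,assay_id,outcome,potency_type,potency_um\n"
        "101,9001,Active,,\n"
        "102,9001,INACTIVE,,\n"
        "103,9001,unspecified,IC50,5.0\n"
    )
    records = sc.read_activity_table(path)
    assert [r.outcome for r in records] == [
        sc.Outcome.ACTIVE, sc.Outcome.INACTIVE, sc.Outcome.UNSPECIFIED
    ]
    assert records[2].potency_type is sc.PotencyType.IC50
    assert records[2].potency_um == 5.0


def test_activity_table_unknown_outcome_names_row(tmp_path):
    path = tmp_path / "act.tsv"
    path.write_text(
        "compound_id\tassay_id\toutcome\n101\t9001\tactive\n102\t9001\thit\n"
    )
    with pytest.raises(ValueError, match="row 3"):
        sc.read_activity_table(path)


def test_activity_table_duplicates_kept_and_round_trip(tmp_path):
    records = [
        sc.ActivityRecord(101, 9001, sc.Outcome.ACTIVE),
        sc.ActivityRecord(101, 9001, sc.Outcome.ACTIVE, sc.PotencyType.EC50, 2.5),
        sc.ActivityRecord(102, 9002, sc.Outcome.INCONCLUSIVE),
    ]
    path = tmp_path / "act.tsv"
    sc.write_activity_table(records, path)
    back = sc.read_activity_table(path)
    assert back == records


def test_activity_record_invariants():
    with pytest.raises(ValueError, match="together"):
        sc.ActivityRecord(1, 1, sc.Outcome.ACTIVE, None, 5.0)
    with pytest.raises(ValueError):
        sc.ActivityRecord(1, 1, "hit")


# ---------------------------------------------------------------------------
# Annotations and clusters
# ---------------------------------------------------------------------------

def test_read_annotations_fasta_and_maps(tmp_path):
    (tmp_path / "assay_gi.tsv").write_text("assay_id\tgi\n9001\t501\n9002\t502\n")
    (tmp_path / "gi.fasta").write_text(">501 some protein\nMKV\n>502\nMKV\n")
    (tmp_path / "gi_bsid.tsv").write_text("gi\tbsid\n501\t7001\n")
    (tmp_path / "flags.tsv").write_text(
        "compound_id\thas_mesh\thas_pharm_action\n101\t1\t0\n"
    )
    tables = sc.read_annotations(
        tmp_path / "assay_gi.tsv", tmp_path / "gi.fasta", None,
        tmp_path / "gi_bsid.tsv", tmp_path / "flags.tsv",
    )
    assert tables.assay_to_gi == {9001: frozenset({501}), 9002: frozenset({502})}
    assert tables.gi_to_sequence == {501: "MKV", 502: "MKV"}
    assert tables.gi_to_bsid == {501: frozenset({7001})}
    assert tables.compound_flags[101].has_mesh


def test_annotation_write_read_round_trip(tmp_path, small_fixture_data):
    sc.write_annotations(small_fixture_data.annotations, tmp_path)
    back = sc.read_annotations(
        tmp_path / "assay_gi.tsv", tmp_path / "gi_seq.fasta", None,
        tmp_path / "gi_bsid.tsv", tmp_path / "compound_flags.tsv",
    )
    assert back.assay_to_gi == small_fixture_data.annotations.assay_to_gi
    assert back.gi_to_sequence == small_fixture_data.annotations.gi_to_sequence
    assert back.gi_to_bsid == small_fixture_data.annotations.gi_to_bsid


def test_cluster_table_round_trip(tmp_path):
    clusters = [
        sc.Cluster((7, 9), ((7, 1), (9, 3)), 7,
                   sc.Context.ASSAY, sc.Measure.ST_STOPT, 9001),
        sc.Cluster((3, 4), (), 3, sc.Context.ASSAY, sc.Measure.TANIMOTO_2D, 9001),
    ]
    path = tmp_path / "clusters.tsv"
    sc.write_clusters(clusters, path)
    back = sc.read_clusters(path)
    assert back == clusters
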