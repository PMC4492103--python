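import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sarclust as sc
from sarclust.similarity import FeatureType

from conftest import embedded_conformer, random_toy_conformer, random_fingerprint
from oracles import (
    grid_overlap_volume,
    maxmin_selection_bruteforce,
    pairwise_overlap_sum,
    rotation_grid_best_st,
)


# ---------------------------------------------------------------------------
# 2-D Tanimoto
# ---------------------------------------------------------------------------

def _fp(cid, on, n=16):
    bits = np.zeros(n, dtype=np.uint8)
    bits[list(on)] = 1
    return sc.Fingerprint(cid, bits)


@pytest.mark.parametrize(
    "on_a, on_b, expected",
    [
        (range(5), range(5), 1.0),            # identical non-empty
        (range(4), range(4, 8), 0.0),          # disjoint
        (range(4), [0, 1, 2, 6, 7, 8], 3 / 7),  # A=4, B=6, AB=3
        ([], [], 0.0),                          # 0/0 convention
    ],
)
def test_tanimoto_2d_worked_examples(on_a, on_b, expected):
    assert sc.tanimoto_2d(_fp(1, on_a), _fp(2, on_b)) == pytest.approx(expected)


def test_tanimoto_2d_length_mismatch():
    with pytest.raises(ValueError, match="length"):
        sc.tanimoto_2d(_fp(1, [0], n=8), _fp(2, [0], n=16))


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.booleans(), min_size=1, max_size=64), st.data())
def test_tanimoto_2d_matches_naive_bit_loop(bits_a, data):
    bits_b = data.draw(
        st.lists(st.booleans(), min_size=len(bits_a), max_size=len(bits_a))
    )
    fa = sc.Fingerprint(1, np.array(bits_a, dtype=np.uint8))
    fb = sc.Fingerprint(2, np.array(bits_b, dtype=np.uint8))
    inter = sum(1 for x, y in zip(bits_a, bits_b) if x and y)
    union = sum(1 for x, y in zip(bits_a, bits_b) if x or y)
    expected = inter / union if union else 0.0
    assert sc.tanimoto_2d(fa, fb) == pytest.approx(expected)
    assert sc.tanimoto_2d(fa, fb) == sc.tanimoto_2d(fb, fa)


# ---------------------------------------------------------------------------
# Gaussian overlap volume
# ---------------------------------------------------------------------------

def test_overlap_single_atom_identity():
    p = [[0.3, -0.2, 1.0]]
    vaa = sc.gaussian_overlap_volume(p, 1.7, p, 1.7)
    assert vaa == pytest.approx(
        sc.gaussian_overlap_volume(p, 1.7, [[0.3, -0.2, 1.0]], 1.7)
    )


def test_overlap_decays_monotonically_with_distance():
    prev = None
    for d in np.linspace(0.0, 12.0, 25):
        v = sc.gaussian_overlap_volume([[0, 0, 0]], 1.7, [[d, 0, 0]], 1.7)
        if prev is not None:
            assert v < prev or d == 0.0
        prev = v
    assert prev < 1e-6


def test_overlap_rejects_nonpositive_radius():
    with pytest.raises(ValueError, match="positive"):
        sc.gaussian_overlap_volume([[0, 0, 0]], 0.0, [[1, 0, 0]], 1.7)


def test_carbon_pair_overlap_matches_grid_integration():
    """Two carbon-radius atoms 1 Å apart: analytic pairwise volume vs 0.1 Å
    grid integration of the product density (independent oracle)."""
    pa, pb = [[0.0, 0.0, 0.0]], [[1.0, 0.0, 0.0]]
    analytic = sc.gaussian_overlap_volume(pa, 1.7, pb, 1.7)
    grid = grid_overlap_volume(pa, 1.7, pb, 1.7, spacing=0.1, pad=5.0)
    assert analytic == pytest.approx(grid, rel=0.01)


def test_overlap_matches_grid_on_random_toys(rng):
    for _ in range(5):
        na, nb = rng.integers(1, 7), rng.integers(1, 7)
        pa = rng.uniform(-2, 2, (na, 3))
        pb = rng.uniform(-2, 2, (nb, 3))
        ra = rng.uniform(1.0, 2.0, na)
        rb = rng.uniform(1.0, 2.0, nb)
        analytic = sc.gaussian_overlap_volume(pa, ra, pb, rb)
        grid = grid_overlap_volume(pa, ra, pb, rb)
        assert analytic == pytest.approx(grid, rel=0.01)
        assert analytic == pytest.approx(
            sc.gaussian_overlap_volume(pb, rb, pa, ra)
        )


# ---------------------------------------------------------------------------
# Shape / color / combo Tanimoto
# ---------------------------------------------------------------------------

def test_shape_tanimoto_self_identity_is_exactly_one():
    conf = sc.Conformer(1, 1, ["C", "N", "O"],
                        [[0, 0, 0], [1.5, 0, 0], [2.2, 1.1, -0.4]])
    assert sc.shape_tanimoto(conf, conf) == pytest.approx(1.0, abs=1e-12)


def test_shape_tanimoto_vanishes_far_apart():
    a = sc.Conformer(1, 1, ["C"], [[0, 0, 0]])
    b = sc.Conformer(2, 1, ["C"], [[100.0, 0, 0]])
    assert sc.shape_tanimoto(a, b) < 1e-6


def test_shape_tanimoto_two_vs_one_atom_closed_form():
    """Hand-evaluated pairwise sums for a fixed 2-atom vs 1-atom geometry."""
    a = sc.Conformer(1, 1, ["C", "C"], [[0, 0, 0], [1.5, 0, 0]])
    b = sc.Conformer(2, 1, ["C"], [[0.5, 0.3, 0.0]])
    atoms_a = [(0, 0, 0, 1.7), (1.5, 0, 0, 1.7)]
    atoms_b = [(0.5, 0.3, 0.0, 1.7)]
    vaa = pairwise_overlap_sum(atoms_a, atoms_a)
    vbb = pairwise_overlap_sum(atoms_b, atoms_b)
    vab = pairwise_overlap_sum(atoms_a, atoms_b)
    assert sc.shape_tanimoto(a, b) == pytest.approx(
        vab / (vaa + vbb - vab), rel=1e-12
    )


def test_color_tanimoto_same_type_only():
    donor_conf = sc.Conformer(1, 1, ["N"], [[0, 0, 0]])
    donor_conf.feature_atoms = [sc.FeatureAtom(FeatureType.DONOR, [0, 0, 0])]
    acceptor_conf = sc.Conformer(2, 1, ["O"], [[0, 0, 0]])
    acceptor_conf.feature_atoms = [sc.FeatureAtom(FeatureType.ACCEPTOR, [0, 0, 0])]
    assert sc.color_tanimoto(donor_conf, donor_conf) == pytest.approx(1.0)
    assert sc.color_tanimoto(donor_conf, acceptor_conf) == 0.0
    bare_a = sc.Conformer(3, 1, ["C"], [[0, 0, 0]])
    bare_b = sc.Conformer(4, 1, ["C"], [[0, 0, 0]])
    assert sc.color_tanimoto(bare_a, bare_b) == 0.0  # 0/0 convention


@pytest.mark.parametrize(
    "st_score, ct_score, combo, normalized",
    [(1.0, 1.0, 2.0, 1.0), (0.0, 0.0, 0.0, 0.0), (0.3, 0.2, 0.5, 0.25)],
)
def test_combo_tanimoto(st_score, ct_score, combo, normalized):
    assert sc.combo_tanimoto(st_score, ct_score) == pytest.approx(combo)
    assert sc.combo_tanimoto(st_score, ct_score, normalized=True) == pytest.approx(
        normalized
    )


# ---------------------------------------------------------------------------
# Feature typing
# ---------------------------------------------------------------------------

def _features_by_type(conf):
    by_type = {}
    for f in conf.feature_atoms:
        by_type.setdefault(f.feature_type, []).append(f)
    return by_type


def test_benzene_features_ring_centroid_plus_hydrophobes():
    conf, mol = embedded_conformer("c1ccccc1")
    sc.assign_feature_atoms(conf, mol)
    by_type = _features_by_type(conf)
    assert len(by_type[FeatureType.RING]) == 1
    assert len(by_type[FeatureType.HYDROPHOBE]) == 6
    assert set(by_type) == {FeatureType.RING, FeatureType.HYDROPHOBE}
    np.testing.assert_allclose(
        by_type[FeatureType.RING][0].position, conf.coords.mean(axis=0), atol=1e-6
    )


def test_acetate_features_anion_and_acceptors():
    conf, mol = embedded_conformer("CC(=O)[O-]")
    sc.assign_feature_atoms(conf, mol)
    by_type = _features_by_type(conf)
    assert len(by_type[FeatureType.ANION]) == 1
    assert len(by_type[FeatureType.ACCEPTOR]) == 2
    assert FeatureType.DONOR not in by_type
    assert FeatureType.RING not in by_type
    # the anion sits on the charged oxygen
    charged_ix = [i for i, a in enumerate(mol.GetAtoms())
                  if a.GetFormalCharge() < 0][0]
    np.testing.assert_allclose(
        by_type[FeatureType.ANION][0].position, conf.coords[charged_ix]
    )


def test_ethane_features_hydrophobes_only():
    conf, mol = embedded_conformer("CC")
    sc.assign_feature_atoms(conf, mol)
    by_type = _features_by_type(conf)
    assert set(by_type) == {FeatureType.HYDROPHOBE}
    assert len(by_type[FeatureType.HYDROPHOBE]) == 2


def test_sulfamide_has_donors_and_acceptors():
    conf, mol = embedded_conformer(sc.fixtures.TEST_SMILES["sulfamide"])
    sc.assign_feature_atoms(conf, mol)
    by_type = _features_by_type(conf)
    assert len(by_type[FeatureType.DONOR]) == 2   # the two NH2 nitrogens
    assert len(by_type[FeatureType.ACCEPTOR]) == 4  # both N and both O


# ---------------------------------------------------------------------------
# Superposition optimization
# ---------------------------------------------------------------------------

def test_optimized_st_recovers_rigid_rotated_copy(rng):
    conf = random_toy_conformer(rng, 1, 1, n_atoms=6)
    rot = sc.fixtures._random_rotation(rng)
    moved = sc.Conformer(2, 1, list(conf.elements), conf.coords @ rot.T + [3, -2, 5])
    sc.assign_planted_features(moved)
    pose = sc.optimize_superposition(conf, moved, "st-opt")
    assert pose.st >= 0.999
    # the returned transform reproduces the score when applied explicitly
    placed = sc.Conformer(2, 1, list(moved.elements), pose.apply(moved.coords))
    assert sc.shape_tanimoto(conf, placed) == pytest.approx(pose.st, abs=1e-9)
    assert np.linalg.det(pose.rotation) == pytest.approx(1.0, abs=1e-9)


def test_single_atom_alignment_translation_closes_gap():
    a = sc.Conformer(1, 1, ["C"], [[0, 0, 0]])
    b = sc.Conformer(2, 1, ["C"], [[25.0, -14.0, 3.0]])
    pose = sc.optimize_superposition(a, b, "st-opt")
    assert pose.st == pytest.approx(1.0, abs=1e-6)


def test_optimized_st_matches_rotation_grid_oracle(rng):
    """Asymmetric 4-atom toys: optimizer must reach (or beat) an exhaustive
    10-degree Euler-grid + centroid-translation search."""
    coords_a = np.array([[0, 0, 0], [1.5, 0, 0], [2.2, 1.2, 0], [1.0, 0.5, 1.4]])
    coords_b = np.array([[0, 0, 0], [1.4, 0.3, 0], [2.5, 1.0, 0.5], [0.6, 1.4, 0.9]])
    a = sc.Conformer(1, 1, ["C"] * 4, coords_a)
    b = sc.Conformer(2, 1, ["C"] * 4, coords_b)
    grid_best = rotation_grid_best_st(coords_a, coords_b, step_deg=10.0)
    pose = sc.optimize_superposition(a, b, "st-opt")
    assert pose.st >= grid_best - 1e-3


def test_optimized_scores_symmetric_under_argument_swap(rng):
    a = random_toy_conformer(rng, 1, 1)
    b = random_toy_conformer(rng, 2, 1)
    for mode in ("st-opt", "ct-opt"):
        st_ab, ct_ab, _ = sc.conformer_pair_score(a, b, mode)
        st_ba, ct_ba, _ = sc.conformer_pair_score(b, a, mode)
        assert st_ab == pytest.approx(st_ba, abs=1e-3)
        assert ct_ab == pytest.approx(ct_ba, abs=1e-3)


def test_combo_equals_st_plus_ct_at_pose_for_both_modes(rng):
    a = random_toy_conformer(rng, 1, 1)
    b = random_toy_conformer(rng, 2, 1)
    for mode in ("st-opt", "ct-opt"):
        pose = sc.optimize_superposition(a, b, mode)
        assert pose.combo == pytest.approx(pose.st + pose.ct, abs=1e-12)
        assert 0.0 <= pose.st <= 1.0
        assert 0.0 <= pose.ct <= 1.0


def test_ct_opt_feature_free_falls_back_to_shape(rng):
    a = sc.Conformer(1, 1, ["C", "C"], [[0, 0, 0], [1.5, 0, 0]])
    b = sc.Conformer(2, 1, ["C", "C"], [[4, 1, 0], [5.5, 1, 0]])
    pose = sc.optimize_superposition(a, b, "ct-opt")
    assert pose.st >= 0.999
    assert pose.ct == 0.0


# ---------------------------------------------------------------------------
# Diverse conformer selection
# ---------------------------------------------------------------------------

def _torsion_sweep_conformers(n=12):
    """A 1-D torsion sweep: the tail of a 6-atom chain rotates in steps."""
    confs = []
    for k in range(n):
        angle = k * (np.pi / n)
        coords = np.array(
            [[i * 1.5, 0.0, 0.0] for i in range(4)]
            + [[4.5 + 1.5 * np.cos(angle), 1.5 * np.sin(angle), 0.0]]
            + [[4.5 + 3.0 * np.cos(angle), 3.0 * np.sin(angle), 0.0]]
        )
        confs.append(sc.Conformer(1, k + 1, ["C"] * 6, coords))
    return confs


def test_select_diverse_returns_all_when_few():
    confs = _torsion_sweep_conformers(3)
    assert sc.select_diverse_conformers(confs, 10) == confs


def test_select_diverse_ties_prefer_low_index():
    base = np.array([[0, 0, 0], [1.5, 0, 0]])
    copies = [sc.Conformer(1, k, ["C", "C"], base.copy()) for k in range(1, 16)]
    chosen = sc.select_diverse_conformers(copies, 10)
    assert [c.conformer_index for c in chosen] == list(range(1, 11))


def test_select_diverse_matches_bruteforce_maxmin():
    confs = _torsion_sweep_conformers(12)
    chosen = sc.select_diverse_conformers(confs, 5)
    coord_sets = {c.conformer_index: c.coords for c in confs}
    expected = maxmin_selection_bruteforce(
        coord_sets, [c.conformer_index for c in confs], 5
    )
    assert [c.conformer_index for c in chosen] == expected


def test_select_diverse_rejects_bad_nmax():
    with pytest.raises(ValueError):
        sc.select_diverse_conformers(_torsion_sweep_conformers(3), 0)


# ---------------------------------------------------------------------------
# Score cache and pre-computation
# ---------------------------------------------------------------------------

def test_cache_put_get_identity_and_orientation(rng):
    a = random_toy_conformer(rng, 3, 2)
    b = random_toy_conformer(rng, 5, 1)
    cache = sc.ScoreCache()
    st, ct, combo = sc.conformer_pair_score(a, b, "st-opt", cache)
    entry = cache.get(3, 2, 5, 1, "st-opt")
    assert (entry.st, entry.ct, entry.combo) == (st, ct, combo)
    # reversed orientation: same scores, inverted transform
    rev = cache.get(5, 1, 3, 2, "st-opt")
    assert rev.st == entry.st
    np.testing.assert_allclose(rev.rotation, entry.rotation.T, atol=1e-12)
    np.testing.assert_allclose(
        rev.rotation @ entry.translation + rev.translation, np.zeros(3), atol=1e-12
    )


def test_cache_save_load_bit_identical(tmp_path, rng):
    a = random_toy_conformer(rng, 1, 1)
    b = random_toy_conformer(rng, 2, 1)
    cache = sc.ScoreCache()
    sc.conformer_pair_score(a, b, "st-opt", cache)
    sc.conformer_pair_score(a, b, "ct-opt", cache)
    path = tmp_path / "cache.tsv"
    cache.save(path)
    reloaded = sc.ScoreCache(path)
    for mode in ("st-opt", "ct-opt"):
        e0 = cache.get(1, 1, 2, 1, mode)
        e1 = reloaded.get(1, 1, 2, 1, mode)
        assert e0.st == e1.st and e0.ct == e1.ct and e0.combo == e1.combo
        assert np.array_equal(e0.rotation, e1.rotation)
        assert np.array_equal(e0.translation, e1.translation)


def test_cache_skips_corrupt_rows(tmp_path, rng, caplog):
    a = random_toy_conformer(rng, 1, 1)
    b = random_toy_conformer(rng, 2, 1)
    cache = sc.ScoreCache()
    sc.conformer_pair_score(a, b, "st-opt", cache)
    path = tmp_path / "cache.tsv"
    cache.save(path)
    with open(path, "a", encoding="utf-8") as fh:
        fh.write("not\ta\tvalid\trow\n")
    reloaded = sc.ScoreCache(path)
    assert len(reloaded) == 1


def test_precompute_only_cotested_pairs(rng):
    confs = {cid: [random_toy_conformer(rng, cid, 1)] for cid in (1, 2, 3, 4)}
    records = [
        sc.ActivityRecord(1, 9001, sc.Outcome.ACTIVE),
        sc.ActivityRecord(2, 9001, sc.Outcome.UNSPECIFIED),
        sc.ActivityRecord(3, 9001, sc.Outcome.INACTIVE),  # inactive: no pair
        sc.ActivityRecord(3, 9002, sc.Outcome.ACTIVE),
        sc.ActivityRecord(4, 9003, sc.Outcome.ACTIVE),    # alone in its assay
    ]
    cache = sc.precompute_pair_scores(confs, records)
    # one co-tested pair (1, 2) x two modes = exactly 2 rows
    assert len(cache) == 2
    assert (1, 1, 2, 1, "st-opt") in cache
    assert (1, 1, 4, 1, "st-opt") not in cache
    # idempotent: re-running adds nothing
    sc.precompute_pair_scores(confs, records, cache=cache)
    assert len(cache) == 2
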