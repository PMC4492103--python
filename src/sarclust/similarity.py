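"""The five structural similarity measures and their supporting machinery.

2-D similarity is the Tanimoto coefficient over substructure-key fingerprint
bits, T = AB / (A + B - AB) with A, B the popcounts and AB the intersection
popcount. 3-D similarity follows the atom-centered Gaussian volume-overlap
model: each heavy atom contributes a density p*exp(-alpha*|r-R|^2) whose
parameters are chosen so the Gaussian volume matches the hard-sphere volume
of the atom, and pairwise (first-order) overlap volumes give

    shape-Tanimoto  ST = V_AB / (V_AA + V_BB - V_AB)
    color-Tanimoto  CT = sum_f V^f_AB / (sum_f V^f_AA + sum_f V^f_BB - sum_f V^f_AB)
    ComboT          = ST + CT            (range 0..2)

where f runs over six pharmacophoric feature types (donor, acceptor, cation,
anion, hydrophobe, ring) represented by fictitious "color" atoms. Scores are
evaluated at a rigid superposition optimized either for shape alone (ST-opt)
or for shape plus color simultaneously (CT-opt).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .chem_io import ActivityRecord, Conformer, Fingerprint, Outcome

logger = logging.getLogger("sarclust")

# Grant-Pickup style Gaussian parameterization: fixed prefactor, width set by
# matching the Gaussian volume p*(pi/alpha)^(3/2) to the hard-sphere volume
# (4/3)*pi*r^3 of the atom.
GAUSSIAN_WEIGHT = 2.7
SHAPE_RADIUS = 1.7   # uniform heavy-atom radius, Å
FEATURE_RADIUS = 1.0  # color-atom radius, Å


class FeatureType(str, Enum):
    DONOR = "donor"
    ACCEPTOR = "acceptor"
    CATION = "cation"
    ANION = "anion"
    HYDROPHOBE = "hydrophobe"
    RING = "ring"


@dataclass
class FeatureAtom:
    """A fictitious pharmacophoric 'color' atom (ring features sit at ring
    centroids)."""

    feature_type: FeatureType
    position: np.ndarray
    radius: float = FEATURE_RADIUS

    def __post_init__(self) -> None:
        self.feature_type = FeatureType(self.feature_type)
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.radius <= 0:
            raise ValueError("feature radius must be positive")


class OptMode(str, Enum):
    ST_OPT = "st-opt"
    CT_OPT = "ct-opt"


@dataclass
class Superposition:
    """A rigid placement of molecule B onto molecule A with its scores.

    ``rotation`` (proper, det +1) and ``translation`` map B's original
    coordinates into A's original frame: b_placed = rotation @ b + translation.
    """

    rotation: np.ndarray
    translation: np.ndarray
    mode: OptMode
    st: float
    ct: float

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.mode = OptMode(self.mode)

    @property
    def combo(self) -> float:
        return self.st + self.ct

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> tuple[np.ndarray, np.ndarray]:
        rt = self.rotation.T
        return rt, -rt @ self.translation


# ---------------------------------------------------------------------------
# 2-D Tanimoto
# ---------------------------------------------------------------------------

def tanimoto_2d(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """Fingerprint Tanimoto AB/(A+B-AB); 0 when both fingerprints are empty."""
    if fp_a.n_bits != fp_b.n_bits:
        raise ValueError(
            f"fingerprint length mismatch: {fp_a.n_bits} vs {fp_b.n_bits}"
        )
    ab = int(np.sum(fp_a.bits & fp_b.bits))
    denom = fp_a.popcount + fp_b.popcount - ab
    if denom == 0:
        return 0.0
    return ab / denom


# ---------------------------------------------------------------------------
# Gaussian volume overlap
# ---------------------------------------------------------------------------

def gaussian_alpha(radius, weight: float = GAUSSIAN_WEIGHT):
    """Width of the atomic Gaussian whose volume matches a sphere of the
    given radius: solves p*(pi/alpha)^(3/2) = (4/3)*pi*r^3."""
    radius = np.asarray(radius, dtype=float)
    return np.pi * (3.0 * weight / (4.0 * np.pi * radius**3)) ** (2.0 / 3.0)


def gaussian_overlap_volume(
    pos_a: np.ndarray,
    rad_a,
    pos_b: np.ndarray,
    rad_b,
    weight_a=None,
    weight_b=None,
) -> float:
    """First-order (pairwise) Gaussian overlap volume between two atom sets.

    V_XY = sum_i sum_j p_i p_j (pi/(a_i+a_j))^{3/2} exp(-a_i a_j d_ij^2/(a_i+a_j)),
    the exact integral of the product of the two summed Gaussian densities.
    Self-overlaps (V_AA) use the same double sum with the diagonal included.
    """
    pos_a = np.asarray(pos_a, dtype=float).reshape(-1, 3)
    pos_b = np.asarray(pos_b, dtype=float).reshape(-1, 3)
    if pos_a.size == 0 or pos_b.size == 0:
        return 0.0
    rad_a = np.broadcast_to(np.asarray(rad_a, dtype=float), (len(pos_a),))
    rad_b = np.broadcast_to(np.asarray(rad_b, dtype=float), (len(pos_b),))
    if np.any(rad_a <= 0) or np.any(rad_b <= 0):
        raise ValueError("atom radii must be positive")
    wa = np.broadcast_to(
        np.asarray(GAUSSIAN_WEIGHT if weight_a is None else weight_a, dtype=float),
        (len(pos_a),),
    )
    wb = np.broadcast_to(
        np.asarray(GAUSSIAN_WEIGHT if weight_b is None else weight_b, dtype=float),
        (len(pos_b),),
    )
    aa = gaussian_alpha(rad_a)[:, None]
    ab = gaussian_alpha(rad_b)[None, :]
    d2 = np.sum((pos_a[:, None, :] - pos_b[None, :, :]) ** 2, axis=-1)
    s = aa + ab
    k = (wa[:, None] * wb[None, :]) * (np.pi / s) ** 1.5
    return float(np.sum(k * np.exp(-aa * ab * d2 / s)))


def _shape_arrays(conf: Conformer, radii: Optional[Mapping[str, float]] = None):
    if radii is None:
        rad = np.full(conf.n_atoms, SHAPE_RADIUS)
    else:
        rad = np.array([radii.get(el, SHAPE_RADIUS) for el in conf.elements])
    return conf.coords, rad


def _feature_arrays(conf: Conformer):
    """Positions and radii of a conformer's feature atoms, grouped by type."""
    groups: dict[FeatureType, tuple[np.ndarray, np.ndarray]] = {}
    for ftype in FeatureType:
        feats = [f for f in conf.feature_atoms if f.feature_type == ftype]
        if feats:
            groups[ftype] = (
                np.array([f.position for f in feats]),
                np.array([f.radius for f in feats]),
            )
    return groups


def shape_tanimoto(
    conf_a: Conformer,
    conf_b: Conformer,
    pose: Optional[Superposition] = None,
    radii: Optional[Mapping[str, float]] = None,
) -> float:
    """ST = V_AB/(V_AA+V_BB-V_AB) at the given pose (identity if omitted)."""
    pa, ra = _shape_arrays(conf_a, radii)
    pb, rb = _shape_arrays(conf_b, radii)
    if pose is not None:
        pb = pose.apply(pb)
    vaa = gaussian_overlap_volume(pa, ra, pa, ra)
    vbb = gaussian_overlap_volume(pb, rb, pb, rb)
    vab = gaussian_overlap_volume(pa, ra, pb, rb)
    return vab / (vaa + vbb - vab)


def color_tanimoto(
    conf_a: Conformer, conf_b: Conformer, pose: Optional[Superposition] = None
) -> float:
    """CT over same-type feature pairs; 0 when both feature sets are empty."""
    ga = _feature_arrays(conf_a)
    gb = _feature_arrays(conf_b)
    if not ga and not gb:
        return 0.0
    vaa = vbb = vab = 0.0
    for ftype, (pa, ra) in ga.items():
        vaa += gaussian_overlap_volume(pa, ra, pa, ra)
    for ftype, (pb, rb) in gb.items():
        pbp = pose.apply(pb) if pose is not None else pb
        vbb += gaussian_overlap_volume(pbp, rb, pbp, rb)
    for ftype in set(ga) & set(gb):
        pa, ra = ga[ftype]
        pb, rb = gb[ftype]
        pbp = pose.apply(pb) if pose is not None else pb
        vab += gaussian_overlap_volume(pa, ra, pbp, rb)
    denom = vaa + vbb - vab
    if denom <= 0:
        return 0.0
    return vab / denom


def combo_tanimoto(st: float, ct: float, normalized: bool = False) -> float:
    """ComboT = ST + CT, in [0, 2]; the normalized variant divides by 2 so it
    can be used with distance thresholds on the unit scale."""
    combo = st + ct
    return combo / 2.0 if normalized else combo


# ---------------------------------------------------------------------------
# Feature-atom assignment
# ---------------------------------------------------------------------------

def assign_feature_atoms(conformer: Conformer, mol) -> Conformer:
    """Fill a conformer's pharmacophoric feature atoms from a connection table.

    Rule table (defaults of this package; the six feature types are standard,
    their operational definitions vary between implementations):
      cation     — atom with formal charge > 0
      anion      — atom with formal charge < 0
      donor      — N or O with at least one attached hydrogen
      acceptor   — N or O with formal charge <= 0
      hydrophobe — carbon whose neighbors are all C or H
      ring       — centroid of each smallest-set ring (heavy atoms)

    ``mol`` is an RDKit molecule whose heavy atoms correspond, in order, to
    the conformer's atoms. An atom may carry several features (a charged
    oxygen is both anion and acceptor). Positions are taken from the
    conformer's coordinates.
    """
    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    if len(heavy) != conformer.n_atoms:
        raise ValueError(
            f"connection table has {len(heavy)} heavy atoms, conformer has "
            f"{conformer.n_atoms}"
        )
    heavy_index = {a.GetIdx(): i for i, a in enumerate(heavy)}
    feats: list[FeatureAtom] = []
    for i, atom in enumerate(heavy):
        pos = conformer.coords[i]
        sym = atom.GetSymbol()
        charge = atom.GetFormalCharge()
        if charge > 0:
            feats.append(FeatureAtom(FeatureType.CATION, pos))
        if charge < 0:
            feats.append(FeatureAtom(FeatureType.ANION, pos))
        if sym in ("N", "O") and atom.GetTotalNumHs(includeNeighbors=True) >= 1:
            feats.append(FeatureAtom(FeatureType.DONOR, pos))
        if sym in ("N", "O") and charge <= 0:
            feats.append(FeatureAtom(FeatureType.ACCEPTOR, pos))
        if sym == "C" and all(
            n.GetSymbol() in ("C", "H") for n in atom.GetNeighbors()
        ):
            feats.append(FeatureAtom(FeatureType.HYDROPHOBE, pos))
    for ring in mol.GetRingInfo().AtomRings():
        members = [heavy_index[i] for i in ring if i in heavy_index]
        if members:
            centroid = conformer.coords[members].mean(axis=0)
            feats.append(FeatureAtom(FeatureType.RING, centroid))
    conformer.feature_atoms = feats
    return conformer


# ---------------------------------------------------------------------------
# Rigid superposition optimization
# ---------------------------------------------------------------------------

def _canonical_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and principal-axes matrix (columns = axes, det +1).

    Axis signs are fixed by the third moment of the coordinate projections
    (largest-component sign as fallback) so the frame is invariant under
    rigid motion of the input, which makes optimized scores invariant too.
    """
    c = coords.mean(axis=0)
    x = coords - c
    cov = x.T @ x / max(len(coords), 1)
    w, v = np.linalg.eigh(cov)
    v = v[:, ::-1].copy()
    for k in range(3):
        proj = x @ v[:, k]
        m3 = float(np.sum(proj**3))
        if abs(m3) > 1e-8:
            if m3 < 0:
                v[:, k] = -v[:, k]
        else:
            j = int(np.argmax(np.abs(v[:, k])))
            if v[j, k] < 0:
                v[:, k] = -v[:, k]
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return c, v


_FLIP_STARTS = [
    np.diag([1.0, 1.0, 1.0]),
    np.diag([1.0, -1.0, -1.0]),
    np.diag([-1.0, 1.0, -1.0]),
    np.diag([-1.0, -1.0, 1.0]),
]


def _extra_starts() -> list[np.ndarray]:
    """Twelve additional 90-degree rotations for `thorough` starts."""
    mats = []
    for axis in np.eye(3):
        for angle in (np.pi / 2, -np.pi / 2):
            mats.append(Rotation.from_rotvec(angle * axis).as_matrix())
    for perm_axis in ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]):
        r = Rotation.from_rotvec(
            (2 * np.pi / 3) * np.asarray(perm_axis, float) / np.sqrt(3)
        ).as_matrix()
        mats.append(r)
        mats.append(r.T)
    return mats[:12]


def optimize_superposition(
    conf_a: Conformer,
    conf_b: Conformer,
    mode: OptMode | str = OptMode.ST_OPT,
    starts: str = "standard",
    radii: Optional[Mapping[str, float]] = None,
) -> Superposition:
    """Find the rigid pose of B onto A maximizing ST (ST-opt) or ST+CT (CT-opt).

    Both molecules are centered and aligned to their principal axes; the four
    proper axis flips (plus twelve extra 90° rotations under
    ``starts="thorough"``) seed a derivative-free simplex search over a
    rotation vector and translation. Deterministic for fixed inputs. CT-opt
    on feature-free molecules falls back to the shape objective (logged).
    """
    mode = OptMode(mode)
    pa, ra = _shape_arrays(conf_a, radii)
    pb, rb = _shape_arrays(conf_b, radii)
    ca, va = _canonical_frame(pa)
    cb, vb = _canonical_frame(pb)
    xa = (pa - ca) @ va  # canonical-frame coordinates of A
    xb0 = (pb - cb) @ vb

    ga = _feature_arrays(conf_a)
    gb = _feature_arrays(conf_b)
    use_color = mode is OptMode.CT_OPT
    if use_color and not ga and not gb:
        logger.info(
            "CT-opt requested for feature-free pair (%d:%d, %d:%d); "
            "optimizing shape objective",
            conf_a.compound_id, conf_a.conformer_index,
            conf_b.compound_id, conf_b.conformer_index,
        )
        use_color = False

    fa = {t: ((p - ca) @ va, r) for t, (p, r) in ga.items()}
    fb0 = {t: ((p - cb) @ vb, r) for t, (p, r) in gb.items()}

    vaa = gaussian_overlap_volume(xa, ra, xa, ra)
    vbb = gaussian_overlap_volume(xb0, rb, xb0, rb)
    caa = sum(gaussian_overlap_volume(p, r, p, r) for p, r in fa.values())
    cbb = sum(gaussian_overlap_volume(p, r, p, r) for p, r in fb0.values())
    shared_types = set(fa) & set(fb0)

    def scores_at(xb, fb) -> tuple[float, float]:
        vab = gaussian_overlap_volume(xa, ra, xb, rb)
        st = vab / (vaa + vbb - vab)
        cab = 0.0
        for t in shared_types:
            p_a, r_a = fa[t]
            p_b, r_b = fb[t]
            cab += gaussian_overlap_volume(p_a, r_a, p_b, r_b)
        cden = caa + cbb - cab
        ct = cab / cden if cden > 0 else 0.0
        return st, ct

    def transform_b(flip: np.ndarray, x: np.ndarray):
        rot = Rotation.from_rotvec(x[:3]).as_matrix() @ flip
        t = x[3:]
        xb = xb0 @ rot.T + t
        fb = {ty: (p @ rot.T + t, r) for ty, (p, r) in fb0.items()}
        return rot, xb, fb

    def objective(x: np.ndarray, flip: np.ndarray) -> float:
        _, xb, fb = transform_b(flip, x)
        st, ct = scores_at(xb, fb)
        return -(st + ct) if use_color else -st

    start_mats = list(_FLIP_STARTS)
    if starts == "thorough":
        start_mats += _extra_starts()

    best = None
    for flip in start_mats:
        res = minimize(
            objective,
            np.zeros(6),
            args=(flip,),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-5, "maxiter": 800},
        )
        if best is None or res.fun < best[0]:
            best = (res.fun, flip, res.x)

    _, flip, x = best
    rot_can, xb, fb = transform_b(flip, x)
    st, ct = scores_at(xb, fb)
    if not shared_types and not (ga or gb):
        ct = 0.0  # both feature-free: stated 0/0 convention

    # compose the full original-frame transform: b -> va (R (vb^T (b - cb))) + va t + ca
    r_total = va @ rot_can @ vb.T
    t_total = va @ x[3:] + ca - r_total @ cb
    return Superposition(r_total, t_total, mode, float(st), float(ct))


# ---------------------------------------------------------------------------
# Diverse conformer selection
# ---------------------------------------------------------------------------

def _centered_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def select_diverse_conformers(
    conformers: Sequence[Conformer], n_max: int = 10
) -> list[Conformer]:
    """Max–min selection of up to ``n_max`` diverse conformers of one compound.

    Diversity distance is heavy-atom RMSD after centroid alignment. The seed
    is the lowest conformer index; each round adds the conformer maximizing
    the minimum RMSD to the selected set, ties broken by lowest index. With
    ``len(conformers) <= n_max`` the input is returned unchanged.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if len(conformers) <= n_max:
        return list(conformers)
    pool = sorted(conformers, key=lambda c: c.conformer_index)
    selected = [pool[0]]
    remaining = pool[1:]
    while len(selected) < n_max and remaining:
        best_c, best_d = None, -1.0
        for cand in remaining:  # pool order = index order, so ties keep lowest
            dmin = min(_centered_rmsd(cand.coords, s.coords) for s in selected)
            if dmin > best_d + 1e-12:
                best_c, best_d = cand, dmin
        selected.append(best_c)
        remaining.remove(best_c)
    return selected


# ---------------------------------------------------------------------------
# Score cache
# ---------------------------------------------------------------------------

@dataclass
class ScoreCacheEntry:
    key: tuple[int, int, int, int, str]  # cid_a, conf_a, cid_b, conf_b, mode
    st: float
    ct: float
    combo: float
    rotation: np.ndarray
    translation: np.ndarray


def _canonical_key(cid_a, conf_a, cid_b, conf_b, mode):
    mode = OptMode(mode).value
    if (cid_a, conf_a) <= (cid_b, conf_b):
        return (cid_a, conf_a, cid_b, conf_b, mode), False
    return (cid_b, conf_b, cid_a, conf_a, mode), True


class ScoreCache:
    """Warehouse of optimized pairwise 3-D scores with their transforms.

    Keys are stored in canonical (a <= b) order; lookups in either direction
    return the same scores, with the transform inverted when the requested
    orientation is the swap of the stored one. Persisted as a TSV with 17
    significant digits so reload is bit-identical.
    """

    COLUMNS = (
        ["cid_a", "conf_a", "cid_b", "conf_b", "mode", "st", "ct", "combo"]
        + [f"r{i}{j}" for i in range(1, 4) for j in range(1, 4)]
        + ["t1", "t2", "t3"]
    )

    def __init__(self, path=None):
        self._entries: dict[tuple, ScoreCacheEntry] = {}
        self.path = Path(path) if path is not None else None
        if self.path is not None and self.path.exists():
            self.load(self.path)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key) -> bool:
        ckey, _ = _canonical_key(*key)
        return ckey in self._entries

    def put(self, entry: ScoreCacheEntry) -> None:
        ckey, swapped = _canonical_key(*entry.key)
        if swapped:
            raise ValueError("cache entries must be stored in canonical order")
        self._entries[ckey] = entry

    def get(self, cid_a, conf_a, cid_b, conf_b, mode) -> Optional[ScoreCacheEntry]:
        ckey, swapped = _canonical_key(cid_a, conf_a, cid_b, conf_b, mode)
        entry = self._entries.get(ckey)
        if entry is None or not swapped:
            return entry
        rt = entry.rotation.T
        return ScoreCacheEntry(
            (cid_a, conf_a, cid_b, conf_b, OptMode(mode).value),
            entry.st, entry.ct, entry.combo,
            rt, -rt @ entry.translation,
        )

    def save(self, path=None) -> None:
        path = Path(path) if path is not None else self.path
        if path is None:
            raise ValueError("no cache path given")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(self.COLUMNS) + "\n")
            for key in sorted(self._entries):
                e = self._entries[key]
                nums = list(e.rotation.ravel()) + list(e.translation)
                fh.write(
                    "\t".join(
                        [str(key[0]), str(key[1]), str(key[2]), str(key[3]), key[4],
                         f"{e.st:.17g}", f"{e.ct:.17g}", f"{e.combo:.17g}"]
                        + [f"{x:.17g}" for x in nums]
                    )
                    + "\n"
                )

    def load(self, path) -> None:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
            for line_no, line in enumerate(fh, start=2):
                parts = line.rstrip("\n").split("\t")
                try:
                    if len(parts) != len(self.COLUMNS):
                        raise ValueError("wrong column count")
                    cid_a, conf_a, cid_b, conf_b = map(int, parts[:4])
                    mode = OptMode(parts[4]).value
                    st, ct, combo = map(float, parts[5:8])
                    nums = np.array([float(x) for x in parts[8:20]])
                except (ValueError, IndexError):
                    logger.warning(
                        "skipping corrupt cache row %d in %s", line_no, path
                    )
                    continue
                entry = ScoreCacheEntry(
                    (cid_a, conf_a, cid_b, conf_b, mode),
                    st, ct, combo, nums[:9].reshape(3, 3), nums[9:],
                )
                self._entries[entry.key] = entry


def conformer_pair_score(
    conf_a: Conformer,
    conf_b: Conformer,
    mode: OptMode | str,
    cache: Optional[ScoreCache] = None,
    starts: str = "standard",
) -> tuple[float, float, float]:
    """Optimized (st, ct, combo) for a conformer pair; cache-aware.

    Optimization always runs in canonical pair order (smaller compound id,
    then conformer index first) so scores are reproducible regardless of
    argument order.
    """
    mode = OptMode(mode)
    ka = (conf_a.compound_id, conf_a.conformer_index)
    kb = (conf_b.compound_id, conf_b.conformer_index)
    if cache is not None:
        hit = cache.get(*ka, *kb, mode)
        if hit is not None:
            return hit.st, hit.ct, hit.combo
    first, second = (conf_a, conf_b) if ka <= kb else (conf_b, conf_a)
    pose = optimize_superposition(first, second, mode, starts=starts)
    if cache is not None:
        key = (
            first.compound_id, first.conformer_index,
            second.compound_id, second.conformer_index, mode.value,
        )
        cache.put(
            ScoreCacheEntry(key, pose.st, pose.ct, pose.combo,
                            pose.rotation, pose.translation)
        )
    return pose.st, pose.ct, pose.combo


def precompute_pair_scores(
    conformers_by_compound: Mapping[int, Sequence[Conformer]],
    records: Iterable[ActivityRecord],
    modes: Sequence[OptMode | str] = (OptMode.ST_OPT, OptMode.CT_OPT),
    cache: Optional[ScoreCache] = None,
    n_max: int = 10,
) -> ScoreCache:
    """Pre-compute 3-D scores for compound pairs co-tested non-inactive in at
    least one common assay; idempotent (cached keys are skipped)."""
    if cache is None:
        cache = ScoreCache()
    by_assay: dict[int, set[int]] = {}
    for rec in records:
        if rec.outcome is not Outcome.INACTIVE and rec.compound_id in conformers_by_compound:
            by_assay.setdefault(rec.assay_id, set()).add(rec.compound_id)
    pairs: set[tuple[int, int]] = set()
    for cids in by_assay.values():
        ordered = sorted(cids)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1:]:
                pairs.add((a, b))
    diverse = {
        cid: select_diverse_conformers(confs, n_max)
        for cid, confs in conformers_by_compound.items()
    }
    for a, b in sorted(pairs):
        for conf_a in diverse[a]:
            for conf_b in diverse[b]:
                for mode in modes:
                    conformer_pair_score(conf_a, conf_b, mode, cache=cache)
    return cache
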