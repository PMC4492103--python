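"""Independent reference implementations used only to check the package.

These deliberately share no code with sarclust: the Gaussian overlap oracle
integrates the product density on a 3-D grid, the clustering oracle is a
plain-Python leader algorithm over sets, and the superposition oracle is an
exhaustive rotation-grid search.
"""
from __future__ import annotations

import math

import numpy as np


def grid_overlap_volume(pos_a, rad_a, pos_b, rad_b, spacing=0.1, pad=5.0,
                        weight=2.7):
    """Numerically integrate the product of the two Gaussian densities on a
    regular grid (spacing in Å, box padded around the union of atoms)."""
    pos_a = np.asarray(pos_a, float).reshape(-1, 3)
    pos_b = np.asarray(pos_b, float).reshape(-1, 3)
    rad_a = np.broadcast_to(np.asarray(rad_a, float), (len(pos_a),))
    rad_b = np.broadcast_to(np.asarray(rad_b, float), (len(pos_b),))
    allp = np.vstack([pos_a, pos_b])
    lo, hi = allp.min(axis=0) - pad, allp.max(axis=0) + pad
    axes = [np.arange(l, h + spacing, spacing) for l, h in zip(lo, hi)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij", sparse=True)

    def density(points, radii):
        rho = np.zeros((len(axes[0]), len(axes[1]), len(axes[2])))
        alphas = np.pi * (3.0 * weight / (4.0 * np.pi * radii**3)) ** (2.0 / 3.0)
        for p, a in zip(points, alphas):
            rho += weight * np.exp(
                -a * ((gx - p[0]) ** 2 + (gy - p[1]) ** 2 + (gz - p[2]) ** 2)
            )
        return rho

    return float(np.sum(density(pos_a, rad_a) * density(pos_b, rad_b))
                 * spacing**3)


def pairwise_overlap_sum(atoms_a, atoms_b, weight=2.7):
    """Closed-form pairwise overlap computed with scalar math only:
    atoms are (x, y, z, radius) tuples."""
    total = 0.0
    for (xa, ya, za, ra) in atoms_a:
        aa = math.pi * (3.0 * weight / (4.0 * math.pi * ra**3)) ** (2.0 / 3.0)
        for (xb, yb, zb, rb) in atoms_b:
            ab = math.pi * (3.0 * weight / (4.0 * math.pi * rb**3)) ** (2.0 / 3.0)
            d2 = (xa - xb) ** 2 + (ya - yb) ** 2 + (za - zb) ** 2
            total += (
                weight * weight
                * (math.pi / (aa + ab)) ** 1.5
                * math.exp(-aa * ab * d2 / (aa + ab))
            )
    return total


def naive_leader_clusters(items, dmat, threshold, strict=False):
    """Plain-Python leader algorithm: returns a list of (representative,
    frozenset(members)) including singletons. ``dmat`` is indexed by item."""
    unassigned = set(items)
    clusters = []
    while unassigned:
        best_item, best_count = None, -1
        for it in sorted(unassigned):
            neighbors = sum(
                1
                for other in unassigned
                if other != it
                and (
                    dmat[(it, other)] < threshold
                    if strict
                    else dmat[(it, other)] <= threshold
                )
            )
            if neighbors > best_count:
                best_item, best_count = it, neighbors
        if best_count <= 0:
            break
        members = {best_item} | {
            other
            for other in unassigned
            if other != best_item
            and (
                dmat[(best_item, other)] < threshold
                if strict
                else dmat[(best_item, other)] <= threshold
            )
        }
        clusters.append((best_item, frozenset(members)))
        unassigned -= members
    for it in sorted(unassigned):
        clusters.append((it, frozenset({it})))
    return clusters


def rotation_grid_best_st(coords_a, coords_b, radius=1.7, step_deg=10.0):
    """Exhaustive rigid-alignment oracle: best shape-Tanimoto over an Euler
    rotation grid with centroid translation."""
    coords_a = np.asarray(coords_a, float)
    coords_b = np.asarray(coords_b, float)
    ca = coords_a - coords_a.mean(axis=0)
    cb = coords_b - coords_b.mean(axis=0)
    atoms_a = [(x, y, z, radius) for x, y, z in ca]
    vaa = pairwise_overlap_sum(atoms_a, atoms_a)
    atoms_b0 = [(x, y, z, radius) for x, y, z in cb]
    vbb = pairwise_overlap_sum(atoms_b0, atoms_b0)
    best = 0.0
    step = math.radians(step_deg)
    alphas = np.arange(0, 2 * math.pi, step)
    betas = np.arange(0, math.pi + 1e-9, step)
    gammas = np.arange(0, 2 * math.pi, step)
    for al in alphas:
        ra = np.array([[math.cos(al), -math.sin(al), 0],
                       [math.sin(al), math.cos(al), 0], [0, 0, 1]])
        for be in betas:
            rb = np.array([[math.cos(be), 0, math.sin(be)], [0, 1, 0],
                           [-math.sin(be), 0, math.cos(be)]])
            for ga in gammas:
                rc = np.array([[math.cos(ga), -math.sin(ga), 0],
                               [math.sin(ga), math.cos(ga), 0], [0, 0, 1]])
                rot = ra @ rb @ rc
                moved = cb @ rot.T
                atoms_b = [(x, y, z, radius) for x, y, z in moved]
                vab = pairwise_overlap_sum(atoms_a, atoms_b)
                st = vab / (vaa + vbb - vab)
                if st > best:
                    best = st
    return best


def maxmin_selection_bruteforce(coord_sets, indices, n_max):
    """Independent max-min diversity selection over centroid-aligned RMSD.

    ``coord_sets``: dict index -> (n, 3) array. Returns selected indices in
    selection order, seeded at the smallest index, ties to smallest index.
    """

    def rmsd(i, j):
        a = coord_sets[i] - coord_sets[i].mean(axis=0)
        b = coord_sets[j] - coord_sets[j].mean(axis=0)
        return math.sqrt(float(np.mean(np.sum((a - b) ** 2, axis=1))))

    remaining = sorted(indices)
    selected = [remaining.pop(0)]
    while len(selected) < n_max and remaining:
        scored = [(min(rmsd(c, s) for s in selected), -c) for c in remaining]
        best = max(range(len(scored)), key=lambda k: scored[k])
        selected.append(remaining.pop(best))
    return selected
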