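"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths under test: rotation optimisation by
quaternion search instead of SVD, midranks by position averaging instead of
scipy, pocket scans by all-pairs loops instead of KD-trees.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def quaternion_rotation(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a (normalised) quaternion (w, x, y, z)."""
    w, x, y, z = q / np.linalg.norm(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def quaternion_min_rmsd(mobile: np.ndarray, target: np.ndarray, seed: int = 0,
                        n_starts: int = 2000) -> float:
    """Minimal RMSD over rotations by quaternion search + simplex refinement.

    Centroids are removed (optimal translation), then the rotation is found
    by evaluating ``n_starts`` random unit quaternions and refining the best
    five by Nelder–Mead.  No SVD anywhere.
    """
    p = mobile - mobile.mean(axis=0)
    q = target - target.mean(axis=0)
    n = len(p)

    def rmsd_of(quat: np.ndarray) -> float:
        r = quaternion_rotation(quat)
        return float(np.sqrt(((p @ r.T - q) ** 2).sum() / n))

    rng = np.random.default_rng(seed)
    quats = rng.normal(size=(n_starts, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    values = np.array([rmsd_of(quat) for quat in quats])
    best = np.inf
    for idx in np.argsort(values)[:5]:
        res = minimize(rmsd_of, quats[idx], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, res.fun)
    return best


def brute_force_midranks(values) -> np.ndarray:
    """Midranks as the average 1-based position among equal values."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def brute_force_spearman(x, y) -> float:
    """Spearman rho as Pearson correlation of brute-force midranks."""
    rx = brute_force_midranks(x)
    ry = brute_force_midranks(y)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    vx = (sx**2).sum()
    vy = (sy**2).sum()
    if vx == 0 or vy == 0:
        return float("nan")
    return float((sx * sy).sum() / np.sqrt(vx * vy))


def brute_force_pockets(coords: np.ndarray, atom_residue, residues, chains,
                        peptide_chain: str, position_map, cutoff: float):
    """All-pairs O(N²) pocket scan; returns pocket label -> set of residues."""
    pockets: dict[str, set] = {}
    for pep_res, p_label in position_map.items():
        lab = "S" + p_label[1:]
        pockets.setdefault(lab, set())
        pep_atoms = [i for i, ri in enumerate(atom_residue) if residues[ri] == pep_res]
        for i, ri in enumerate(atom_residue):
            res = residues[ri]
            if res.chain == peptide_chain:
                continue
            for j in pep_atoms:
                if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                    pockets[lab].add(res)
                    break
    return pockets
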