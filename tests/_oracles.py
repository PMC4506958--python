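"""Independent oracles used only by tests.

These deliberately avoid the package's own code paths: the quaternion RMSD
uses Horn's eigenvalue method instead of SVD; the clustering oracle is a
direct transliteration of the greedy neighbor-count procedure with plain
loops; the packing oracle enumerates gemmi's operator tables over a fixed
shift range.
"""

import gemmi
import numpy as np


def quaternion_rmsd(ref: np.ndarray, mov: np.ndarray) -> float:
    """Minimal RMSD after optimal rotation, via Horn's quaternion eigenproblem."""
    P = np.asarray(ref, float)
    Q = np.asarray(mov, float)
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    S = Q.T @ P  # S[a, b] = sum_i Q[i, a] P[i, b]
    sxx, sxy, sxz = S[0]
    syx, syy, syz = S[1]
    szx, szy, szz = S[2]
    K = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    e0 = (P ** 2).sum() + (Q ** 2).sum()
    msd = max(0.0, (e0 - 2.0 * lam) / len(P))
    return float(np.sqrt(msd))


def exhaustive_daura(values: np.ndarray, cutoff: float) -> list[tuple[int, set]]:
    """Greedy neighbor-count clustering, written with explicit loops."""
    n = values.shape[0]
    remaining = set(range(n))
    clusters = []
    while remaining:
        best_center, best_neighbors = None, None
        for i in sorted(remaining):
            neighbors = {j for j in remaining if j != i and values[i, j] < cutoff}
            if best_neighbors is None or len(neighbors) > len(best_neighbors):
                best_center, best_neighbors = i, neighbors
        members = {best_center} | best_neighbors
        clusters.append((best_center, members))
        remaining -= members
    return clusters


def brute_force_packing(model, cutoff: float, max_shift: int = 2) -> tuple[int, int]:
    """Ligand contact counts from exhaustive gemmi-operator enumeration."""
    sg = gemmi.find_spacegroup_by_name(model.spacegroup.hm_symbol)
    ortho = model.cell.orthogonalization_matrix
    frac = np.linalg.inv(ortho)
    coords = model.coords()
    prot = np.array([coords[i] for i, a in enumerate(model.atoms)
                     if not a.is_het and not a.is_water
                     and a.element.upper() != "H"])
    lig = np.array([coords[i] for i, a in enumerate(model.atoms)
                    if a.is_het and not a.is_water and a.element.upper() != "H"])
    prot_frac = prot @ frac.T
    n_asu = n_sym = 0
    ops = list(sg.operations())
    for k, op in enumerate(ops):
        rot = np.array(op.rot, float) / gemmi.Op.DEN
        tran = np.array(op.tran, float) / gemmi.Op.DEN
        base = prot_frac @ rot.T + tran
        for sx in range(-max_shift, max_shift + 1):
            for sy in range(-max_shift, max_shift + 1):
                for sz in range(-max_shift, max_shift + 1):
                    xyz = (base + np.array([sx, sy, sz])) @ ortho.T
                    d = np.linalg.norm(lig[:, None, :] - xyz[None, :, :], axis=2)
                    count = int((d <= cutoff).sum())
                    if k == 0 and (sx, sy, sz) == (0, 0, 0):
                        n_asu += count
                    else:
                        n_sym += count
    return n_asu, n_sym


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random proper rotation plus a random translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=10.0, size=3)
    return Q, t
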