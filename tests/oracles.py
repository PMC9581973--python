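"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (double loops, scalar math) and shares
no code paths with the vectorized detectors it checks.
"""

from __future__ import annotations

import math

import numpy as np


def plane_of(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane via SVD: (centroid, unit normal, canonical sign)."""
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    normal = vt[2]
    for axis in (2, 0, 1):
        if normal[axis] > 1e-12:
            break
        if normal[axis] < -1e-12:
            normal = -normal
            break
    return centroid, normal


def stack_pairs_bruteforce(positions, base_rings, quin_rings, cutoff, guard):
    """All (base ring index, quinoline ring index) stacked pairs, O(B*Q)."""
    hits = set()
    for bi, br in enumerate(base_rings):
        cb, nb = plane_of(positions[br.atom_indices])
        for qi, qr in enumerate(quin_rings):
            cq, nq = plane_of(positions[qr.atom_indices])
            nq_al = -nq if float(np.dot(nb, nq)) < 0 else nq
            bis = nb + nq_al
            bis = bis / np.linalg.norm(bis)
            d = cq - cb
            vsep = abs(float(np.dot(d, bis)))
            cdist = float(np.linalg.norm(d))
            if vsep < cutoff and cdist < cutoff + guard:
                hits.add((bi, qi))
    return hits


def hbonds_bruteforce(positions, das, dist_cutoff, angle_cutoff):
    """All (donor index, acceptor index) hydrogen bonds, O(D*A)."""
    hits = set()
    for i in range(len(das.donors)):
        d = positions[das.donors[i, 0]]
        h = positions[das.donors[i, 1]]
        for j in range(len(das.acceptors)):
            if das.acceptor_molecule_ids[j] == das.donor_molecule_ids[i]:
                continue
            if das.acceptors[j] == das.donors[i, 0]:
                continue
            a = positions[das.acceptors[j]]
            r = float(np.linalg.norm(a - d))
            if r > dist_cutoff:
                continue
            v1, v2 = h - d, a - d
            cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if ang <= angle_cutoff:
                hits.add((i, j))
    return hits


def nonbonded_bruteforce(positions, group_a, group_b, charges, sigmas, epsilons, cutoff):
    """Scalar double-loop Coulomb + LJ cross sum with Lorentz-Berthelot rules."""
    f = 138.935458
    coul = lj = 0.0
    for i in group_a:
        for j in group_b:
            r = float(np.linalg.norm(positions[j] - positions[i]))
            if r > cutoff:
                continue
            coul += f * charges[i] * charges[j] / r
            sig = 0.5 * (sigmas[i] + sigmas[j])
            eps = math.sqrt(epsilons[i] * epsilons[j])
            sr6 = (sig / r) ** 6
            lj += 4.0 * eps * (sr6 * sr6 - sr6)
    return coul, lj
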