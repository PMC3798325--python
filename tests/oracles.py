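"""Independent brute-force oracles used by the test suite.

Deliberately naive re-implementations of the quantities under test,
written against the definitions rather than the library code paths.
"""

from __future__ import annotations

from collections import Counter

import numpy as np


def two_sphere_accessible_area(ra, rb, d):
    """Accessible area of expanded sphere A occluded by expanded sphere B.

    Closed-form spherical-cap geometry; ra/rb are the solvent-expanded
    radii and d the center distance.
    """
    if d >= ra + rb:
        return 4.0 * np.pi * ra**2
    if d + ra <= rb:
        return 0.0
    x = (d * d + ra * ra - rb * rb) / (2.0 * d)
    h = ra - x
    return 4.0 * np.pi * ra**2 - 2.0 * np.pi * ra * h


def wu_kabat_brute(column):
    counts = Counter(c for c in column if c != "-")
    ks = list(counts.values())
    return sum(ks) * len(ks) / max(ks)


def chain_ca(chain):
    """Residue number -> Cα coordinates for a single-chain structure."""
    out = {}
    for res in chain.residues:
        ca = res.atom("CA")
        out[res.number] = np.asarray(ca.pos)
    return out


def epitopes_brute(chain, rel_sasa, *, center_t=75.0, member_t=20.0,
                   merge_r=5.0, expand_r=10.0):
    """Three-rule prediction recomputed by exhaustive loops.

    ``rel_sasa`` maps residue number -> relative SASA (%).  Returns a list
    of (centers frozenset, members frozenset) ordered by smallest center,
    using residue numbers.
    """
    ca = chain_ca(chain)
    centers = sorted(r for r, v in rel_sasa.items() if v > center_t)
    # transitive closure by repeated passes (single linkage)
    groups = [{c} for c in centers]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if any(
                    np.linalg.norm(ca[a] - ca[b]) < merge_r
                    for a in groups[i]
                    for b in groups[j]
                ):
                    groups[i] |= groups[j]
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    groups.sort(key=min)
    order = [res.number for res in chain.residues]
    out = []
    for g in groups:
        members = set(g)
        for r in order:
            if r in members or not rel_sasa[r] > member_t:
                continue
            if any(np.linalg.norm(ca[r] - ca[c]) < expand_r for c in g):
                members.add(r)
        # one pass of single-gap filling over chain order
        filled = set(members)
        for k in range(1, len(order) - 1):
            if (
                order[k] not in members
                and order[k - 1] in members
                and order[k + 1] in members
            ):
                filled.add(order[k])
        out.append((frozenset(g), frozenset(filled)))
    return out


def best_hamming_offset(seq, pattern):
    best = (len(pattern) + 1, 0)
    for off in range(len(seq) - len(pattern) + 1):
        mm = sum(a != b for a, b in zip(seq[off : off + len(pattern)], pattern))
        if mm < best[0]:
            best = (mm, off)
    return best  # (mismatches, offset)


def rmsd_by_minimisation(x, y):
    """Best-fit RMSD via generic numeric optimisation over rigid motions."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    xc = x - x.mean(0)
    yc = y - y.mean(0)

    def cost(v):
        r = Rotation.from_rotvec(v).as_matrix()
        return np.sqrt(((yc @ r.T - xc) ** 2).sum(-1).mean())

    best = None
    for v0 in ([0.1, 0.0, 0.0], [1.5, 0.5, -0.5], [-1.0, 2.0, 1.0], [3.0, 0.0, 3.0]):
        res = minimize(cost, v0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        if best is None or res.fun < best:
            best = res.fun
    return best
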