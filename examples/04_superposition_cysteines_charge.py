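"""Rigid superposition, disulfide screening and formal-charge summaries."""

import numpy as np

from epimap import (
    GlobuleSpec,
    cys_pair_distances,
    kabsch_superpose,
    make_globule,
    sequence_charge,
)

# 1. Kabsch recovery of a planted rigid motion
rng = np.random.default_rng(0)
x = rng.normal(scale=6.0, size=(80, 3))
theta = 0.8
rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1.0]])
y = x @ rot.T + np.array([10.0, -4.0, 2.0])
res = kabsch_superpose(x, y)
print(f"RMSD after superposition: {res.rmsd:.2e} A over {res.n_pairs} pairs")

# 2. Cysteine pairs at planted Calpha separations
structure, truth = make_globule(
    GlobuleSpec(n_residues=50, cys_pairs=((10, 30, 5.6),), seed=3)
)
for pair in cys_pair_distances(structure).pairs:
    print(f"{pair.a.label}-{pair.b.label}: {pair.distance:.2f} A, "
          f"disulfide-feasible: {pair.feasible}")

# 3. Formal charges of a profilin-like sequence
seq = "MSWQAYVDDHLMCDIDGQGSNSLASAIVGHDGSVWAQSSSFPQFKPQEITGIMKDFEEPGHLAPTGLHLGGIKYMVIQGEPGAVIRGKKGSGGITIKKTGQALVFGIYEEPVTPGQCNMVVERLGDYLIDQGL"
charge = sequence_charge(seq)
print(
    f"length {charge.length}: net {charge.net_charge:+d} "
    f"({charge.pct_negative:.2f}% negative, {charge.pct_positive:.2f}% positive)"
)

# A rigid motion is recovered to machine precision (RMSD ~ 1e-15); the
# planted 5.6 A pair falls inside the canonical 3.0-7.5 A cystine window;
# the charge summary counts Asp/Glu as -1 and Lys/Arg as +1.
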