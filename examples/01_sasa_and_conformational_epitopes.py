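"""Predict conformational epitopes on a synthetic globule.

Builds a 60-residue globule with three residues displaced far enough
outward to be protruding (relative SASA > 75%), computes Gly-X-Gly
relative accessibility, and runs the three-rule epitope prediction.
"""

from epimap import (
    EpitopeParams,
    GlobuleSpec,
    SasaConfig,
    compute_exposures,
    make_globule,
    predict_epitopes,
)

structure, truth = make_globule(
    GlobuleSpec(n_residues=60, protruding=(8, 25, 47), seed=42)
)
exposures = compute_exposures(structure, SasaConfig(n_points=480))

protruding = [e for e in exposures if e.protruding]
print(f"planted protruding residues: {truth.protruding_resnums}")
print(f"detected protruding residues: {[e.ref.number for e in protruding]}")

table = predict_epitopes(structure, exposures, EpitopeParams())
for row in table:
    centers = ",".join(c.label for c in row.centers)
    print(f"epitope {row.epitope_id}: center {centers}, {row.n_residues} residues")

# Each epitope is a surface patch: its center(s) plus every partially
# accessible residue within 10 A, plus single sequence gaps.  The planted
# residues seed exactly one epitope each because they are >10 A apart.
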