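"""Overlap of linear B-/T-cell epitopes with conformational epitopes.

Maps the monoclonal-defined linear profilin epitopes (10A4, 3H8, ...)
onto a chain by best Hamming match, then classifies each conformational
epitope's overlap with every mapped span.
"""

from epimap import EpitopeRow, EpitopeTable, map_linear, overlap_summary
from epimap.reference import load_linear_bcell_epitopes
from epimap.structio import Atom, Chain, Residue, ResidueRef, Structure, THREE_TO_ONE

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# a toy chain embedding two of the published epitope peptides
sequence = "GGAMSWQAYVGGDDAGGERLGDYGGAA"
chain = Chain(id="A")
for i, aa in enumerate(sequence):
    chain.residues.append(
        Residue(number=i + 1, icode="", name=ONE_TO_THREE[aa],
                atoms=[Atom(name="CA", element="C", x=float(i) * 3.8, y=0, z=0)])
    )

mapped = []
for epitope in load_linear_bcell_epitopes():
    try:
        m = map_linear(chain, epitope, max_mismatches=1)
    except Exception:
        continue
    mapped.append(m)
    span = f"{m.span[0].number}-{m.span[-1].number}"
    print(f"{m.label} mapped at residues {span} with {m.mismatches} mismatch(es)")

members = [ResidueRef("A", n, "", chain.residues[n - 1].name) for n in range(2, 13)]
conf = EpitopeTable(rows=[EpitopeRow(
    structure_id="toy", epitope_id=1, centers=[members[0]], members=members)])

report = overlap_summary(conf, mapped)
for (eid, label), ov in report.matrix.items():
    print(f"conformational {eid} vs {label}: {ov.klass} ({ov.shared} shared)")
print(f"rollup: {report.rollup}")

# 10A4 (MSWQAYV) sits fully inside the conformational member set 2-12, so
# the overlap is "total"; 3H8 (ERLGDY) maps downstream and is disjoint.
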