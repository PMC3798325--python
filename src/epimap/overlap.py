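"""Linear-epitope localisation and overlap with conformational epitopes.

Linear B-cell epitopes (antibody-defined peptides) and T-cell anchor
9-mers are placed on a chain by best ungapped sequence match, then each
conformational epitope's member set is intersected with every mapped span.
Overlap is *total* when the linear span is fully contained in the
conformational member set, *partial* otherwise (if non-empty), *none* when
disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .structio import Chain, EpitopeTable, ResidueRef, chain_sequence

__all__ = [
    "LinearEpitope",
    "MappedEpitope",
    "Overlap",
    "OverlapReport",
    "UnmappedError",
    "map_linear",
    "anchor_to_epitope",
    "classify_overlap",
    "overlap_summary",
]


@dataclass(frozen=True)
class LinearEpitope:
    label: str  # e.g. "10A4"
    kind: str  # "bcell" | "tcell"
    sequence: str  # defining peptide


def anchor_to_epitope(
    anchor_label: str, reference_sequence: str, length: int = 9
) -> LinearEpitope:
    """T-cell epitope peptide from an anchor start label like ``L70``.

    The 9-mer convention of HLA-DR binding cores; the peptide is read off
    the supplied reference sequence at the anchor's 1-based position.
    """
    aa, pos = anchor_label[0], int(anchor_label[1:])
    if not 1 <= pos <= len(reference_sequence) - length + 1:
        raise ValueError(f"anchor {anchor_label} out of range for sequence")
    if reference_sequence[pos - 1] != aa:
        raise ValueError(
            f"anchor {anchor_label}: reference has {reference_sequence[pos - 1]!r} "
            f"at position {pos}"
        )
    return LinearEpitope(
        label=anchor_label, kind="tcell",
        sequence=reference_sequence[pos - 1 : pos - 1 + length],
    )


@dataclass
class MappedEpitope:
    epitope: LinearEpitope
    chain_id: str
    span: list[ResidueRef]  # contiguous chain residues
    mismatches: int

    @property
    def label(self) -> str:
        return self.epitope.label

    @property
    def kind(self) -> str:
        return self.epitope.kind


class UnmappedError(Exception):
    def __init__(self, epitope: LinearEpitope, best_offset: int, best_mismatches: int):
        self.epitope = epitope
        self.best_offset = best_offset
        self.best_mismatches = best_mismatches
        super().__init__(
            f"epitope {epitope.label!r} not mappable: best candidate at offset "
            f"{best_offset} with {best_mismatches} mismatches"
        )


def map_linear(
    chain: Chain, epitope: LinearEpitope, max_mismatches: int = 2
) -> MappedEpitope:
    """Best ungapped (Hamming) placement of the epitope on the chain.

    Fewest mismatches wins; ties go to the leftmost offset.  Fails if the
    best placement exceeds ``max_mismatches``.
    """
    seq = chain_sequence(chain)
    pat = epitope.sequence.upper()
    if len(pat) > len(seq):
        raise UnmappedError(epitope, 0, len(pat))
    best_off, best_mm = 0, len(pat) + 1
    for off in range(len(seq) - len(pat) + 1):
        mm = sum(1 for a, b in zip(seq[off : off + len(pat)], pat) if a != b)
        if mm < best_mm:
            best_off, best_mm = off, mm
    if best_mm > max_mismatches:
        raise UnmappedError(epitope, best_off, best_mm)
    span = [
        ResidueRef(chain.id, r.number, r.icode, r.name)
        for r in chain.residues[best_off : best_off + len(pat)]
    ]
    return MappedEpitope(
        epitope=epitope, chain_id=chain.id, span=span, mismatches=best_mm
    )


@dataclass(frozen=True)
class Overlap:
    klass: str  # "total" | "partial" | "none"
    shared: int


def classify_overlap(
    conf_members: set[ResidueRef], linear: MappedEpitope
) -> Overlap:
    """Overlap class of one conformational member set vs one mapped span."""
    span = set(linear.span)
    shared = len(conf_members & span)
    if shared == 0:
        klass = "none"
    elif shared == len(span):
        klass = "total"
    else:
        klass = "partial"
    return Overlap(klass=klass, shared=shared)


@dataclass
class OverlapReport:
    matrix: dict[tuple[int, str], Overlap]  # (epitope_id, linear label) -> overlap
    rollup: dict[int, str] = field(default_factory=dict)
    # rollup classes: overlaps-B-only / overlaps-T-only / both / neither


def overlap_summary(
    table: EpitopeTable, mapped: list[MappedEpitope]
) -> OverlapReport:
    """Full overlap matrix plus a per-conformational-epitope rollup."""
    matrix = {}
    rollup = {}
    for row in table:
        members = set(row.members)
        hits_b = hits_t = False
        for lin in mapped:
            ov = classify_overlap(members, lin)
            matrix[(row.epitope_id, lin.label)] = ov
            if ov.shared > 0:
                if lin.kind == "bcell":
                    hits_b = True
                elif lin.kind == "tcell":
                    hits_t = True
        if hits_b and hits_t:
            rollup[row.epitope_id] = "both"
        elif hits_b:
            rollup[row.epitope_id] = "overlaps-B-only"
        elif hits_t:
            rollup[row.epitope_id] = "overlaps-T-only"
        else:
            rollup[row.epitope_id] = "neither"
    return OverlapReport(matrix=matrix, rollup=rollup)
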