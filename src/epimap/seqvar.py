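"""Alignment-column variability and epitope-variant quantification.

Wu–Kabat variability per column (V = N·k/n over non-gap residues), a
normalised index for low/intermediate/high classification, enumeration of
the distinct sequence variants of a region across an alignment with their
frequencies, and presence/frequency analysis of HLA-DR anchor motifs
across sequence groups.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .structio import MSA

__all__ = [
    "ColumnVariability",
    "EpitopeVariantTable",
    "VariantRow",
    "AnchorMatrix",
    "wu_kabat",
    "variability_profile",
    "extract_region_variants",
    "anchor_analysis",
]

GAP = "-"


@dataclass(frozen=True)
class ColumnVariability:
    ref_position: int  # 1-based ungapped reference position
    v: float  # Wu-Kabat value, >= 1
    viv: float  # v normalised by the per-alignment median of v
    klass: str  # low / intermediate / high


def wu_kabat(column: list[str] | str) -> float:
    """Wu–Kabat variability V = N·k/n of one alignment column.

    N = non-gap residues, k = distinct residues, n = count of the most
    frequent residue.  Gaps are excluded; an all-gap column is undefined.
    """
    counts = Counter(c for c in column if c != GAP)
    if not counts:
        raise ValueError("all-gap column has undefined variability")
    n_total = sum(counts.values())
    k = len(counts)
    n_mode = max(counts.values())
    return n_total * k / n_mode


def variability_profile(
    msa: MSA, thresholds: tuple[float, float] = (1.0, 3.0)
) -> list[ColumnVariability]:
    """Per-reference-position Wu–Kabat profile with normalised classes.

    The normalised index viv = V / median(V) makes the published class
    boundaries (low < 1 <= intermediate <= 3 < high) reachable on both
    sides; raw V is reported alongside.  Columns where the reference is
    gapped are skipped.
    """
    if msa.n_sequences < 2:
        raise ValueError("variability needs at least 2 sequences")
    low, high = thresholds
    cols = sorted(msa.column_to_ref.items())
    values = [(pos, wu_kabat(msa.column(col))) for col, pos in cols]
    median = float(np.median([v for _, v in values]))
    out = []
    for pos, v in values:
        viv = v / median if median > 0 else float("nan")
        if viv < low:
            klass = "low"
        elif viv > high:
            klass = "high"
        else:
            klass = "intermediate"
        out.append(ColumnVariability(ref_position=pos, v=v, viv=viv, klass=klass))
    return out


@dataclass(frozen=True)
class VariantRow:
    suffix: int  # 0 = designated template variant
    sequence: str
    count: int
    frequency: float  # %


@dataclass
class EpitopeVariantTable:
    region_id: str
    start: int  # 1-based inclusive, reference coordinates
    end: int
    rows: list[VariantRow] = field(default_factory=list)
    n_included: int = 0
    excluded: list[str] = field(default_factory=list)  # record ids with unknowns

    def variant(self, suffix: int) -> VariantRow:
        for row in self.rows:
            if row.suffix == suffix:
                return row
        raise KeyError(suffix)

    def label(self, suffix: int) -> str:
        return f"{self.region_id}-{suffix}"


def extract_region_variants(
    msa: MSA,
    region: tuple[str, int, int],
    template: str | None = None,
) -> EpitopeVariantTable:
    """Enumerate distinct region variants across the alignment.

    The region is a reference-coordinate span (1-based inclusive); each
    sequence contributes its ungapped subsequence over the corresponding
    alignment columns, so indels inside the region show up as
    length-variant strings.  Sequences with unknown residues (X) in the
    region are excluded and recorded.  Suffix 0 is the template's variant;
    the rest are numbered by descending frequency (ties: first occurrence
    in input order).
    """
    region_id, start, end = region
    template = template if template is not None else msa.reference
    if template not in dict(msa.records):
        raise KeyError(f"template record {template!r} not in alignment")
    ref_to_col = msa.ref_to_column
    if start < 1 or end > max(ref_to_col) or start > end:
        raise ValueError(
            f"region {region_id}: span {start}-{end} outside reference (1-{max(ref_to_col)})"
        )
    col_lo, col_hi = ref_to_col[start], ref_to_col[end]
    variants: dict[str, int] = {}
    first_seen: dict[str, int] = {}
    excluded = []
    template_variant = None
    for order, (rid, seq) in enumerate(msa.records):
        sub = seq[col_lo : col_hi + 1].replace(GAP, "")
        if "X" in sub:
            excluded.append(rid)
            continue
        variants[sub] = variants.get(sub, 0) + 1
        first_seen.setdefault(sub, order)
        if rid == template:
            template_variant = sub
    n_included = sum(variants.values())
    if n_included == 0:
        raise ValueError(f"region {region_id}: no sequence contributes a complete span")
    ordered = sorted(
        variants.items(), key=lambda kv: (-kv[1], first_seen[kv[0]])
    )
    rows = []
    suffix = 1
    for var, count in ordered:
        if var == template_variant:
            s = 0
        else:
            s = suffix
            suffix += 1
        rows.append(
            VariantRow(
                suffix=s,
                sequence=var,
                count=count,
                frequency=100.0 * count / n_included,
            )
        )
    rows.sort(key=lambda r: r.suffix)
    return EpitopeVariantTable(
        region_id=region_id,
        start=start,
        end=end,
        rows=rows,
        n_included=n_included,
        excluded=excluded,
    )


@dataclass(frozen=True)
class AnchorCell:
    frequency: float  # %
    klass: str  # high / intermediate / low / absent


@dataclass
class AnchorMatrix:
    anchors: list[str]
    groups: list[str]
    cells: dict[tuple[str, str], AnchorCell]
    shared: set[str] = field(default_factory=set)  # high in all groups
    specific: dict[str, str] = field(default_factory=dict)  # anchor -> sole high group


def anchor_analysis(
    anchor_calls: dict[str, set[str]],
    group_of: dict[str, str],
    thresholds: tuple[float, float] = (70.0, 30.0),
) -> AnchorMatrix:
    """Anchor presence frequencies per sequence group.

    ``anchor_calls`` maps sequence id -> set of anchor labels present in
    that sequence (labels are initial-residue tags like ``L70``).  Classes:
    high if frequency > high threshold, low if below the low threshold
    (but present), absent at 0%, intermediate otherwise.  An anchor is
    *shared* when high in every group, *specific* when high in exactly one.
    """
    high_t, low_t = thresholds
    groups = sorted(set(group_of.values()))
    members: dict[str, list[str]] = {g: [] for g in groups}
    for sid, g in group_of.items():
        members[g].append(sid)
    for g, sids in members.items():
        if not sids:
            raise ValueError(f"group {g!r} is empty")
    missing = set(anchor_calls) - set(group_of)
    if missing:
        raise ValueError(f"sequences without a group: {sorted(missing)}")
    anchors = sorted({a for calls in anchor_calls.values() for a in calls})
    cells = {}
    high_in: dict[str, list[str]] = {a: [] for a in anchors}
    for a in anchors:
        for g in groups:
            present = sum(1 for sid in members[g] if a in anchor_calls.get(sid, set()))
            freq = 100.0 * present / len(members[g])
            if freq == 0.0:
                klass = "absent"
            elif freq > high_t:
                klass = "high"
                high_in[a].append(g)
            elif freq < low_t:
                klass = "low"
            else:
                klass = "intermediate"
            cells[(a, g)] = AnchorCell(frequency=freq, klass=klass)
    shared = {a for a in anchors if len(high_in[a]) == len(groups)}
    specific = {a: high_in[a][0] for a in anchors if len(high_in[a]) == 1}
    return AnchorMatrix(
        anchors=anchors, groups=groups, cells=cells, shared=shared, specific=specific
    )
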