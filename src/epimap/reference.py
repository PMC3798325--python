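"""Curated reference tables shipped with the package.

Small published inputs the analyses consume: the discontinuous-epitope map
of the Hev b 8 latex profilin (segments of author-numbered residues), the
five monoclonal-defined linear B-cell profilin epitopes, and the
high-frequency HLA-DR anchor starts per plant species.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

from .overlap import LinearEpitope

__all__ = [
    "ReferenceEpitope",
    "parse_segments",
    "load_hevb8_epitopes",
    "load_linear_bcell_epitopes",
    "load_tcell_anchors",
]

_SEGMENT = re.compile(r"^(\d+)(?:-(\d+))?:([A-Z]+)$")


def parse_segments(text: str) -> list[tuple[int, str]]:
    """Expand ';'-joined residue segments into (number, amino acid) pairs.

    A segment is either ``pos:X`` (one residue) or ``start-end:SEQ`` (a
    contiguous stretch whose sequence length must match the span).
    """
    out: list[tuple[int, str]] = []
    for seg in text.split(";"):
        m = _SEGMENT.match(seg.strip())
        if not m:
            raise ValueError(f"bad residue segment {seg!r}")
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        seq = m.group(3)
        if end - start + 1 != len(seq):
            raise ValueError(
                f"segment {seg!r}: span {start}-{end} does not match "
                f"sequence length {len(seq)}"
            )
        out.extend((start + k, seq[k]) for k in range(len(seq)))
    return out


@dataclass(frozen=True)
class ReferenceEpitope:
    epitope_id: int
    centers: tuple[tuple[int, str], ...]
    members: tuple[tuple[int, str], ...]

    @property
    def n_residues(self) -> int:
        return len(self.members)


def _read_data(name: str) -> list[str]:
    text = resources.files("epimap.data").joinpath(name).read_text()
    return [l for l in text.splitlines() if l.strip() and not l.startswith("#")]


def load_hevb8_epitopes() -> list[ReferenceEpitope]:
    """The published conformational epitope map of Hev b 8 (1g5u chain A)."""
    lines = _read_data("hevb8_conformational_epitopes.tsv")
    assert lines[0].startswith("epitope_id")
    out = []
    for line in lines[1:]:
        eid, centers, segments = line.split("\t")
        out.append(
            ReferenceEpitope(
                epitope_id=int(eid),
                centers=tuple(parse_segments(centers)),
                members=tuple(parse_segments(segments)),
            )
        )
    return out


def load_linear_bcell_epitopes() -> list[LinearEpitope]:
    lines = _read_data("linear_bcell_epitopes.tsv")
    assert lines[0].startswith("label")
    return [
        LinearEpitope(label=lab, kind=kind, sequence=seq)
        for lab, kind, seq in (l.split("\t") for l in lines[1:])
    ]


def load_tcell_anchors() -> dict[str, list[str]]:
    """High-frequency HLA-DR anchor labels per species."""
    lines = _read_data("tcell_anchors.tsv")
    species = lines[0].split("\t")
    anchors: dict[str, list[str]] = {sp: [] for sp in species}
    for line in lines[1:]:
        cells = line.split("\t")
        for sp, cell in zip(species, cells):
            if cell.strip():
                anchors[sp].append(cell.strip())
    return anchors
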