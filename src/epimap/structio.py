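"""Structure and alignment I/O.

Canonical in-memory representations for the pipeline: a lightweight
:class:`Structure` (chains of residues of atoms, author numbering preserved)
read from fixed-column PDB files via gemmi, and an :class:`MSA` wrapping an
aligned sequence set with a designated reference record and a column map to
ungapped reference coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
from Bio import AlignIO

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "ResidueRef",
    "MSA",
    "EpitopeTable",
    "EpitopeRow",
    "StructureError",
    "StructureFormatError",
    "EmptyStructureError",
    "AlignmentError",
    "read_structure",
    "write_structure",
    "read_alignment",
    "write_epitope_table",
    "read_epitope_table",
    "chain_sequence",
]

# 3-letter -> 1-letter for the 20 standard residues; anything else maps to X
# for sequence-level work while staying in the structure geometrically.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class StructureError(Exception):
    """Base class for structure I/O problems."""


class StructureFormatError(StructureError):
    """The file is not parseable PDB text."""


class EmptyStructureError(StructureError):
    """No residues survived parsing and filtering."""


class AlignmentError(Exception):
    """Alignment unreadable, ragged, or missing the reference record."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0

    @property
    def pos(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass(frozen=True, order=True)
class ResidueRef:
    """Stable residue identity: chain id, author number, insertion code, name."""

    chain: str
    number: int
    icode: str = ""
    name: str = ""

    @property
    def label(self) -> str:
        """Compact one-letter label like ``S2`` (author numbering)."""
        one = THREE_TO_ONE.get(self.name, "X")
        return f"{one}{self.number}{self.icode}"

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chain}:{self.number}{self.icode}:{self.name}"


@dataclass
class Residue:
    number: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id!r}")

    def first_chain(self) -> Chain:
        if not self.chains:
            raise EmptyStructureError(f"structure {self.id!r} has no chains")
        return self.chains[0]

    def residues(self) -> Iterator[tuple[str, Residue]]:
        for c in self.chains:
            for r in c.residues:
                yield c.id, r

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def validate(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for cid, res in self.residues():
            key = (cid, res.number, res.icode)
            if key in seen:
                raise StructureError(f"duplicate residue identity {key}")
            seen.add(key)
            if not res.atoms:
                raise StructureError(f"residue {key} has no atoms")
            for a in res.atoms:
                if not all(map(math.isfinite, (a.x, a.y, a.z))):
                    raise StructureError(f"non-finite coordinate in {key}")


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # Highest occupancy wins; ties resolved by file order.
    best = atoms[0]
    for a in atoms[1:]:
        if a.occ > best.occ:
            best = a
    return best


def read_structure(
    path: str | Path,
    model_index: int = 0,
    *,
    keep_hetero: bool = False,
    keep_waters: bool = False,
) -> Structure:
    """Read a fixed-column PDB file into a :class:`Structure`.

    Waters and heteroatom (HETATM) residues are excluded by default.
    Alternate locations are resolved to the highest-occupancy conformer
    (ties: first in file). ``model_index`` selects among NMR-style models.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    if not 0 <= model_index < len(st):
        raise IndexError(f"model_index {model_index} out of range (n={len(st)})")
    model = st[model_index]
    st.setup_entities()

    out = Structure(id=st.name or path.stem)
    for ch in model:
        chain = Chain(id=ch.name)
        for res in ch:
            if res.is_water() and not keep_waters:
                continue
            if res.het_flag == "H" and not res.is_water() and not keep_hetero:
                continue
            groups: dict[str, list[gemmi.Atom]] = {}
            order: list[str] = []
            for at in res:
                if at.name not in groups:
                    groups[at.name] = []
                    order.append(at.name)
                groups[at.name].append(at)
            atoms = []
            for name in order:
                at = _pick_altloc(groups[name])
                atoms.append(
                    Atom(
                        name=name,
                        element=at.element.name.upper(),
                        x=at.pos.x,
                        y=at.pos.y,
                        z=at.pos.z,
                        occupancy=at.occ,
                    )
                )
            if atoms:
                chain.residues.append(
                    Residue(
                        number=res.seqid.num,
                        icode=(res.seqid.icode or "").strip(),
                        name=res.name,
                        atoms=atoms,
                    )
                )
        if chain.residues:
            out.chains.append(chain)
    if not out.chains:
        raise EmptyStructureError(f"{path}: empty structure after filtering")
    out.validate()
    return out


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as a single-model PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for chain in structure.chains:
        gch = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            gres.het_flag = "A"
            for a in res.atoms:
                gat = gemmi.Atom()
                gat.name = a.name
                gat.element = gemmi.Element(a.element)
                gat.pos = gemmi.Position(a.x, a.y, a.z)
                gat.occ = a.occupancy
                gres.add_atom(gat)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def chain_sequence(chain: Chain) -> str:
    """One-letter sequence of a chain in file order (non-standard -> X)."""
    return "".join(r.one_letter for r in chain.residues)


# ---------------------------------------------------------------------------
# Alignments


@dataclass
class MSA:
    """An aligned sequence set with a designated reference record.

    ``column_to_ref`` maps 0-based alignment columns to 1-based ungapped
    positions of the reference sequence (columns where the reference is
    gapped are absent from the map).
    """

    records: list[tuple[str, str]]
    reference: str

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("empty alignment")
        length = len(self.records[0][1])
        for rid, seq in self.records:
            if len(seq) != length:
                raise AlignmentError(
                    f"ragged alignment: record {rid!r} has length {len(seq)}, "
                    f"expected {length}"
                )
        if self.reference not in dict(self.records):
            raise AlignmentError(f"reference {self.reference!r} not in alignment")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    def sequence(self, rid: str) -> str:
        return dict(self.records)[rid]

    @property
    def column_to_ref(self) -> dict[int, int]:
        ref = self.sequence(self.reference)
        out: dict[int, int] = {}
        pos = 0
        for col, ch in enumerate(ref):
            if ch != "-":
                pos += 1
                out[col] = pos
        return out

    @property
    def ref_to_column(self) -> dict[int, int]:
        return {p: c for c, p in self.column_to_ref.items()}

    def column(self, col: int) -> list[str]:
        return [seq[col] for _, seq in self.records]


def read_alignment(
    path: str | Path, format: str = "fasta", reference: str | None = None
) -> MSA:
    """Read a FASTA or Clustal alignment into an :class:`MSA`.

    ``reference`` defaults to the first record.
    """
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {format!r}")
    try:
        aln = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise AlignmentError(f"{path}: {exc}") from exc
    records = [(rec.id, str(rec.seq).upper()) for rec in aln]
    ref = reference if reference is not None else records[0][0]
    return MSA(records=records, reference=ref)


# ---------------------------------------------------------------------------
# Epitope tables


@dataclass
class EpitopeRow:
    structure_id: str
    epitope_id: int
    centers: list[ResidueRef]
    members: list[ResidueRef]
    provenance: dict[ResidueRef, str] = field(default_factory=dict)

    @property
    def n_residues(self) -> int:
        return len(self.members)

    def validate(self) -> None:
        if not set(self.centers) <= set(self.members):
            raise ValueError(
                f"epitope {self.epitope_id}: centers not a subset of members"
            )


@dataclass
class EpitopeTable:
    rows: list[EpitopeRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[EpitopeRow]:
        return iter(self.rows)

    def validate(self) -> None:
        for row in self.rows:
            row.validate()


_HEADER = ["structure", "epitope_id", "centers", "members", "n_residues", "provenance"]


def _fmt_ref(r: ResidueRef) -> str:
    return f"{r.chain}:{r.number}{r.icode}:{r.name}"


def _parse_ref(s: str) -> ResidueRef:
    chain, numic, name = s.split(":")
    i = len(numic)
    while i > 0 and not numic[i - 1].isdigit():
        i -= 1
    return ResidueRef(chain=chain, number=int(numic[:i]), icode=numic[i:], name=name)


def write_epitope_table(table: EpitopeTable, path: str | Path) -> None:
    """Serialize an epitope table as TSV (one row per epitope)."""
    table.validate()
    lines = ["\t".join(_HEADER)]
    for row in table:
        members = sorted(row.members, key=lambda r: (r.chain, r.number, r.icode))
        lines.append(
            "\t".join(
                [
                    row.structure_id,
                    str(row.epitope_id),
                    ";".join(_fmt_ref(c) for c in sorted(row.centers)),
                    ";".join(_fmt_ref(m) for m in members),
                    str(row.n_residues),
                    ";".join(row.provenance.get(m, "member") for m in members),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_epitope_table(path: str | Path) -> EpitopeTable:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != _HEADER:
        raise ValueError(f"{path}: not an epitope table")
    rows = []
    for line in lines[1:]:
        sid, eid, centers_s, members_s, n_s, prov_s = line.split("\t")
        centers = [_parse_ref(s) for s in centers_s.split(";") if s]
        members = [_parse_ref(s) for s in members_s.split(";") if s]
        provs = prov_s.split(";") if prov_s else []
        provenance = dict(zip(members, provs))
        row = EpitopeRow(sid, int(eid), centers, members, provenance)
        if row.n_residues != int(n_s):
            raise ValueError(f"{path}: member count mismatch in epitope {eid}")
        rows.append(row)
    return EpitopeTable(rows=rows)
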