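"""Seeded generators of structures and alignments with known ground truth.

The globule generator builds idealized single-chain models — a densely
packed spherical shell of two-atom (Cα + dummy side-chain) residues whose
mutual occlusion keeps them partially accessible, with designated residues
displaced outward so far that they are guaranteed protruding, optional
cysteine pairs placed at exact Cα separations, and an optional fully
buried residue caged at the core.  The geometry is idealized on purpose:
the algorithms under test depend only on distances and exposure, so
constructions with provable accessibility properties beat ad hoc realism.

The alignment generator plants region variants at exact largest-remainder
quota counts so variant-frequency recovery can be checked exactly.

Both generators are deterministic under (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structio import MSA, Atom, Chain, Residue, Structure

__all__ = [
    "GlobuleSpec",
    "GlobuleTruth",
    "MsaSpec",
    "MsaTruth",
    "GenerationError",
    "make_globule",
    "make_msa",
    "write_msa_fasta",
]


class GenerationError(ValueError):
    pass


# Icosahedron vertex directions; any point of a sphere is within 37.4 deg
# of a vertex, which makes a 2 Å cage at these directions occlude a probe-
# expanded carbon sphere completely.
def _icosahedron() -> np.ndarray:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            v += [(0, a, b), (a, b, 0), (b, 0, a)]
    v = np.asarray(v, float)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _spiral_directions(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * i / golden
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass(frozen=True)
class GlobuleSpec:
    """Recipe for a synthetic globule.

    Residue indices are 0-based; residue numbers in the output are 1-based.
    ``protruding`` residues are displaced ``protrusion`` Å beyond the shell;
    ``cys_pairs`` are (i, j, Cα distance Å) with both residues built as CYS;
    ``buried`` (at most one index) is caged at the core by dummy atoms
    carried by its sequence neighbours.
    """

    n_residues: int
    protruding: tuple[int, ...] = ()
    cys_pairs: tuple[tuple[int, int, float], ...] = ()
    buried: int | None = None
    seed: int = 0
    area_per_residue: float = 22.0  # Å^2 of shell surface per residue
    protrusion: float = 7.0  # Å beyond the shell
    min_radius: float = 8.0

    def validate(self) -> None:
        if self.n_residues < 8:
            raise GenerationError("need at least 8 residues")
        special: set[int] = set()

        def claim(idx: int, what: str) -> None:
            if not 0 <= idx < self.n_residues:
                raise GenerationError(f"{what} index {idx} out of range")
            if idx in special:
                raise GenerationError(f"index {idx} claimed twice")
            special.add(idx)

        for idx in self.protruding:
            claim(idx, "protruding")
        for i, j, d in self.cys_pairs:
            claim(i, "cysteine")
            claim(j, "cysteine")
            if d <= 0:
                raise GenerationError("cysteine target distance must be positive")
        if self.buried is not None:
            claim(self.buried, "buried")
            for nb in (self.buried - 1, self.buried + 1):
                if not 0 <= nb < self.n_residues:
                    raise GenerationError("buried residue needs both sequence neighbours")
                if nb in self.protruding or any(
                    nb in (i, j) for i, j, _ in self.cys_pairs
                ):
                    raise GenerationError("buried residue neighbours must be ordinary")


@dataclass
class GlobuleTruth:
    """Machine-readable ground truth accompanying a generated globule."""

    protruding_resnums: list[int]
    buried_resnum: int | None
    cys_distances: dict[tuple[int, int], float]  # 1-based resnum pairs -> Å
    shell_radius: float


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix, sign-fixed; uniform over SO(3).
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_globule(spec: GlobuleSpec) -> tuple[Structure, GlobuleTruth]:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    radius = max(spec.min_radius, np.sqrt(n * spec.area_per_residue / (4.0 * np.pi)))
    dirs = _spiral_directions(n) @ _random_rotation(rng).T

    cys_members = {i for i, j, _ in spec.cys_pairs} | {j for _, j, _ in spec.cys_pairs}
    plug: dict[int, np.ndarray] = {}  # shell slot kept filled under a protrusion
    cage_hosts: dict[int, list[np.ndarray]] = {}
    positions_ca: dict[int, np.ndarray] = {}
    positions_cb: dict[int, np.ndarray | None] = {}
    names: dict[int, str] = {}

    for idx in range(n):
        d = dirs[idx]
        if idx == spec.buried:
            positions_ca[idx] = np.zeros(3)
            positions_cb[idx] = None
            names[idx] = "ALA"
        elif idx in spec.protruding:
            positions_ca[idx] = (radius + spec.protrusion) * d
            positions_cb[idx] = (radius + spec.protrusion - 1.5) * d
            # keep the vacated shell slot occupied so neighbours stay occluded
            plug[idx] = radius * d
            names[idx] = "ALA"
        elif idx in cys_members:
            names[idx] = "CYS"  # placed below, pairwise
            positions_cb[idx] = None
        else:
            positions_ca[idx] = radius * d
            positions_cb[idx] = (radius - 1.5) * d
            names[idx] = "ALA"

    truth_cys: dict[tuple[int, int], float] = {}
    for i, j, target in spec.cys_pairs:
        u = dirs[i]
        # deterministic tangent perpendicular to u
        t = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(t) < 1e-6:
            t = np.cross(u, [0.0, 1.0, 0.0])
        t /= np.linalg.norm(t)
        mid = (radius + spec.protrusion) * u  # keep the pair clear of the shell
        positions_ca[i] = mid - 0.5 * target * t
        positions_ca[j] = mid + 0.5 * target * t
        truth_cys[(i + 1, j + 1)] = float(target)

    if spec.buried is not None:
        cage_dirs = _icosahedron()
        cage = [2.0 * d for d in cage_dirs]
        cage_hosts[spec.buried - 1] = cage[:6]
        cage_hosts[spec.buried + 1] = cage[6:]

    chain = Chain(id="A")
    for idx in range(n):
        atoms = [
            Atom(name="CA", element="C", x=round(positions_ca[idx][0], 3),
                 y=round(positions_ca[idx][1], 3), z=round(positions_ca[idx][2], 3))
        ]
        cb = positions_cb.get(idx)
        if cb is not None:
            atoms.append(
                Atom(name="CB", element="C",
                     x=round(cb[0], 3), y=round(cb[1], 3), z=round(cb[2], 3))
            )
        if idx in plug:
            atoms.append(
                Atom(name="CG", element="C", x=round(plug[idx][0], 3),
                     y=round(plug[idx][1], 3), z=round(plug[idx][2], 3))
            )
        for k, pos in enumerate(cage_hosts.get(idx, [])):
            atoms.append(
                Atom(name=f"D{k + 1}", element="C",
                     x=round(pos[0], 3), y=round(pos[1], 3), z=round(pos[2], 3))
            )
        chain.residues.append(
            Residue(number=idx + 1, icode="", name=names[idx], atoms=atoms)
        )
    st = Structure(id=f"globule-{spec.seed}", chains=[chain])
    st.validate()
    truth = GlobuleTruth(
        protruding_resnums=[i + 1 for i in sorted(spec.protruding)],
        buried_resnum=None if spec.buried is None else spec.buried + 1,
        cys_distances=truth_cys,
        shell_radius=float(radius),
    )
    return st, truth


# ---------------------------------------------------------------------------
# Alignments


@dataclass(frozen=True)
class MsaSpec:
    """Recipe for a synthetic alignment with planted region variants.

    Regions are (id, start, end) in 1-based template coordinates and must
    not overlap.  For each region, ``variants[region_id]`` lists
    (sequence, target frequency %) entries — the first entry must be the
    template's own substring; all variants must keep the region length and
    frequencies must sum to 100.
    """

    template: str
    n_sequences: int
    regions: tuple[tuple[str, int, int], ...] = ()
    variants: dict[str, tuple[tuple[str, float], ...]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_sequences < 1:
            raise GenerationError("need at least one sequence")
        spans = sorted((start, end, rid) for rid, start, end in self.regions)
        prev_end = 0
        for start, end, rid in spans:
            if start < 1 or end > len(self.template) or start > end:
                raise GenerationError(f"region {rid}: bad span {start}-{end}")
            if start <= prev_end:
                raise GenerationError(f"region {rid} overlaps a previous region")
            prev_end = end
        for rid, start, end in self.regions:
            entries = self.variants.get(rid)
            if not entries:
                raise GenerationError(f"region {rid}: no variants given")
            expected = self.template[start - 1 : end]
            if entries[0][0] != expected:
                raise GenerationError(
                    f"region {rid}: first variant must equal the template "
                    f"substring {expected!r}"
                )
            for seq, freq in entries:
                if len(seq) != end - start + 1:
                    raise GenerationError(
                        f"region {rid}: variant {seq!r} changes region length"
                    )
                if freq < 0:
                    raise GenerationError("negative frequency")
            total = sum(f for _, f in entries)
            if abs(total - 100.0) > 1e-6:
                raise GenerationError(f"region {rid}: frequencies sum to {total}")


@dataclass
class MsaTruth:
    template_id: str
    counts: dict[str, dict[str, int]]  # region id -> variant sequence -> count


def _largest_remainder(freqs: list[float], n: int) -> list[int]:
    quotas = [f * n / 100.0 for f in freqs]
    counts = [int(np.floor(q)) for q in quotas]
    short = n - sum(counts)
    remainders = sorted(
        range(len(freqs)), key=lambda k: (-(quotas[k] - counts[k]), k)
    )
    for k in remainders[:short]:
        counts[k] += 1
    return counts


def make_msa(spec: MsaSpec) -> tuple[MSA, MsaTruth]:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sequences
    ids = [f"seq{k + 1:04d}" for k in range(n)]
    seqs = [list(spec.template) for _ in range(n)]
    counts_truth: dict[str, dict[str, int]] = {}
    for rid, start, end in spec.regions:
        entries = list(spec.variants[rid])
        counts = _largest_remainder([f for _, f in entries], n)
        if counts[0] == 0:
            raise GenerationError(
                f"region {rid}: template variant quota is zero at n={n}"
            )
        assignment = []
        for (var, _), c in zip(entries, counts):
            assignment += [var] * c
        assignment = list(rng.permutation(assignment))
        # keep sequence 1 as a faithful template representative
        if assignment[0] != entries[0][0]:
            k = assignment.index(entries[0][0])
            assignment[0], assignment[k] = assignment[k], assignment[0]
        for seq, var in zip(seqs, assignment):
            seq[start - 1 : end] = list(var)
        counts_truth[rid] = {var: c for (var, _), c in zip(entries, counts) if c > 0}
    records = [(rid, "".join(s)) for rid, s in zip(ids, seqs)]
    msa = MSA(records=records, reference=ids[0])
    return msa, MsaTruth(template_id=ids[0], counts=counts_truth)


def write_msa_fasta(msa: MSA, path: str | Path) -> None:
    lines = []
    for rid, seq in msa.records:
        lines.append(f">{rid}")
        lines.append(seq)
    Path(path).write_text("\n".join(lines) + "\n")
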