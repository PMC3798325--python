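"""Structure comparison: Kabsch superposition, cysteine screens, charges.

Rigid-body least-squares superposition of mapped Cα coordinates (proper
rotation enforced), alignment-mapped pairwise RMSD between chains of
different structures, a Cα–Cα distance screen for disulfide-feasible
cysteine pairs, and formal-charge summaries of protein sequences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.SVDSuperimposer import SVDSuperimposer

from .structio import Chain, ResidueRef, Structure, chain_sequence

__all__ = [
    "SuperpositionResult",
    "CysPair",
    "CysPairTable",
    "ChargeSummary",
    "kabsch_superpose",
    "map_chains_by_alignment",
    "pairwise_structure_rmsd",
    "cys_pair_distances",
    "sequence_charge",
    "GeometryError",
]


class GeometryError(Exception):
    pass


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # length-3, Å
    rmsd: float  # Å
    n_pairs: int
    mapping: list[tuple[int, int]] = field(default_factory=list)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted transform (mobile -> reference frame)."""
        return coords @ self.rotation + self.translation


def kabsch_superpose(
    coords_ref: np.ndarray,
    coords_mobile: np.ndarray,
    mapping: list[tuple[int, int]] | None = None,
) -> SuperpositionResult:
    """Least-squares optimal superposition of mapped coordinate pairs.

    ``mapping`` pairs (ref index, mobile index); by default positions are
    paired one-to-one.  At least 3 non-collinear pairs are required.
    """
    a = np.asarray(coords_ref, float)
    b = np.asarray(coords_mobile, float)
    if mapping is None:
        if len(a) != len(b):
            raise ValueError("unequal coordinate counts and no mapping given")
        mapping = [(i, i) for i in range(len(a))]
    if len(mapping) < 3:
        raise GeometryError("need at least 3 mapped pairs")
    x = a[[i for i, _ in mapping]]
    y = b[[j for _, j in mapping]]
    # Collinearity check: rank of the centred reference set.
    if np.linalg.matrix_rank(x - x.mean(0), tol=1e-8) < 2:
        raise GeometryError("mapped reference coordinates are collinear")
    sup = SVDSuperimposer()
    sup.set(x, y)
    sup.run()
    rot, tran = sup.get_rotran()
    return SuperpositionResult(
        rotation=rot,
        translation=tran,
        rmsd=float(sup.get_rms()),
        n_pairs=len(mapping),
        mapping=list(mapping),
    )


def _ca_coords(chain: Chain) -> tuple[np.ndarray, list[int]]:
    coords, idx = [], []
    for i, res in enumerate(chain.residues):
        ca = res.atom("CA")
        if ca is not None:
            coords.append(ca.pos)
            idx.append(i)
    return np.asarray(coords, float), idx


def map_chains_by_alignment(
    chain_a: Chain,
    chain_b: Chain,
    *,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
) -> list[tuple[int, int]]:
    """Residue-index pairs from a global alignment of two chain sequences."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(chain_sequence(chain_a), chain_sequence(chain_b))[0]
    pairs = []
    for (a_lo, a_hi), (b_lo, b_hi) in zip(*aln.aligned):
        pairs.extend(zip(range(a_lo, a_hi), range(b_lo, b_hi)))
    return pairs


def superpose_chains(
    chain_a: Chain,
    chain_b: Chain,
    *,
    trim_outliers: bool = False,
    max_cycles: int = 5,
    sigma_cut: float = 2.0,
) -> SuperpositionResult:
    """Alignment-mapped Cα superposition of two chains.

    With ``trim_outliers`` the fit is refined by repeatedly discarding
    pairs with residual distance above ``sigma_cut`` standard deviations
    of the pair distances, mimicking the refinement cycles of interactive
    structure-alignment tools.
    """
    ca_a, idx_a = _ca_coords(chain_a)
    ca_b, idx_b = _ca_coords(chain_b)
    pos_a = {r: k for k, r in enumerate(idx_a)}
    pos_b = {r: k for k, r in enumerate(idx_b)}
    pairs = [
        (pos_a[i], pos_b[j])
        for i, j in map_chains_by_alignment(chain_a, chain_b)
        if i in pos_a and j in pos_b
    ]
    result = kabsch_superpose(ca_a, ca_b, pairs)
    if not trim_outliers:
        return result
    for _ in range(max_cycles):
        moved = result.transform(ca_b)
        dists = np.array(
            [np.linalg.norm(ca_a[i] - moved[j]) for i, j in result.mapping]
        )
        cut = dists.mean() + sigma_cut * dists.std()
        kept = [p for p, d in zip(result.mapping, dists) if d <= cut]
        if len(kept) == len(result.mapping) or len(kept) < 3:
            break
        result = kabsch_superpose(ca_a, ca_b, kept)
    return result


def pairwise_structure_rmsd(
    structures: list[Structure],
    chain_ids: list[str] | None = None,
    *,
    trim_outliers: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric matrix of alignment-mapped Cα RMSDs (Å) and pair counts.

    Unmappable pairs (alignment yields <3 Cα pairs) are flagged with NaN
    rather than raising.
    """
    if len(structures) < 2:
        raise ValueError("need at least 2 structures")
    chains = []
    for k, st in enumerate(structures):
        cid = chain_ids[k] if chain_ids else None
        chains.append(st.chain(cid) if cid else st.first_chain())
    n = len(chains)
    rmsd = np.zeros((n, n))
    counts = np.zeros((n, n), int)
    for i in range(n):
        counts[i, i] = len(_ca_coords(chains[i])[0])
        for j in range(i + 1, n):
            try:
                res = superpose_chains(chains[i], chains[j], trim_outliers=trim_outliers)
                rmsd[i, j] = rmsd[j, i] = res.rmsd
                counts[i, j] = counts[j, i] = res.n_pairs
            except GeometryError:
                rmsd[i, j] = rmsd[j, i] = np.nan
    return rmsd, counts


@dataclass(frozen=True)
class CysPair:
    a: ResidueRef
    b: ResidueRef
    distance: float  # Cα–Cα, Å
    feasible: bool


@dataclass
class CysPairTable:
    window: tuple[float, float]
    pairs: list[CysPair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def feasible_pairs(self) -> list[CysPair]:
        return [p for p in self.pairs if p.feasible]


def cys_pair_distances(
    structure: Structure, window: tuple[float, float] = (3.0, 7.5)
) -> CysPairTable:
    """All cysteine Cα–Cα distances with a disulfide-feasibility flag.

    The default 3.0–7.5 Å window brackets the Cα–Cα separations seen in
    canonical cystine bridges (~4.5–6.5 Å) with margin for strained ones.
    """
    lo, hi = window
    cys = []
    for cid, res in structure.residues():
        if res.name == "CYS":
            ca = res.atom("CA")
            if ca is None:
                raise GeometryError(
                    f"cysteine {cid}:{res.number}{res.icode} has no CA atom"
                )
            cys.append((ResidueRef(cid, res.number, res.icode, res.name), np.asarray(ca.pos)))
    pairs = []
    for (ra, pa), (rb, pb) in itertools.combinations(cys, 2):
        d = float(np.linalg.norm(pa - pb))
        pairs.append(CysPair(a=ra, b=rb, distance=d, feasible=lo <= d <= hi))
    return CysPairTable(window=window, pairs=pairs)


NEGATIVE = set("DE")
POSITIVE = set("KR")


@dataclass(frozen=True)
class ChargeSummary:
    sequence_id: str
    length: int
    n_negative: int
    n_positive: int
    unknown: int  # residues outside the 20-letter alphabet (counted in length)

    @property
    def pct_negative(self) -> float:
        return 100.0 * self.n_negative / self.length

    @property
    def pct_positive(self) -> float:
        return 100.0 * self.n_positive / self.length

    @property
    def net_charge(self) -> int:
        return self.n_positive - self.n_negative


def sequence_charge(
    sequence: str, sequence_id: str = "", *, include_histidine: bool = False
) -> ChargeSummary:
    """Formal-charge bookkeeping: Asp/Glu −1, Lys/Arg +1 (His optional).

    Termini and protonation equilibria are ignored; the net charge is the
    count difference.  Unknown letters count toward length only.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    positive = POSITIVE | ({"H"} if include_histidine else set())
    standard = set("ACDEFGHIKLMNPQRSTVWY")
    return ChargeSummary(
        sequence_id=sequence_id,
        length=len(seq),
        n_negative=sum(1 for c in seq if c in NEGATIVE),
        n_positive=sum(1 for c in seq if c in positive),
        unknown=sum(1 for c in seq if c not in standard),
    )
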