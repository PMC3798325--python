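"""Conformational (discontinuous) B-cell epitope prediction.

A three-rule structure-based algorithm operating on a chain with computed
Gly-X-Gly-relative solvent accessibilities:

1. Residues with relative SASA strictly above the center threshold (75%)
   are *protruding* and seed epitopes; protruding residues closer to each
   other than the merge radius (0.5 nm) are combined into one epitope
   (single-linkage, so chains of close centers merge transitively).
2. Every partially accessible residue (relative SASA > 20%) within the
   expansion radius (1 nm — the typical footprint of an antigen-antibody
   contact) of *any* center residue of the group joins the epitope.
3. A single residue flanked in sequence by two epitope members is pulled
   in, since it will constrain the conformation of its neighbours.  Gaps
   of two or more residues are left alone, and the rule is applied once.

Distances are Cα–Cα by default (minimum heavy-atom distance available as
an option).  Epitopes are numbered in ascending order of their smallest
center residue number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sasa import ResidueExposure
from .structio import Chain, EpitopeRow, EpitopeTable, ResidueRef, Structure

__all__ = [
    "EpitopeParams",
    "GeometryError",
    "select_centers",
    "merge_centers",
    "expand_members",
    "fill_single_gaps",
    "predict_epitopes",
    "parameter_sweep",
]


class GeometryError(Exception):
    """A residue lacks the atom required by the configured distance basis."""


@dataclass(frozen=True)
class EpitopeParams:
    """Thresholds and radii of the three-rule algorithm.

    All SASA comparisons are strict (>), distance comparisons are strict (<),
    matching the published wording of the rules.
    """

    center_threshold: float = 75.0  # % relative SASA seeding an epitope
    member_threshold: float = 20.0  # % relative SASA for rule-2 expansion
    merge_radius: float = 5.0  # Å, 0.5 nm center-combination cutoff
    expansion_radius: float = 10.0  # Å, 1 nm antigen-antibody footprint
    distance_basis: str = "calpha"  # or "min_heavy_atom"

    def __post_init__(self) -> None:
        if self.member_threshold >= self.center_threshold:
            raise ValueError("member threshold must be below center threshold")
        if self.merge_radius <= 0 or self.expansion_radius <= 0:
            raise ValueError("radii must be positive")
        if self.distance_basis not in ("calpha", "min_heavy_atom"):
            raise ValueError(f"unknown distance basis {self.distance_basis!r}")


def _residue_coords(chain: Chain, basis: str) -> dict[int, np.ndarray]:
    """Representative coordinates per residue index along the chain."""
    coords: dict[int, np.ndarray] = {}
    for i, res in enumerate(chain.residues):
        if basis == "calpha":
            ca = res.atom("CA")
            if ca is None:
                raise GeometryError(
                    f"residue {chain.id}:{res.number}{res.icode}:{res.name} has no CA"
                )
            coords[i] = np.asarray([ca.pos], float)
        else:
            heavy = [a.pos for a in res.atoms if a.element != "H"]
            if not heavy:
                raise GeometryError(
                    f"residue {chain.id}:{res.number}{res.icode}:{res.name} "
                    "has no heavy atoms"
                )
            coords[i] = np.asarray(heavy, float)
    return coords


def _pair_distance(a: np.ndarray, b: np.ndarray) -> float:
    d = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((d * d).sum(-1)).min())


def select_centers(
    exposures: list[ResidueExposure], params: EpitopeParams | None = None
) -> set[ResidueRef]:
    """Rule 1a: residues strictly above the center threshold."""
    params = params or EpitopeParams()
    return {e.ref for e in exposures if e.relative > params.center_threshold}


def merge_centers(
    centers: set[ResidueRef],
    chain: Chain,
    params: EpitopeParams | None = None,
) -> list[list[ResidueRef]]:
    """Rule 1b: single-linkage groups of centers closer than the merge radius.

    Groups are returned ordered by their smallest residue number.
    """
    params = params or EpitopeParams()
    idx_of = {
        ResidueRef(chain.id, r.number, r.icode, r.name): i
        for i, r in enumerate(chain.residues)
    }
    missing = [c for c in centers if c not in idx_of]
    if missing:
        raise GeometryError(f"center residues not on chain {chain.id}: {missing}")
    coords = _residue_coords(chain, params.distance_basis)
    members = sorted(centers, key=lambda r: (r.number, r.icode))
    # Union-find over center pairs within the merge radius.
    parent = {c: c for c in members}

    def find(x: ResidueRef) -> ResidueRef:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            if _pair_distance(coords[idx_of[a]], coords[idx_of[b]]) < params.merge_radius:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    groups: dict[ResidueRef, list[ResidueRef]] = {}
    for c in members:
        groups.setdefault(find(c), []).append(c)
    return sorted(groups.values(), key=lambda g: min((r.number, r.icode) for r in g))


def expand_members(
    group: list[ResidueRef],
    exposures: list[ResidueExposure],
    chain: Chain,
    params: EpitopeParams | None = None,
) -> set[ResidueRef]:
    """Rule 2: add accessible residues within the expansion radius of any center."""
    params = params or EpitopeParams()
    if not group:
        raise ValueError("empty center group")
    coords = _residue_coords(chain, params.distance_basis)
    idx_of = {
        ResidueRef(chain.id, r.number, r.icode, r.name): i
        for i, r in enumerate(chain.residues)
    }
    exposure_of = {e.ref: e for e in exposures}
    members = set(group)
    group_coords = [coords[idx_of[c]] for c in group]
    for ref, idx in idx_of.items():
        if ref in members:
            continue
        e = exposure_of.get(ref)
        if e is None or not e.relative > params.member_threshold:
            continue
        if any(
            _pair_distance(coords[idx], gc) < params.expansion_radius
            for gc in group_coords
        ):
            members.add(ref)
    return members


def fill_single_gaps(members: set[ResidueRef], chain: Chain) -> set[ResidueRef]:
    """Rule 3: include any lone residue whose both sequence neighbours are members.

    Neighbourhood is positional along the chain (file order); applied once.
    """
    refs = [ResidueRef(chain.id, r.number, r.icode, r.name) for r in chain.residues]
    out = set(members)
    for i in range(1, len(refs) - 1):
        if refs[i] not in members and refs[i - 1] in members and refs[i + 1] in members:
            out.add(refs[i])
    return out


def predict_epitopes(
    structure: Structure,
    exposures: list[ResidueExposure],
    params: EpitopeParams | None = None,
    chain_id: str | None = None,
) -> EpitopeTable:
    """Run the full three-rule pipeline on one chain.

    ``exposures`` must cover the chain's residues (as from
    :func:`epimap.sasa.compute_exposures` restricted to the chain).
    """
    params = params or EpitopeParams()
    chain = structure.chain(chain_id) if chain_id else structure.first_chain()
    chain_exposures = [e for e in exposures if e.ref.chain == chain.id]
    centers = select_centers(chain_exposures, params)
    groups = merge_centers(centers, chain, params)
    rows = []
    for eid, group in enumerate(groups, start=1):
        expanded = expand_members(group, chain_exposures, chain, params)
        filled = fill_single_gaps(expanded, chain)
        provenance = {}
        for m in filled:
            if m in group:
                provenance[m] = "center"
            elif m in expanded:
                provenance[m] = "proximity"
            else:
                provenance[m] = "gap_fill"
        rows.append(
            EpitopeRow(
                structure_id=structure.id,
                epitope_id=eid,
                centers=sorted(group),
                members=sorted(filled),
                provenance=provenance,
            )
        )
    table = EpitopeTable(rows=rows)
    table.validate()
    return table


def parameter_sweep(
    structure: Structure,
    exposures_by_config: dict[str, list[ResidueExposure]],
    params_grid: list[EpitopeParams],
    chain_id: str | None = None,
) -> list[dict]:
    """Sensitivity report: epitope count and size range per configuration.

    ``exposures_by_config`` maps a label (e.g. a GXG-table name) to the
    exposures computed under that configuration; each is crossed with every
    parameter set in ``params_grid``.
    """
    report = []
    for label, exposures in exposures_by_config.items():
        for params in params_grid:
            table = predict_epitopes(structure, exposures, params, chain_id)
            sizes = [row.n_residues for row in table]
            report.append(
                {
                    "exposure_config": label,
                    "distance_basis": params.distance_basis,
                    "center_threshold": params.center_threshold,
                    "member_threshold": params.member_threshold,
                    "merge_radius": params.merge_radius,
                    "expansion_radius": params.expansion_radius,
                    "n_epitopes": len(table),
                    "min_size": min(sizes) if sizes else 0,
                    "max_size": max(sizes) if sizes else 0,
                }
            )
    return report
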