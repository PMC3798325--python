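"""Solvent accessible surface area (Shrake–Rupley) and exposure classes.

Per-atom SASA is computed by the Shrake–Rupley rolling-probe point-count:
each atom's solvent-expanded sphere (van der Waals radius + probe radius)
is sampled with a deterministic golden-spiral point set, and the accessible
fraction is the fraction of points not inside any neighbouring expanded
sphere.  Per-residue SASA sums atom areas; relative SASA normalises by the
residue type's standard-state (Gly-X-Gly tripeptide) area, so values above
100% can occur at chain termini and are not clamped.

Exposure classes follow the conventions of conformational-epitope work on
allergens: buried < 20%, partially accessible >= 20%, surface >= 25%,
protruding > 75% of the Gly-X-Gly reference (cumulative flags).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .structio import Residue, ResidueRef, Structure

__all__ = [
    "SasaConfig",
    "ResidueExposure",
    "sphere_points",
    "atom_sasa",
    "residue_sasa",
    "relative_sasa",
    "compute_exposures",
    "UnknownElementError",
    "MissingReferenceError",
]


class UnknownElementError(KeyError):
    """An atom's element has no entry in the radii table."""


class MissingReferenceError(KeyError):
    """A residue type has no Gly-X-Gly reference area and no fallback."""


def _load_table(name: str) -> dict[str, float]:
    text = resources.files("epimap.data").joinpath(name).read_text()
    out: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith(("residue\t", "element\t")):
            continue
        key, val = line.split("\t")
        out[key] = float(val)
    return out


def default_radii() -> dict[str, float]:
    return _load_table("atomic_radii.tsv")


def default_gxg() -> dict[str, float]:
    return _load_table("gxg_reference.tsv")


@dataclass
class SasaConfig:
    """Parameters of the SASA computation.

    probe_radius: solvent probe, Å (water = 1.4).
    n_points: sphere sample points per atom; more points, smoother areas.
    radii: element -> van der Waals radius (Å).
    gxg_reference: residue 3-letter name -> standard-state area (Å^2).
    thresholds: (buried/partial cut, surface cut, protruding cut) in %.
    """

    probe_radius: float = 1.4
    n_points: int = 960
    radii: dict[str, float] = field(default_factory=default_radii)
    gxg_reference: dict[str, float] = field(default_factory=default_gxg)
    partial_threshold: float = 20.0
    surface_threshold: float = 25.0
    protruding_threshold: float = 75.0

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe radius must be positive")
        if self.n_points < 24:
            raise ValueError("need at least 24 sample points per atom")

    def with_points(self, n: int) -> "SasaConfig":
        return replace(self, n_points=n)


@dataclass(frozen=True)
class ResidueExposure:
    ref: ResidueRef
    absolute: float  # Å^2
    reference: float  # Å^2, Gly-X-Gly standard state
    relative: float  # % of reference; may exceed 100 at termini
    partial_threshold: float = 20.0
    surface_threshold: float = 25.0
    protruding_threshold: float = 75.0

    @property
    def buried(self) -> bool:
        return self.relative < self.partial_threshold

    @property
    def partially_accessible(self) -> bool:
        return self.relative >= self.partial_threshold

    @property
    def surface(self) -> bool:
        return self.relative >= self.surface_threshold

    @property
    def protruding(self) -> bool:
        return self.relative > self.protruding_threshold

    @property
    def exposure_class(self) -> str:
        if self.protruding:
            return "protruding"
        if self.surface:
            return "surface"
        if self.partially_accessible:
            return "partially_accessible"
        return "buried"


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit sphere point set, shape (n, 3)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * i / phi
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _gather_atoms(
    structure: Structure, config: SasaConfig
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, Residue]]]:
    coords, radii, owners = [], [], []
    for cid, res in structure.residues():
        for a in res.atoms:
            if a.element not in config.radii:
                raise UnknownElementError(
                    f"no radius for element {a.element!r} "
                    f"(atom {a.name} in {cid}:{res.number}{res.icode}:{res.name})"
                )
            coords.append(a.pos)
            radii.append(config.radii[a.element])
            owners.append((cid, res))
    return np.asarray(coords, float), np.asarray(radii, float), owners


def atom_sasa(structure: Structure, config: SasaConfig | None = None) -> np.ndarray:
    """Per-atom Shrake–Rupley areas (Å^2), in structure atom order."""
    config = config or SasaConfig()
    coords, radii, _ = _gather_atoms(structure, config)
    if coords.size == 0:
        raise ValueError("empty structure")
    pts = sphere_points(config.n_points)
    expanded = radii + config.probe_radius
    n = len(coords)
    areas = np.empty(n)
    # Neighbour prelimit: atoms farther than r_i + max(r_j) can't occlude.
    max_exp = expanded.max()
    for i in range(n):
        d = np.linalg.norm(coords - coords[i], axis=1)
        neigh = np.nonzero((d < expanded[i] + max_exp) & (np.arange(n) != i))[0]
        neigh = neigh[d[neigh] < expanded[i] + expanded[neigh]]
        sphere = coords[i] + expanded[i] * pts  # (n_points, 3)
        if len(neigh):
            diff = sphere[:, None, :] - coords[neigh][None, :, :]
            inside = (diff * diff).sum(-1) < (expanded[neigh] ** 2)[None, :]
            accessible = ~inside.any(axis=1)
        else:
            accessible = np.ones(len(sphere), bool)
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible.mean()
    return areas


def residue_sasa(
    structure: Structure, atom_areas: np.ndarray, config: SasaConfig | None = None
) -> list[tuple[ResidueRef, float]]:
    """Sum per-atom areas into per-residue absolute SASA."""
    config = config or SasaConfig()
    _, _, owners = _gather_atoms(structure, config)
    if len(atom_areas) != len(owners):
        raise ValueError("atom areas do not match structure atom count")
    totals: dict[tuple[str, int, str], float] = {}
    refs: dict[tuple[str, int, str], ResidueRef] = {}
    order: list[tuple[str, int, str]] = []
    for (cid, res), area in zip(owners, atom_areas):
        key = (cid, res.number, res.icode)
        if key not in totals:
            totals[key] = 0.0
            refs[key] = ResidueRef(cid, res.number, res.icode, res.name)
            order.append(key)
        totals[key] += float(area)
    return [(refs[k], totals[k]) for k in order]


def relative_sasa(
    absolute: list[tuple[ResidueRef, float]],
    config: SasaConfig | None = None,
    *,
    unknown_fallback: float | None = None,
) -> list[ResidueExposure]:
    """Convert absolute areas to Gly-X-Gly-relative percentages.

    ``unknown_fallback`` supplies a reference area for residue types missing
    from the table (e.g. non-standard residues); without it they raise.
    """
    config = config or SasaConfig()
    out = []
    for ref, area in absolute:
        reference = config.gxg_reference.get(ref.name, unknown_fallback)
        if reference is None:
            raise MissingReferenceError(
                f"no Gly-X-Gly reference area for residue type {ref.name!r}"
            )
        out.append(
            ResidueExposure(
                ref=ref,
                absolute=area,
                reference=reference,
                relative=100.0 * area / reference,
                partial_threshold=config.partial_threshold,
                surface_threshold=config.surface_threshold,
                protruding_threshold=config.protruding_threshold,
            )
        )
    return out


def compute_exposures(
    structure: Structure,
    config: SasaConfig | None = None,
    *,
    unknown_fallback: float | None = None,
) -> list[ResidueExposure]:
    """Full per-residue exposure pipeline: atoms -> residues -> relative %."""
    config = config or SasaConfig()
    areas = atom_sasa(structure, config)
    absolute = residue_sasa(structure, areas, config)
    return relative_sasa(absolute, config, unknown_fallback=unknown_fallback)


def write_exposure_table(exposures: list[ResidueExposure], path: str | Path) -> None:
    lines = ["chain\tresnum\tresname\tabs_sasa\trel_sasa\tclass"]
    for e in exposures:
        lines.append(
            f"{e.ref.chain}\t{e.ref.number}{e.ref.icode}\t{e.ref.name}\t"
            f"{e.absolute:.3f}\t{e.relative:.2f}\t{e.exposure_class}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
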