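"""Sliding-window physicochemical profiles and antigenic-region calling.

Three published per-residue scales are shipped as data files: Kyte-Doolittle
hydropathy, Welling antigenicity and Parker hydrophilicity.  A profile is
the mean scale value over a centred odd window (truncated and flagged at
the termini).  High-antigenicity regions are maximal runs of positions
where enough scales point in the antigenic direction (hydropathy counts as
positive when hydrophilic, i.e. below zero), optionally gated by mean
relative solvent accessibility over the span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .sasa import ResidueExposure

__all__ = [
    "AntigenicityProfile",
    "AntigenicRegion",
    "RegionParams",
    "available_scales",
    "load_scale",
    "scale_profile",
    "call_regions",
]

_SCALE_FILES = {
    "kyte_doolittle": "scale_kyte_doolittle.tsv",
    "kd": "scale_kyte_doolittle.tsv",
    "welling": "scale_welling.tsv",
    "parker": "scale_parker.tsv",
}

# Scales where *lower* values mean more antigenic/hydrophilic: the sign is
# flipped when testing for "positive peaks".
_INVERTED = {"kyte_doolittle", "kd"}


def available_scales() -> list[str]:
    return ["kyte_doolittle", "welling", "parker"]


def load_scale(name: str) -> dict[str, float]:
    key = name.lower()
    if key not in _SCALE_FILES:
        raise KeyError(f"unknown scale {name!r}; choose from {available_scales()}")
    text = resources.files("epimap.data").joinpath(_SCALE_FILES[key]).read_text()
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("residue\t"):
            continue
        aa, val = line.split("\t")
        out[aa] = float(val)
    return out


@dataclass
class AntigenicityProfile:
    sequence_id: str
    scale: str
    window: int
    values: np.ndarray  # one value per sequence position
    flagged: np.ndarray  # bool; truncated-window edges and X-containing windows

    def __len__(self) -> int:
        return len(self.values)

    @property
    def antigenic_positive(self) -> np.ndarray:
        """Boolean mask where the profile points in the antigenic direction."""
        if self.scale in _INVERTED:
            return self.values < 0.0
        return self.values > 0.0


def scale_profile(
    sequence: str,
    scale: str,
    window: int = 7,
    sequence_id: str = "",
) -> AntigenicityProfile:
    """Windowed-mean profile of ``sequence`` under the named scale.

    The window is centred; positions within half a window of either
    terminus average over the truncated window and are flagged.  Unknown
    residues (X) are excluded from the window mean, and windows containing
    them are flagged.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if window > len(sequence):
        raise ValueError("window exceeds sequence length")
    table = load_scale(scale)
    seq = sequence.upper()
    bad = set(seq) - set(table) - {"X"}
    if bad:
        raise ValueError(f"sequence contains non-standard residues {sorted(bad)}")
    half = window // 2
    n = len(seq)
    values = np.empty(n)
    flagged = np.zeros(n, bool)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        chunk = seq[lo:hi]
        known = [table[c] for c in chunk if c != "X"]
        values[i] = float(np.mean(known)) if known else np.nan
        if hi - lo < window or "X" in chunk:
            flagged[i] = True
    return AntigenicityProfile(
        sequence_id=sequence_id, scale=scale.lower(), window=window,
        values=values, flagged=flagged,
    )


@dataclass(frozen=True)
class AntigenicRegion:
    region_id: str
    start: int  # 1-based inclusive
    end: int
    supporting_scales: tuple[str, ...]
    mean_relative_sasa: float | None = None


@dataclass
class RegionParams:
    min_run_length: int = 5
    min_supporting_scales: int = 2
    sasa_threshold: float = 25.0  # % relative SASA gate on the span mean


def call_regions(
    profiles: list[AntigenicityProfile],
    exposures: list[ResidueExposure] | None = None,
    params: RegionParams | None = None,
) -> list[AntigenicRegion]:
    """Call maximal high-antigenicity runs supported by enough scales.

    A position is *positive* when at least ``min_supporting_scales``
    profiles point in the antigenic direction there.  Maximal runs of at
    least ``min_run_length`` positives become regions, labelled A1, A2, ...
    left to right.  With ``exposures`` given (position i -> i-th exposure),
    a region is kept only if its mean relative SASA exceeds the threshold.
    """
    params = params or RegionParams()
    if not profiles:
        raise ValueError("no profiles given")
    n = len(profiles[0])
    if any(len(p) != n for p in profiles):
        raise ValueError("profiles have differing lengths")
    if exposures is not None and len(exposures) != n:
        raise ValueError(
            f"exposures ({len(exposures)}) do not match profile length ({n})"
        )
    support = np.zeros(n, int)
    masks = {p.scale: p.antigenic_positive for p in profiles}
    for mask in masks.values():
        support += mask.astype(int)
    positive = support >= params.min_supporting_scales

    regions = []
    label = 1
    i = 0
    while i < n:
        if positive[i]:
            j = i
            while j + 1 < n and positive[j + 1]:
                j += 1
            if j - i + 1 >= params.min_run_length:
                supporting = tuple(
                    name for name, mask in masks.items() if mask[i : j + 1].all()
                )
                mean_sasa = None
                keep = True
                if exposures is not None:
                    mean_sasa = float(
                        np.mean([e.relative for e in exposures[i : j + 1]])
                    )
                    keep = mean_sasa > params.sasa_threshold
                if keep:
                    regions.append(
                        AntigenicRegion(
                            region_id=f"A{label}",
                            start=i + 1,
                            end=j + 1,
                            supporting_scales=supporting,
                            mean_relative_sasa=mean_sasa,
                        )
                    )
                    label += 1
            i = j + 1
        else:
            i += 1
    return regions
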