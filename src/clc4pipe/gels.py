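"""Synthetic gel lane intensity profiles.

A lane is a 1-D intensity profile on a migration axis (mm from the well).
Migration is linear in log molecular weight:

    position(MW) = migration_a - migration_b * log10(MW_kDa)

so heavier species run shorter distances. Bands are unit-normalized Gaussians
scaled by their true area, on top of a constant baseline, plus optional noise.
The per-band ground truth and the MW map are stored on the profile so the
densitometry pipeline can be validated by round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["GelBand", "GelLaneSpec", "LaneProfile", "synth_gel_lane"]


@dataclass(frozen=True)
class GelBand:
    """One designed band: label, apparent MW (kDa), true area, width (mm)."""

    label: str
    mw_kda: float
    area: float
    width: float = 1.0

    def __post_init__(self) -> None:
        if self.mw_kda <= 0:
            raise ValueError("mw_kda must be positive")
        if self.area < 0:
            raise ValueError("band area must be non-negative")
        if self.width <= 0:
            raise ValueError("band width must be positive")


@dataclass(frozen=True)
class GelLaneSpec:
    """Design of one synthetic lane."""

    bands: tuple
    migration_a: float = 140.0   # mm
    migration_b: float = 55.0    # mm per decade of MW
    baseline: float = 20.0       # a.u.
    noise_sd: float = 0.0        # a.u.
    length_mm: float = 60.0
    dx_mm: float = 0.05

    def __post_init__(self) -> None:
        bands = tuple(b if isinstance(b, GelBand) else GelBand(*b)
                      for b in self.bands)
        object.__setattr__(self, "bands", bands)
        labels = [b.label for b in bands]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate band labels in {labels}")
        if self.migration_b <= 0:
            raise ValueError("migration_b must be positive (heavier species "
                             "migrate less)")
        if self.noise_sd < 0 or self.baseline < 0:
            raise ValueError("baseline and noise_sd must be non-negative")


@dataclass
class LaneProfile:
    """A 1-D gel lane: intensity against migration position.

    ``mw_map = (migration_a, migration_b)`` calibrates position against
    log10(MW). ``bands_truth`` carries the designed bands for synthetic lanes
    (None for imported data).
    """

    position: np.ndarray   # mm, strictly increasing
    intensity: np.ndarray  # a.u.
    mw_map: tuple[float, float]
    bands_truth: Optional[tuple] = None
    baseline_truth: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.position.shape != self.intensity.shape or self.position.ndim != 1:
            raise ValueError("position and intensity must be 1-D and aligned")
        if not np.all(np.diff(self.position) > 0):
            raise ValueError("positions must be strictly increasing")

    def mw_to_pos(self, mw_kda):
        a, b = self.mw_map
        return a - b * np.log10(np.asarray(mw_kda, float))

    def pos_to_mw(self, pos):
        a, b = self.mw_map
        return 10.0 ** ((a - np.asarray(pos, float)) / b)


def synth_gel_lane(spec: GelLaneSpec, seed=0) -> LaneProfile:
    """Render a lane profile from its design, with stored ground truth."""
    rng = np.random.default_rng(seed)
    x = np.arange(0.0, spec.length_mm + spec.dx_mm / 2, spec.dx_mm)
    y = np.full_like(x, spec.baseline)
    for band in spec.bands:
        pos = spec.migration_a - spec.migration_b * np.log10(band.mw_kda)
        y += (band.area / (band.width * np.sqrt(2 * np.pi))
              * np.exp(-0.5 * ((x - pos) / band.width) ** 2))
    if spec.noise_sd > 0:
        y = y + rng.normal(0, spec.noise_sd, x.shape)
    return LaneProfile(
        position=x, intensity=y,
        mw_map=(spec.migration_a, spec.migration_b),
        bands_truth=spec.bands, baseline_truth=spec.baseline,
        meta={"noise_sd": spec.noise_sd},
    )
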