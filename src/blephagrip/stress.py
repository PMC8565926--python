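"""Suction-stress estimates from whole-animal forces and disc geometry.

A larva attaches with up to six suction organs.  Dividing the peak detachment
force by the total contact area gives the suction stress, under two bracketing
assumptions:

* *conservative* — all six organs in contact, and the contact area of each is a
  fitted circle that includes the outer fringe layer (which lies outside the
  suction seal).  Both choices inflate the area, so the stress is a lower
  bound.
* *realistic* — only ``organs_in_contact`` organs (three of six by default)
  remain attached immediately before detachment, and the fringe (33% of the
  imaged area by default) is excluded:

  ``realistic = conservative / ((1 - fringe_fraction) * organs_in_contact / n_organs)``

Stresses are computed per individual (its own force over its own representative
disc area), then aggregated as mean +/- SD across individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_FRINGE_FRACTION",
    "DEFAULT_N_ORGANS",
    "DEFAULT_ORGANS_IN_CONTACT",
    "DEFAULT_BEAMS_PER_QUADRANT",
    "DiscGeometry",
    "StressEstimate",
    "disc_area",
    "conservative_stress",
    "realistic_stress",
    "beam_geometry",
    "stress_table",
    "aggregate_stress",
]

DEFAULT_FRINGE_FRACTION = 0.33
DEFAULT_N_ORGANS = 6
DEFAULT_ORGANS_IN_CONTACT = 3
DEFAULT_BEAMS_PER_QUADRANT = 72


@dataclass(frozen=True)
class DiscGeometry:
    """Contact-area model of one individual's representative suction disc.

    ``disc_area_um2`` may be given directly; otherwise it is derived from the
    fitted-circle diameter ``disc_diameter_um`` as pi*(d/2)^2.
    """

    species: str
    individual_id: str
    disc_diameter_um: float | None = None
    disc_area_um2: float | None = None
    n_organs_total: int = DEFAULT_N_ORGANS

    def __post_init__(self) -> None:
        if self.disc_area_um2 is None and self.disc_diameter_um is None:
            raise ValueError("need disc_diameter_um or disc_area_um2")
        if self.disc_area_um2 is not None and not self.disc_area_um2 > 0:
            raise ValueError("disc_area_um2 must be > 0")
        if self.disc_diameter_um is not None and not self.disc_diameter_um > 0:
            raise ValueError("disc_diameter_um must be > 0")

    @property
    def area_um2(self) -> float:
        if self.disc_area_um2 is not None:
            return self.disc_area_um2
        return disc_area(self.disc_diameter_um)


@dataclass(frozen=True)
class StressEstimate:
    """Per-individual shear/normal stress under both area assumptions, kPa."""

    species: str
    individual_id: str
    orientation: str
    conservative_kpa: float
    realistic_kpa: float


def disc_area(diameter: float) -> float:
    """Area of the fitted contact circle, pi*(d/2)^2 (same length unit as d)."""
    if not diameter > 0:
        raise ValueError(f"diameter must be > 0, got {diameter!r}")
    return math.pi * (diameter / 2.0) ** 2


def conservative_stress(peak_force_mn: float, disc_area_um2: float,
                        n_organs: int = DEFAULT_N_ORGANS) -> float:
    """Conservative suction stress in kPa.

    ``peak_force_mn`` is the whole-animal peak force (mN); ``disc_area_um2``
    the fringe-inclusive area of one representative disc (um^2); all
    ``n_organs`` organs are assumed loaded.  1 mN / 1 um^2 = 1 GPa = 1e6 kPa.
    """
    if not peak_force_mn >= 0:
        raise ValueError("peak force must be >= 0")
    if not disc_area_um2 > 0:
        raise ValueError("disc area must be > 0")
    if not n_organs > 0:
        raise ValueError("n_organs must be > 0")
    return peak_force_mn / (n_organs * disc_area_um2) * 1e6


def realistic_stress(conservative_kpa: float,
                     fringe_fraction: float = DEFAULT_FRINGE_FRACTION,
                     organs_in_contact: int = DEFAULT_ORGANS_IN_CONTACT,
                     n_organs: int = DEFAULT_N_ORGANS) -> float:
    """Correct a conservative stress for fringe area and partial organ contact.

    Dividing by ``(1 - fringe_fraction) * organs_in_contact / n_organs``
    shrinks the effective contact area, so the realistic stress is always at
    least the conservative one.
    """
    if not 0 <= fringe_fraction < 1:
        raise ValueError(f"fringe_fraction must be in [0, 1), got {fringe_fraction!r}")
    if not 0 < organs_in_contact <= n_organs:
        raise ValueError("need 0 < organs_in_contact <= n_organs")
    return conservative_kpa / ((1.0 - fringe_fraction) * organs_in_contact / n_organs)


def beam_geometry(beams_per_quadrant: int = DEFAULT_BEAMS_PER_QUADRANT) -> dict:
    """Radial-beam layout of the suction disc.

    The disc interior is reinforced by radial beams; counting them in one 90
    degree segment and multiplying by four gives the per-disc count and the
    angular spacing between neighbouring beams.
    """
    if not beams_per_quadrant > 0:
        raise ValueError("beams_per_quadrant must be > 0")
    beams_per_disc = 4 * beams_per_quadrant
    return {
        "beams_per_disc": beams_per_disc,
        "angular_spacing_deg": 360.0 / beams_per_disc,
    }


def stress_table(
    forces: pd.DataFrame,
    geometry: pd.DataFrame,
    fringe_fraction: float = DEFAULT_FRINGE_FRACTION,
    organs_in_contact: int = DEFAULT_ORGANS_IN_CONTACT,
    n_organs: int = DEFAULT_N_ORGANS,
) -> pd.DataFrame:
    """Join per-individual peak forces with disc geometry and derive stresses.

    ``forces`` needs columns species, individual_id, orientation, force_mN
    (one peak row per individual and orientation); ``geometry`` needs species,
    individual_id and either disc_diameter_um or disc_area_um2.  Returns one
    row per matched individual with conservative and realistic stresses (kPa).
    """
    geo = geometry.copy()
    if "disc_area_um2" not in geo.columns:
        geo["disc_area_um2"] = np.nan
    if "disc_diameter_um" in geo.columns:
        need = geo["disc_area_um2"].isna()
        geo.loc[need, "disc_area_um2"] = [
            disc_area(d) for d in geo.loc[need, "disc_diameter_um"]
        ]
    if geo["disc_area_um2"].isna().any():
        raise ValueError("geometry rows without diameter or area")

    merged = forces.merge(
        geo[["species", "individual_id", "disc_area_um2"]],
        on=["species", "individual_id"],
        how="inner",
    )
    cons = np.array(
        [
            conservative_stress(f, a, n_organs)
            for f, a in zip(merged["force_mN"], merged["disc_area_um2"])
        ]
    )
    real = np.array(
        [realistic_stress(c, fringe_fraction, organs_in_contact, n_organs) for c in cons]
    )
    out = merged[["species", "individual_id", "orientation", "force_mN",
                  "disc_area_um2"]].copy()
    out["conservative_kpa"] = cons
    out["realistic_kpa"] = real
    return out


def aggregate_stress(per_individual: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of stresses across individuals, by species and orientation.

    SD is the sample standard deviation (ddof=1); a single individual yields
    NaN SD rather than an error.
    """
    grouped = per_individual.groupby(["species", "orientation"], sort=True)
    rows = []
    for (species, orientation), g in grouped:
        rows.append(
            {
                "species": species,
                "orientation": orientation,
                "n": len(g),
                "conservative_mean_kpa": g["conservative_kpa"].mean(),
                "conservative_sd_kpa": g["conservative_kpa"].std(ddof=1),
                "realistic_mean_kpa": g["realistic_kpa"].mean(),
                "realistic_sd_kpa": g["realistic_kpa"].std(ddof=1),
            }
        )
    return pd.DataFrame(rows)
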