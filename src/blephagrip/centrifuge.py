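"""Centrifuge attachment-force assay.

Whole-animal attachment performance is measured by spinning a specimen on a
platform at increasing rotation frequency until it detaches.  At detachment the
specimen at radial position ``r`` experiences a centripetal acceleration
``a = (2*pi*f)**2 * r``, so the force that peeled it off the substrate is
``F = m * a`` and its dimensionless force per body weight is ``a / g``.

The assay has a hard ceiling on rotation frequency (safety limit, 75 rps by
default).  Specimens that never detach are *censored*: their acceleration is
replaced by the maximum acceleration at which a conspecific *did* detach, a
conservative substitution that never exaggerates performance.  Where a specimen
was spun several times, the highest force across repeats is its peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "G_STANDARD",
    "DEFAULT_CEILING_RPS",
    "ORIENTATIONS",
    "SUBSTRATES",
    "CentrifugeTrial",
    "ForceResult",
    "InvalidTrialError",
    "UnresolvableCensoringError",
    "centripetal_acceleration",
    "detachment_force",
    "force_per_body_weight",
    "censor_adjust",
    "peak_per_individual",
    "read_trials_csv",
    "write_trials_csv",
    "trials_to_dataframe",
    "trials_from_dataframe",
    "results_to_dataframe",
]

#: Standard gravitational acceleration used to normalise forces, m s^-2.
G_STANDARD = 9.81

#: Default safety ceiling of the centrifuge, rotations per second.
DEFAULT_CEILING_RPS = 75.0

ORIENTATIONS = ("shear", "normal")
SUBSTRATES = ("smooth", "micro_rough", "coarse_rough")

#: Column order of the trial CSV interface (masses in mg, radii in mm).
TRIAL_CSV_COLUMNS = [
    "species",
    "individual_id",
    "trial_id",
    "mass_mg",
    "radius_mm",
    "freq_rps",
    "orientation",
    "substrate",
    "detached",
]


class InvalidTrialError(ValueError):
    """A trial record violates a physical precondition."""


class UnresolvableCensoringError(ValueError):
    """A species has only censored trials, so no substitute acceleration exists."""


@dataclass(frozen=True)
class CentrifugeTrial:
    """One specimen x run record, SI units internally.

    Parameters
    ----------
    mass : float
        Specimen mass in kg, strictly positive.
    radius : float
        Radial position of the specimen on the platform in m, strictly positive.
    freq : float
        Rotation frequency at detachment (or at the ceiling, if censored), rps.
    detached : bool
        False marks a censored trial: the specimen held on at ``freq``.
    """

    species: str
    individual_id: str
    trial_id: str
    mass: float
    radius: float
    freq: float
    orientation: str = "shear"
    substrate: str = "smooth"
    detached: bool = True

    def __post_init__(self) -> None:
        if not (self.mass > 0):
            raise InvalidTrialError(f"mass must be > 0, got {self.mass!r}")
        if not (self.radius > 0):
            raise InvalidTrialError(f"radius must be > 0, got {self.radius!r}")
        if self.freq < 0:
            raise InvalidTrialError(f"freq must be >= 0, got {self.freq!r}")
        if self.orientation not in ORIENTATIONS:
            raise InvalidTrialError(f"unknown orientation {self.orientation!r}")
        if self.substrate not in SUBSTRATES:
            raise InvalidTrialError(f"unknown substrate {self.substrate!r}")


@dataclass(frozen=True)
class ForceResult:
    """Derived force quantities for one trial (SI units)."""

    trial: CentrifugeTrial
    acceleration: float
    force: float
    force_per_body_weight: float
    censored_substituted: bool = False

    @property
    def species(self) -> str:
        return self.trial.species

    @property
    def individual_id(self) -> str:
        return self.trial.individual_id


def centripetal_acceleration(freq: float, radius: float) -> float:
    """Centripetal acceleration ``(2*pi*f)**2 * r`` in m s^-2."""
    if radius <= 0:
        raise InvalidTrialError(f"radius must be > 0, got {radius!r}")
    if freq < 0:
        raise InvalidTrialError(f"freq must be >= 0, got {freq!r}")
    return (2.0 * math.pi * freq) ** 2 * radius


def detachment_force(mass: float, freq: float, radius: float) -> float:
    """Detachment force ``m * (2*pi*f)**2 * r`` in N.

    Linear in mass and radius, quadratic in rotation frequency.
    """
    if mass <= 0:
        raise InvalidTrialError(f"mass must be > 0, got {mass!r}")
    return mass * centripetal_acceleration(freq, radius)


def force_per_body_weight(freq: float, radius: float, g: float = G_STANDARD) -> float:
    """Dimensionless attachment performance ``(2*pi*f)**2 * r / g``.

    The specimen mass cancels, so equally adhesive specimens of different
    sizes score identically.
    """
    if g <= 0:
        raise InvalidTrialError(f"g must be > 0, got {g!r}")
    return centripetal_acceleration(freq, radius) / g


def _force_result(
    trial: CentrifugeTrial,
    acceleration: float,
    g: float,
    censored_substituted: bool,
) -> ForceResult:
    return ForceResult(
        trial=trial,
        acceleration=acceleration,
        force=trial.mass * acceleration,
        force_per_body_weight=acceleration / g,
        censored_substituted=censored_substituted,
    )


def censor_adjust(
    trials: Sequence[CentrifugeTrial], g: float = G_STANDARD
) -> list[ForceResult]:
    """Convert trials to forces, substituting censored accelerations.

    A censored trial (``detached=False``) is assigned the maximum centripetal
    acceleration among the *detached* trials of the same species; force is then
    recomputed with the censored specimen's own mass and radius.  Detached
    trials pass through unchanged.  Idempotent: the substituted acceleration is
    by construction at least the trial's own (the censored specimen outlasted
    every detached conspecific), so re-applying the rule changes nothing.

    Raises
    ------
    UnresolvableCensoringError
        If some species has censored trials but no detached trial to borrow an
        acceleration from.
    """
    max_detached: dict[str, float] = {}
    for t in trials:
        if t.detached:
            a = centripetal_acceleration(t.freq, t.radius)
            if a > max_detached.get(t.species, -math.inf):
                max_detached[t.species] = a

    out: list[ForceResult] = []
    for t in trials:
        own = centripetal_acceleration(t.freq, t.radius)
        if t.detached:
            out.append(_force_result(t, own, g, False))
        else:
            if t.species not in max_detached:
                raise UnresolvableCensoringError(
                    f"species {t.species!r} has only censored trials"
                )
            sub = max(max_detached[t.species], own)
            out.append(_force_result(t, sub, g, True))
    return out


def peak_per_individual(results: Iterable[ForceResult]) -> list[ForceResult]:
    """Reduce repeated runs to one peak per individual.

    Returns, for every (species, individual) pair, the repeat with the highest
    force; its per-body-weight value travels with it.  Order follows first
    appearance of each individual.
    """
    best: dict[tuple[str, str], ForceResult] = {}
    order: list[tuple[str, str]] = []
    for r in results:
        key = (r.species, r.individual_id)
        if key not in best:
            best[key] = r
            order.append(key)
        elif r.force > best[key].force:
            best[key] = r
    if not order:
        raise ValueError("peak_per_individual: no results given")
    return [best[k] for k in order]


# ---------------------------------------------------------------------------
# CSV interface (mass in mg, radius in mm at the file boundary; SI inside).
# Floats are written with %.10g so that a read/write round trip reproduces the
# parsed values exactly.
# ---------------------------------------------------------------------------

def trials_from_dataframe(
    df: pd.DataFrame, ceiling: float | None = DEFAULT_CEILING_RPS
) -> list[CentrifugeTrial]:
    missing = [c for c in TRIAL_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidTrialError(f"trial table missing columns: {missing}")
    trials = []
    for row in df.itertuples(index=False):
        freq = float(row.freq_rps)
        if ceiling is not None and freq > ceiling * (1 + 1e-9):
            raise InvalidTrialError(
                f"trial {row.trial_id!r}: freq {freq} rps exceeds ceiling {ceiling}"
            )
        detached = row.detached
        if isinstance(detached, str):
            detached = detached.strip().lower() in ("true", "1", "yes")
        trials.append(
            CentrifugeTrial(
                species=str(row.species),
                individual_id=str(row.individual_id),
                trial_id=str(row.trial_id),
                mass=float(row.mass_mg) * 1e-6,
                radius=float(row.radius_mm) * 1e-3,
                freq=freq,
                orientation=str(row.orientation),
                substrate=str(row.substrate),
                detached=bool(detached),
            )
        )
    return trials


def trials_to_dataframe(trials: Sequence[CentrifugeTrial]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [t.species for t in trials],
            "individual_id": [t.individual_id for t in trials],
            "trial_id": [t.trial_id for t in trials],
            "mass_mg": [t.mass * 1e6 for t in trials],
            "radius_mm": [t.radius * 1e3 for t in trials],
            "freq_rps": [t.freq for t in trials],
            "orientation": [t.orientation for t in trials],
            "substrate": [t.substrate for t in trials],
            "detached": [t.detached for t in trials],
        }
    )


def read_trials_csv(
    path: str | Path, ceiling: float | None = DEFAULT_CEILING_RPS
) -> list[CentrifugeTrial]:
    return trials_from_dataframe(pd.read_csv(path), ceiling=ceiling)


def write_trials_csv(trials: Sequence[CentrifugeTrial], path: str | Path) -> None:
    trials_to_dataframe(trials).to_csv(path, index=False, float_format="%.10g")


def results_to_dataframe(results: Sequence[ForceResult]) -> pd.DataFrame:
    """Tabulate force results (force in mN at the file boundary)."""
    return pd.DataFrame(
        {
            "species": [r.species for r in results],
            "individual_id": [r.individual_id for r in results],
            "trial_id": [r.trial.trial_id for r in results],
            "orientation": [r.trial.orientation for r in results],
            "substrate": [r.trial.substrate for r in results],
            "acceleration_m_s2": [r.acceleration for r in results],
            "force_mN": [r.force * 1e3 for r in results],
            "force_per_body_weight": [r.force_per_body_weight for r in results],
            "censored_substituted": [r.censored_substituted for r in results],
        }
    )
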