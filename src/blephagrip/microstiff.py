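"""Lower bound on the microtrichia cuticle elastic modulus via the elastica.

The suction-disc surface carries a dense array of spine-like microtrichia that
contact the substrate only at their tips, even when the disc is pressed onto
micro-structured surfaces.  Modelling a microtrichium as an inclined
cylindrical cantilever (length ``L``, diameter ``D``, angle ``alpha`` to the
substrate) loaded at the tip by the share ``F`` of the suction force
perpendicular to the substrate, there is a critical elastic modulus below
which the beam would bend far enough for its tip tangent to reach the
substrate plane ("side contact").  Since side contact is never observed, the
cuticle modulus must exceed this critical value.

Large-deflection (elastica) theory gives the critical modulus in closed form.
With tangent angle ``theta(s)`` measured from the substrate plane, moment
balance for a tip force perpendicular to the substrate reads
``EI * theta'' = F * cos(theta)`` with ``theta(0) = alpha`` at the clamped base
and zero curvature at the tip.  At the margin of side contact the tip angle is
zero, and the arc-length integral reduces to elliptic integrals of the first
kind with elliptic modulus ``p**2 = 1/2``:

    L * sqrt(F / (E I)) = K(p^2) - F_inc(phi_a | p^2),
    phi_a = arcsin( sin((90 deg - alpha)/2) / p ),

hence

    E_crit = F * L**2 / ( I * [K(p^2) - F_inc(phi_a | p^2)]**2 ),

with ``I = pi * D**4 / 64`` the second moment of area of the circular cross
section.  ``E_crit`` decreases monotonically with ``alpha``: steeper
microtrichia are harder to flatten.  An independent numerical oracle
(:func:`elastica_side_contact`, shooting on the same boundary-value problem)
is provided to validate the closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.special import ellipk, ellipkinc

__all__ = [
    "P_SQUARED",
    "MicrotrichiumBeam",
    "LoadSharing",
    "ElasticaContact",
    "microtrichia_count",
    "round_to_thousand",
    "per_tip_force",
    "second_moment",
    "incomplete_elliptic_f",
    "complete_elliptic_k",
    "elliptic_amplitude",
    "critical_modulus",
    "elastica_side_contact",
    "critical_modulus_numeric",
    "stiffness_scan",
]

#: Elliptic modulus squared fixed by the perpendicular-load geometry.
P_SQUARED = 0.5


@dataclass(frozen=True)
class MicrotrichiumBeam:
    """Geometry and tip load of one microtrichium (SI units).

    Defaults are the measured microtrichium geometry: length 6.7 um, diameter
    0.56 um, resting angle 45 degrees to the disc surface, and a 56 nN share
    of the peak normal suction load.
    """

    length: float = 6.7e-6
    diameter: float = 0.56e-6
    angle_deg: float = 45.0
    tip_force: float = 56e-9

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError("length must be > 0")
        if not self.diameter > 0:
            raise ValueError("diameter must be > 0")
        if not 0 < self.angle_deg < 90:
            raise ValueError(f"angle must lie in (0, 90) deg, got {self.angle_deg!r}")
        if not self.tip_force >= 0:
            raise ValueError("tip_force must be >= 0")

    @property
    def second_moment(self) -> float:
        """Second moment of area of the circular section, pi*D^4/64 (m^4)."""
        return second_moment(self.diameter)


@dataclass(frozen=True)
class LoadSharing:
    """Division of the whole-animal peak normal force among microtrichia tips.

    The disc area bearing spine-like microtrichia (~49,000 um^2) times their
    tip density (~0.7 um^-2) gives the number of tips assumed to share the
    per-organ load equally.
    """

    whole_animal_force: float = 11.6e-3
    n_organs: int = 6
    disc_microtrichia_area_um2: float = 49_000.0
    tip_density_per_um2: float = 0.7

    @property
    def microtrichia_count(self) -> float:
        return microtrichia_count(self.disc_microtrichia_area_um2,
                                  self.tip_density_per_um2)

    @property
    def per_tip_force(self) -> float:
        return per_tip_force(self.whole_animal_force, self.n_organs,
                             self.microtrichia_count)


@dataclass(frozen=True)
class ElasticaContact:
    """Outcome of the numerical large-deflection solve at a given modulus."""

    side_contact: bool
    tip_rotation: float  # rad, rotation of the tip tangent from its rest angle
    tip_angle: float  # rad, final tip tangent angle to the substrate


def microtrichia_count(area_um2: float, density_per_um2: float) -> float:
    """Number of microtrichia tips: area x density (exact product).

    A zero density is degenerate (no load-bearing tips) and returns 0.0;
    display rounding is left to :func:`round_to_thousand`.
    """
    if not area_um2 > 0:
        raise ValueError("area must be > 0")
    if density_per_um2 < 0:
        raise ValueError("density must be >= 0")
    return area_um2 * density_per_um2


def round_to_thousand(count: float) -> int:
    """Report-level rounding of a tip count to the nearest thousand."""
    return int(round(count / 1000.0)) * 1000


def per_tip_force(whole_force: float, n_organs: int, count: float) -> float:
    """Equal-share load on one microtrichium tip: F_total / n_organs / count."""
    if not whole_force >= 0:
        raise ValueError("whole_force must be >= 0")
    if not n_organs > 0:
        raise ValueError("n_organs must be > 0")
    if not count > 0:
        raise ValueError("count must be > 0")
    return whole_force / n_organs / count


def second_moment(diameter: float) -> float:
    """Second moment of area of a solid circular section, pi*D^4/64."""
    if not diameter > 0:
        raise ValueError("diameter must be > 0")
    return math.pi * diameter**4 / 64.0


def incomplete_elliptic_f(phi: float, m: float) -> float:
    """Incomplete elliptic integral of the first kind F(phi | m).

    ``F(phi | m) = integral_0^phi dtheta / sqrt(1 - m sin^2 theta)`` with
    parameter ``m = p**2 < 1``.  ``F(pi/2 | m) = K(m)``.
    """
    if not 0 <= m < 1:
        raise ValueError(f"elliptic parameter m must lie in [0, 1), got {m!r}")
    if not 0 <= phi <= math.pi / 2:
        raise ValueError(f"amplitude must lie in [0, pi/2], got {phi!r}")
    return float(ellipkinc(phi, m))


def complete_elliptic_k(m: float) -> float:
    """Complete elliptic integral of the first kind K(m)."""
    if not 0 <= m < 1:
        raise ValueError(f"elliptic parameter m must lie in [0, 1), got {m!r}")
    return float(ellipk(m))


def elliptic_amplitude(angle_deg: float) -> float:
    """Elliptic amplitude phi_a for a beam at ``angle_deg`` to the substrate.

    ``phi_a = arcsin( sin((90 deg - alpha) / 2) / p )`` with ``p = 1/sqrt(2)``;
    the complement appears because the tip force is perpendicular to the
    substrate while the angle is measured from the substrate plane.
    """
    if not 0 < angle_deg <= 90:
        raise ValueError(f"angle must lie in (0, 90] deg, got {angle_deg!r}")
    half_complement = math.radians(90.0 - angle_deg) / 2.0
    return math.asin(math.sin(half_complement) / math.sqrt(P_SQUARED))


def critical_modulus(beam: MicrotrichiumBeam) -> float:
    """Closed-form critical elastic modulus (Pa) below which side contact occurs.

    ``E_crit = F L^2 / (I [K(1/2) - F_inc(phi_a | 1/2)]**2)``; linear in the
    tip force, quadratic in length, proportional to D^-4, and monotonically
    decreasing in the contact angle.
    """
    if not beam.tip_force > 0:
        raise ValueError("critical modulus requires a positive tip force")
    k = complete_elliptic_k(P_SQUARED)
    f = incomplete_elliptic_f(elliptic_amplitude(beam.angle_deg), P_SQUARED)
    lam = k - f  # = L * sqrt(F / (E I)) at the side-contact margin
    return beam.tip_force * beam.length**2 / (beam.second_moment * lam**2)


# ---------------------------------------------------------------------------
# Numerical oracle: shooting on the inextensible large-deflection cantilever.
# Nondimensionalised with t = (arc length from the tip) / L the BVP becomes
#   theta'' = beta * cos(theta),  beta = F L^2 / (E I),
# with zero curvature at the tip (t=0) and theta = alpha at the base (t=1).
# ---------------------------------------------------------------------------

_ODE_RTOL = 1e-8
_ODE_NODES = 201


def _base_residual(tip_angle: float, beta: float, alpha: float) -> float:
    """Shooting residual for the monotone equilibrium branch.

    Integrates from the free tip (zero curvature) towards the base and stops
    at the first crossing of the clamp angle ``alpha``.  Returns a positive
    number if the crossing happens before the full length is used (beam too
    curved for this tip angle), the base-angle deficit otherwise.  The event
    keeps the root-find on the monotone branch: oscillatory equilibria that
    revisit ``alpha`` after a turning point are rejected.
    """

    def reach_alpha(t, y):
        return y[0] - alpha

    reach_alpha.terminal = True
    reach_alpha.direction = 1.0

    if tip_angle >= alpha:
        return 1.0
    sol = solve_ivp(
        lambda t, y: (y[1], beta * math.cos(y[0])),
        (0.0, 1.0),
        (tip_angle, 0.0),
        t_eval=np.linspace(0.0, 1.0, _ODE_NODES),
        events=reach_alpha,
        rtol=_ODE_RTOL,
        atol=1e-12,
    )
    if not sol.success:  # pragma: no cover - RK45 on a smooth ODE
        raise RuntimeError(f"elastica integration failed: {sol.message}")
    if sol.status == 1:  # reached alpha at arc fraction t* <= 1
        return 1.0 - float(sol.t_events[0][0])
    return float(sol.y[0, -1]) - alpha


def elastica_side_contact(modulus: float, beam: MicrotrichiumBeam) -> ElasticaContact:
    """Numerically solve the large-deflection cantilever at a given modulus.

    Shooting method: the tip tangent angle is the unknown; the elastica is
    integrated from the free tip (zero curvature) to the base, and the tip
    angle is adjusted until the base matches the clamped angle ``alpha``.
    Side contact is declared when the equilibrium tip tangent reaches the
    substrate plane, i.e. the tip rotation reaches ``alpha``.

    Raises
    ------
    RuntimeError
        If the shooting root-find cannot bracket a solution.
    """
    if not modulus > 0:
        raise ValueError("modulus must be > 0")
    alpha = math.radians(beam.angle_deg)
    if beam.tip_force == 0:
        return ElasticaContact(False, 0.0, alpha)
    beta = beam.tip_force * beam.length**2 / (modulus * beam.second_moment)

    def residual(tip_angle: float) -> float:
        return _base_residual(tip_angle, beta, alpha)

    lo, hi = -math.pi / 2 + 1e-9, alpha
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo * r_hi > 0:
        raise RuntimeError(
            "elastica shooting failed to bracket the tip angle "
            f"(beta={beta:.3g}, residuals {r_lo:.3g}/{r_hi:.3g})"
        )
    tip_angle = brentq(residual, lo, hi, xtol=1e-12, rtol=1e-12)
    rotation = alpha - tip_angle
    return ElasticaContact(tip_angle <= 1e-9, rotation, tip_angle)


def critical_modulus_numeric(
    beam: MicrotrichiumBeam, rel_tol: float = 1e-6, via: str = "margin"
) -> float:
    """Critical modulus from the numerical elastica, independent of the closed form.

    ``via='margin'`` (default) pins the marginal state directly: with the tip
    tangent flat on the substrate, root-find the load parameter ``beta`` whose
    base angle equals ``alpha``.  ``via='bisect'`` brackets the critical
    modulus by bisection on the boolean outcome of
    :func:`elastica_side_contact`; slower, used as a cross-check.
    """
    if not beam.tip_force > 0:
        raise ValueError("critical modulus requires a positive tip force")
    alpha = math.radians(beam.angle_deg)
    scale = beam.tip_force * beam.length**2 / beam.second_moment

    if via == "margin":
        beta_crit = brentq(
            lambda b: _base_residual(0.0, b, alpha),
            1e-8,
            50.0,
            xtol=1e-14,
            rtol=1e-12,
        )
        return scale / beta_crit

    if via != "bisect":
        raise ValueError(f"unknown mode {via!r}")
    guess = scale  # beta = 1; true beta_crit is O(1)
    lo, hi = guess / 50.0, guess * 50.0
    if elastica_side_contact(lo, beam).side_contact is False:
        raise RuntimeError("bisection lower bound does not show side contact")
    if elastica_side_contact(hi, beam).side_contact is True:
        raise RuntimeError("bisection upper bound still shows side contact")
    while (hi - lo) / hi > rel_tol:
        mid = math.sqrt(lo * hi)
        if elastica_side_contact(mid, beam).side_contact:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def stiffness_scan(
    beam: MicrotrichiumBeam,
    alpha_grid_deg,
    oracle: bool = False,
) -> pd.DataFrame:
    """Critical modulus across a grid of contact angles.

    Returns one row per angle with ``E_crit_gpa`` from the closed form and,
    when ``oracle=True``, ``E_crit_oracle_gpa`` from the numerical elastica.
    """
    rows = []
    for a in alpha_grid_deg:
        b = replace(beam, angle_deg=float(a))
        row = {"alpha_deg": float(a), "E_crit_gpa": critical_modulus(b) / 1e9}
        if oracle:
            row["E_crit_oracle_gpa"] = critical_modulus_numeric(b) / 1e9
        rows.append(row)
    return pd.DataFrame(rows)
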