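"""Synthetic inputs with the statistical structure of the real assays.

Three generators cover the pipeline's inputs end to end:

* :func:`gen_force_trials` — centrifuge trial records whose per-body-weight
  peaks follow a lognormal distribution moment-matched to a species profile
  (arithmetic mean and SD), attenuated per substrate, and censored at the
  machine's frequency ceiling exactly as in the real assay;
* :func:`gen_rough_surface` — Gaussian random fields rescaled to an exact
  target Ra, standing in for interferometry height maps;
* :func:`gen_zstack` — focal stacks rendered from a known height map with
  height-dependent defocus blur, the ground truth for shape-from-focus.

Every generator is a pure function of its parameters and seed.  The default
species profiles carry the measured per-body-weight shear performance on
smooth substrates: 585 +/- 330 (*Liponeura cordata*), 324 +/- 153
(*L. cinerascens*) and 1120 +/- 282 (*Hapalothrix lugubris*) (mean +/- SD).
Substrate attenuation reproduces the observed fold changes of geometric means:
a twofold drop from smooth to micro-rough for the larvae, and for the
stick-insect comparator a 16-fold drop on micro-rough with smooth and
coarse-rough equivalent.  Stick-insect absolute levels are not published;
the default (40 +/- 15 body weights) is an assumed, tunable placeholder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .centrifuge import (
    DEFAULT_CEILING_RPS,
    G_STANDARD,
    CentrifugeTrial,
)
from .surface import HeightMap, ZStack

__all__ = [
    "SpeciesForceProfile",
    "DEFAULT_PROFILES",
    "gen_force_trials",
    "gen_rough_surface",
    "gen_zstack",
    "gen_disc_geometry",
]


@dataclass(frozen=True)
class SpeciesForceProfile:
    """Distributional profile of one species' attachment performance.

    ``mean_shear_bw`` / ``sd_shear_bw`` are the arithmetic mean and SD of the
    peak shear force per body weight on the smooth substrate; other substrates
    scale the whole distribution by ``substrate_multipliers`` (<= 1, smooth=1).
    """

    species: str
    mean_shear_bw: float
    sd_shear_bw: float
    substrate_multipliers: dict = field(
        default_factory=lambda: {"smooth": 1.0, "micro_rough": 0.5,
                                 "coarse_rough": 0.25}
    )
    mass_range_mg: tuple[float, float] = (2.0, 12.0)
    ceiling_rps: float | None = DEFAULT_CEILING_RPS

    def __post_init__(self) -> None:
        if not (self.mean_shear_bw > 0 and self.sd_shear_bw > 0):
            raise ValueError("mean and sd must be > 0")
        if self.substrate_multipliers.get("smooth", 1.0) != 1.0:
            raise ValueError("smooth multiplier must be 1")
        if any(not 0 < m <= 1 for m in self.substrate_multipliers.values()):
            raise ValueError("substrate multipliers must lie in (0, 1]")


#: Measured larval profiles (smooth-substrate shear, mean +/- SD body weights)
#: plus an assumed-level stick-insect comparator (only its fold changes across
#: substrates are empirical).
DEFAULT_PROFILES = {
    "L_cordata": SpeciesForceProfile("L_cordata", 585.0, 330.0),
    "L_cinerascens": SpeciesForceProfile("L_cinerascens", 324.0, 153.0),
    "H_lugubris": SpeciesForceProfile("H_lugubris", 1120.0, 282.0),
    "C_morosus": SpeciesForceProfile(
        "C_morosus",
        40.0,
        15.0,
        substrate_multipliers={"smooth": 1.0, "micro_rough": 1.0 / 16.0,
                               "coarse_rough": 1.0},
    ),
}


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match (mu, sigma) of a lognormal to arithmetic mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("moment matching requires positive mean and sd")
    sigma2 = math.log1p((sd / mean) ** 2)  # always finite for sd < inf
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def gen_force_trials(
    profile: SpeciesForceProfile,
    n: int,
    radius: float = 0.07,
    seed: int | np.random.Generator = 0,
    substrate: str = "smooth",
    orientation: str = "shear",
    repeats: int = 1,
    g: float = G_STANDARD,
) -> list[CentrifugeTrial]:
    """Draw ``n`` individuals' centrifuge trials for one substrate.

    Per-body-weight peaks are lognormal with the profile's moments scaled by
    the substrate multiplier; each is converted to a detachment frequency via
    ``f = sqrt(bw * g / r) / (2 * pi)`` at platform radius ``radius`` (m).
    Draws whose frequency would exceed the profile's ceiling are emitted as
    censored trials pinned at the ceiling (``detached=False``).  ``repeats``
    i.i.d. runs share each individual's id, mirroring the 2-4 repeats per
    specimen in the real assay.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if substrate not in profile.substrate_multipliers:
        raise ValueError(f"no multiplier for substrate {substrate!r}")
    rng = np.random.default_rng(seed)
    mult = profile.substrate_multipliers[substrate]
    mu, sigma = _lognormal_params(profile.mean_shear_bw * mult,
                                  profile.sd_shear_bw * mult)
    lo, hi = profile.mass_range_mg
    masses_mg = rng.uniform(lo, hi, size=n)
    bw = rng.lognormal(mu, sigma, size=(n, repeats))

    trials: list[CentrifugeTrial] = []
    for i in range(n):
        for j in range(repeats):
            freq = math.sqrt(bw[i, j] * g / radius) / (2.0 * math.pi)
            ceiling = profile.ceiling_rps
            detached = ceiling is None or freq <= ceiling
            trials.append(
                CentrifugeTrial(
                    species=profile.species,
                    individual_id=f"{profile.species}_{substrate}_{i:04d}",
                    trial_id=f"{profile.species}_{substrate}_{i:04d}_r{j}",
                    mass=masses_mg[i] * 1e-6,
                    radius=radius,
                    freq=freq if detached else float(ceiling),
                    orientation=orientation,
                    substrate=substrate,
                    detached=detached,
                )
            )
    return trials


def gen_rough_surface(
    target_ra: float,
    corr_len: float,
    shape: tuple[int, int] = (128, 128),
    pitch: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> HeightMap:
    """Isotropic Gaussian random surface with an exact target Ra.

    Spectral synthesis: white Gaussian noise is filtered in Fourier space with
    a Gaussian spectrum of correlation length ``corr_len`` (um), then the
    zero-mean field is rescaled so that the measured Ra (mean absolute
    deviation after mean detrend) equals ``target_ra`` exactly.
    """
    if not target_ra > 0:
        raise ValueError("target_ra must be > 0")
    if corr_len < pitch:
        raise ValueError("corr_len must be at least the pixel pitch")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    ky = np.fft.fftfreq(ny, d=pitch)
    kx = np.fft.fftfreq(nx, d=pitch)
    k2 = ky[:, None] ** 2 + kx[None, :] ** 2
    spectrum = np.exp(-(math.pi * corr_len) ** 2 * k2 / 2.0)
    noise = rng.standard_normal((ny, nx))
    fieldr = np.real(np.fft.ifft2(np.fft.fft2(noise) * spectrum))
    fieldr -= fieldr.mean()
    ra = np.abs(fieldr).mean()
    if ra == 0:  # pragma: no cover - degenerate white-noise fluke
        raise RuntimeError("generated field is flat; change seed or corr_len")
    return HeightMap(heights=fieldr * (target_ra / ra), pixel_pitch=pitch)


def _speckle_texture(shape: tuple[int, int], rng: np.random.Generator,
                     corr_px: float = 1.5) -> np.ndarray:
    """Band-limited random speckle with unit mean and strong local contrast."""
    from scipy.ndimage import gaussian_filter

    t = gaussian_filter(rng.standard_normal(shape), corr_px, mode="wrap")
    t = (t - t.mean()) / t.std()
    return 1.0 + 0.5 * t


def gen_zstack(
    hmap: HeightMap,
    z_levels: np.ndarray,
    texture_seed: int | np.random.Generator = 0,
    noise_sd: float = 0.0,
    defocus_slope: float = 0.8,
    n_blur_levels: int = 16,
) -> ZStack:
    """Render a focal stack from a ground-truth height map.

    Each plane at height ``z`` shows the speckle texture blurred with a
    Gaussian kernel of width ``defocus_slope * |z - h(x, y)|`` um (converted
    to pixels through the map's pitch), plus additive Gaussian noise of
    standard deviation ``noise_sd``.  Spatially varying blur is approximated
    by blurring at ``n_blur_levels`` quantised defocus distances and linearly
    interpolating per pixel; maps with few distinct heights are exact.
    """
    from scipy.ndimage import gaussian_filter

    z = np.asarray(z_levels, dtype=np.float64)
    if z.ndim != 1 or z.size < 3:
        raise ValueError("z_levels must be a 1-D array with >= 3 planes")
    if not np.all(np.diff(z) > 0):
        raise ValueError("z_levels must be strictly increasing")
    h = hmap.heights
    if z[0] > h.min() or z[-1] < h.max():
        raise ValueError("z_levels must span the height range of the map")
    rng = np.random.default_rng(texture_seed)
    texture = _speckle_texture(h.shape, rng)

    frames = np.empty((z.size, *h.shape))
    for k, zk in enumerate(z):
        dist = np.abs(zk - h)
        levels = np.unique(dist)
        if levels.size > n_blur_levels:
            levels = np.linspace(levels.min(), levels.max(), n_blur_levels)
        blurred = np.stack(
            [
                gaussian_filter(texture, defocus_slope * d / hmap.pixel_pitch,
                                mode="wrap")
                if d > 0
                else texture
                for d in levels
            ]
        )
        if levels.size == 1:
            frame = blurred[0]
        else:
            idx = np.clip(np.searchsorted(levels, dist) - 1, 0, levels.size - 2)
            span = levels[idx + 1] - levels[idx]
            w = np.where(span > 0, (dist - levels[idx]) / np.where(span > 0, span, 1.0),
                         0.0)
            rows = np.arange(h.shape[0])[:, None]
            cols = np.arange(h.shape[1])[None, :]
            frame = (1 - w) * blurred[idx, rows, cols] + w * blurred[idx + 1, rows, cols]
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
        frames[k] = frame
    return ZStack(frames=frames, z_positions=z, pixel_pitch=hmap.pixel_pitch)


def gen_disc_geometry(
    species: str,
    individual_ids,
    mean_diameter_um: float = 250.0,
    cv: float = 0.1,
    seed: int | np.random.Generator = 0,
):
    """Per-individual representative disc diameters (lognormal around the mean).

    The 250 um default is back-solved from the measured conservative shear
    stress and peak force of *H. lugubris* (six organs of ~49,000 um^2 each).
    Returns a DataFrame matching the geometry CSV interface.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    mu, sigma = _lognormal_params(mean_diameter_um, cv * mean_diameter_um)
    return pd.DataFrame(
        {
            "species": species,
            "individual_id": list(individual_ids),
            "disc_diameter_um": rng.lognormal(mu, sigma, size=len(individual_ids)),
        }
    )
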