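"""Surface metrology: roughness metrics and shape-from-focus reconstruction.

Two profilometry routes feed the roughness table for the test substrates:
white-light interferometry delivers a height map directly, while coarser
substrates are imaged as a focal Z-stack from which the height map is
reconstructed by locating, per pixel, the plane of maximal image sharpness
(shape-from-focus).  Either way the map is summarised by

* ``Ra`` — mean absolute height deviation,
* ``Rq`` — root-mean-square roughness,
* ``PV`` — maximum peak-to-valley height,

computed after detrending (best-fit plane removal by default, matching
interferometry practice).  ``Ra <= Rq <= PV`` always.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "HeightMap",
    "ZStack",
    "RoughnessSummary",
    "roughness_metrics",
    "shape_from_focus",
    "pattern_heightmap",
    "read_heightmap",
    "write_heightmap",
    "read_zstack",
    "write_zstack",
]


@dataclass
class HeightMap:
    """Gridded surface heights in um with lateral pixel pitch in um.

    ``mask`` marks valid pixels (True = valid); ``None`` means all valid.
    """

    heights: np.ndarray
    pixel_pitch: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D grid")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be > 0")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.heights.shape:
                raise ValueError("mask shape must match heights")
        valid = self.heights if self.mask is None else self.heights[self.mask]
        if valid.size and not np.isfinite(valid).all():
            raise ValueError("heights must be finite on valid pixels")

    @property
    def valid_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.ones_like(self.heights, dtype=bool)
        return self.mask

    @property
    def scan_area_um(self) -> tuple[float, float]:
        ny, nx = self.heights.shape
        return (ny * self.pixel_pitch, nx * self.pixel_pitch)


@dataclass
class ZStack:
    """Focal image stack: frames at strictly increasing z positions (um)."""

    frames: np.ndarray
    z_positions: np.ndarray
    pixel_pitch: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.z_positions = np.asarray(self.z_positions, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if self.frames.shape[0] != self.z_positions.size:
            raise ValueError("one z position per frame required")
        if self.frames.shape[0] < 3:
            raise ValueError("a Z-stack needs at least 3 planes")
        if not np.all(np.diff(self.z_positions) > 0):
            raise ValueError("z_positions must be strictly increasing")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be > 0")


@dataclass(frozen=True)
class RoughnessSummary:
    """Roughness metrics in um plus the physical scan area in um x um."""

    ra: float
    rq: float
    pv: float
    scan_area_um: tuple[float, float]


def _detrend(heights: np.ndarray, mask: np.ndarray, mode: str) -> np.ndarray:
    if mode == "none":
        return heights
    if mode == "mean":
        return heights - heights[mask].mean()
    if mode == "plane":
        ny, nx = heights.shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        a = np.column_stack(
            [xx[mask].ravel(), yy[mask].ravel(), np.ones(mask.sum())]
        )
        coef, *_ = np.linalg.lstsq(a, heights[mask].ravel(), rcond=None)
        return heights - (coef[0] * xx + coef[1] * yy + coef[2])
    raise ValueError(f"unknown detrend mode {mode!r}")


def roughness_metrics(hmap: HeightMap, detrend: str = "plane") -> RoughnessSummary:
    """Compute Ra, Rq and PV of a height map after detrending.

    ``detrend`` is one of ``none`` (use heights as-is), ``mean`` (subtract the
    mean level) or ``plane`` (remove the least-squares best-fit plane, the
    default).  Masked pixels are excluded from the fit and the statistics.
    """
    mask = hmap.valid_mask
    if mask.sum() < 4:
        raise ValueError("roughness_metrics needs at least 4 valid pixels")
    resid = _detrend(hmap.heights, mask, detrend)[mask]
    # Ra/Rq are deviations about the mean line of the retained surface; after
    # mean/plane removal this is a round-off guard, for "none" it makes the
    # metrics offset-invariant as roughness definitions require
    dev = resid - resid.mean()
    ra = float(np.abs(dev).mean())
    rq = float(np.sqrt((dev**2).mean()))
    pv = float(resid.max() - resid.min())
    return RoughnessSummary(ra=ra, rq=rq, pv=pv, scan_area_um=hmap.scan_area_um)


def _focus_measure(frame: np.ndarray, window: int) -> np.ndarray:
    """Local variance of a 3x3 Laplacian response (classic sharpness measure)."""
    hp = ndimage.laplace(frame, mode="nearest")
    mean = ndimage.uniform_filter(hp, size=window, mode="nearest")
    meansq = ndimage.uniform_filter(hp * hp, size=window, mode="nearest")
    return np.maximum(meansq - mean * mean, 0.0)


def shape_from_focus(
    stack: ZStack,
    window: int = 9,
    contrast_rel_threshold: float = 1e-3,
) -> HeightMap:
    """Reconstruct a height map from a focal stack.

    Per pixel, the sharpness (local variance of a Laplacian high-pass response
    over a ``window`` x ``window`` neighbourhood) is evaluated in every plane;
    the height is the z of the sharpest plane, refined by fitting a parabola
    through the focus measure at the argmax and its two neighbours.  Pixels
    whose best focus response is below ``contrast_rel_threshold`` times the
    global maximum are masked as textureless.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    n, ny, nx = stack.frames.shape
    fm = np.empty((n, ny, nx))
    for k in range(n):
        fm[k] = _focus_measure(stack.frames[k], window)

    best = np.argmax(fm, axis=0)
    peak = np.take_along_axis(fm, best[None], axis=0)[0]
    global_max = float(peak.max(initial=0.0))
    valid = peak > contrast_rel_threshold * global_max if global_max > 0 else np.zeros(
        (ny, nx), dtype=bool
    )

    z = stack.z_positions
    heights = z[best].astype(np.float64)
    # 3-point parabolic refinement around interior argmaxima (uniform z grid
    # not assumed: interpolate on the index axis, then map through z linearly)
    interior = (best > 0) & (best < n - 1) & valid
    if interior.any():
        iy, ix = np.nonzero(interior)
        k = best[iy, ix]
        f0, f1, f2 = fm[k - 1, iy, ix], fm[k, iy, ix], fm[k + 1, iy, ix]
        denom = f0 - 2 * f1 + f2
        delta = np.zeros_like(f1)
        ok = denom < 0
        delta[ok] = 0.5 * (f0[ok] - f2[ok]) / denom[ok]
        delta = np.clip(delta, -0.5, 0.5)
        z_lo = np.where(delta < 0, z[k - 1], z[k])
        z_hi = np.where(delta < 0, z[k], z[np.minimum(k + 1, n - 1)])
        frac = np.where(delta < 0, 1.0 + delta, delta)
        heights[iy, ix] = z_lo + frac * (z_hi - z_lo)

    heights[~valid] = 0.0
    return HeightMap(heights=heights, pixel_pitch=stack.pixel_pitch, mask=valid)


def pattern_heightmap(
    ridge_w: float,
    groove_w: float,
    depth: float,
    pitch: float,
    shape: tuple[int, int],
) -> HeightMap:
    """Ideal periodic ridge-and-groove surface (photolithography target).

    Columns alternate between ridge level (``depth``) and groove level (0)
    with period ``ridge_w + groove_w`` um along x.  The pixel pitch must
    resolve both features with at least 2 pixels.
    """
    if min(ridge_w, groove_w, depth, pitch) <= 0:
        raise ValueError("all pattern dimensions must be > 0")
    if ridge_w / pitch < 2 or groove_w / pitch < 2:
        raise ValueError("pixel pitch too coarse: need >= 2 px per feature")
    ny, nx = shape
    x = (np.arange(nx) + 0.5) * pitch
    phase = np.mod(x, ridge_w + groove_w)
    profile = np.where(phase < ridge_w, depth, 0.0)
    return HeightMap(heights=np.tile(profile, (ny, 1)), pixel_pitch=pitch)


# ---------------------------------------------------------------------------
# File formats: 32-bit float TIFF (um) or CSV matrix, with a JSON sidecar
# holding the lateral pixel pitch; Z-stacks as multi-page TIFF + JSON z list.
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_heightmap(hmap: HeightMap, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, hmap.heights.astype(np.float32))
    else:
        np.savetxt(path, hmap.heights, delimiter=",", fmt="%.8g")
    meta = {"pixel_pitch_um": hmap.pixel_pitch}
    if hmap.mask is not None:
        meta["mask"] = hmap.mask.astype(int).tolist()
    _sidecar(path).write_text(json.dumps(meta))


def read_heightmap(path: str | Path) -> HeightMap:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        heights = tifffile.imread(path).astype(np.float64)
    else:
        heights = np.atleast_2d(np.loadtxt(path, delimiter=","))
    meta = json.loads(_sidecar(path).read_text())
    mask = np.array(meta["mask"], dtype=bool) if "mask" in meta else None
    return HeightMap(heights=heights, pixel_pitch=float(meta["pixel_pitch_um"]),
                     mask=mask)


def write_zstack(stack: ZStack, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32),
                     photometric="minisblack")
    _sidecar(path).write_text(
        json.dumps(
            {
                "z_positions_um": stack.z_positions.tolist(),
                "pixel_pitch_um": stack.pixel_pitch,
            }
        )
    )


def read_zstack(path: str | Path) -> ZStack:
    path = Path(path)
    frames = tifffile.imread(path).astype(np.float64)
    meta = json.loads(_sidecar(path).read_text())
    return ZStack(
        frames=frames,
        z_positions=np.array(meta["z_positions_um"], dtype=np.float64),
        pixel_pitch=float(meta["pixel_pitch_um"]),
    )
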