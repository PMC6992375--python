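"""Physics-based synthetic IRM image generator.

Every downstream stage of the pipeline (correction, fringe analysis, cell
topography, tracking) is verified against images rendered here from known
ground truth, because IRM studies deposit no raw image data. Two specimen
families are emulated:

* a planoconvex calibration lens resting on the cover glass in air, whose
  gap height follows ``z(x) = R - sqrt(R**2 - x**2)`` and which produces
  concentric Newton's-rings-like fringes; and
* rod-shaped gliding bacteria (~5 μm × ~0.5 μm, *M. xanthus*-like) in
  aqueous medium (n = 1.33), with basal gap heights 0–200 nm, imaged at
  488 nm and 635 nm, gliding at ~9–16 μm/min with aperiodic height
  fluctuations.

Rendering applies the three-layer interference law per pixel, convolves with
a diffraction-limited Gaussian blur, multiplies by a smooth low-frequency
background field, and adds Gaussian detector noise. All randomness flows
from one explicit seed; equal seeds give bit-identical stacks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .frames import IRMFrame
from .optics import OpticalConfig, interference_intensity

__all__ = [
    "HeightMap",
    "LensGeometry",
    "CellSpec",
    "CellScene",
    "lens_height_map",
    "basal_profile",
    "cell_height_map",
    "render_irm",
    "gliding_movie",
    "GlidingMovie",
    "lens_optical_config",
    "cell_optical_config",
]

#: Default lateral sampling for cell scenes (μm/pixel); the line-profile
#: averaging width of 3 pixels then spans 0.3 μm across a 0.5-μm-wide cell.
CELL_PIXEL_SIZE = 0.1
#: Default lateral sampling for the lens specimen (μm/pixel).
LENS_PIXEL_SIZE = 0.84
#: Numerical apertures used for the diffraction blur of each specimen type.
CELL_NA = 1.35
LENS_NA = 0.3


def lens_optical_config(wavelengths=(488.0,), gap_index: float = 1.0,
                        n_lens: float = 1.515) -> OpticalConfig:
    """Optical config for the lens-on-glass specimen: the thin film is the
    air gap (default n = 1) between cover glass and lens glass."""
    return OpticalConfig(n_glass=1.515, n_medium=gap_index, n_cell=n_lens,
                         wavelengths=tuple(wavelengths))


def cell_optical_config(wavelengths=(488.0, 635.0)) -> OpticalConfig:
    """Optical config for bacteria in aqueous medium on glass."""
    return OpticalConfig(wavelengths=tuple(wavelengths))


@dataclass
class HeightMap:
    """Per-pixel cover-glass-to-specimen gap height.

    heights are in nm (>= 0); ``mask`` marks specimen pixels — where it is
    False only the glass–medium reflection contributes.
    """

    heights: np.ndarray
    pixel_size: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be 2D")
        if np.any(self.heights < 0):
            raise ValueError("gap heights must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.mask is None:
            self.mask = np.ones(self.heights.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.heights.shape:
                raise ValueError("mask shape must match heights")


@dataclass(frozen=True)
class LensGeometry:
    """Planoconvex lens resting convex-side-down on the cover glass."""

    radius_of_curvature: float        # mm
    center: tuple[float, float] = (0.0, 0.0)   # μm, in image coordinates
    aperture: float | None = None     # diameter, mm; defaults to 2R
    gap_index: float = 1.0            # refractive index of the gap (air)

    def __post_init__(self) -> None:
        if self.radius_of_curvature <= 0:
            raise ValueError("radius_of_curvature must be > 0")
        ap = self.aperture if self.aperture is not None else 2 * self.radius_of_curvature
        if ap > 2 * self.radius_of_curvature:
            raise ValueError("aperture cannot exceed the lens diameter 2R")
        object.__setattr__(self, "aperture", ap)

    def height_nm(self, x_um):
        """Gap height z(x) = R - sqrt(R^2 - x^2) in nm at radial distance
        ``x_um`` (μm) from the contact point."""
        r_um = self.radius_of_curvature * 1000.0
        x = np.asarray(x_um, dtype=float)
        if np.any(x > r_um):
            raise ValueError("radial distance exceeds the lens radius R")
        return (r_um - np.sqrt(r_um ** 2 - x ** 2)) * 1000.0


def lens_height_map(geom: LensGeometry, extent: float, pixel_size: float) -> HeightMap:
    """Render the lens gap-height field over a square ``extent`` × ``extent``
    μm window centred on ``geom.center``.

    The profile is exactly 0 at the contact point and monotone increasing in
    radial distance.
    """
    if extent / 2 > geom.aperture * 1000.0 / 2:
        raise ValueError(
            f"extent {extent} μm exceeds the lens aperture {geom.aperture} mm"
        )
    n = int(round(extent / pixel_size))
    ii, jj = np.mgrid[0:n, 0:n]
    # contact point sits at the window centre offset by geom.center
    x = jj * pixel_size - (extent / 2 + geom.center[0])
    y = ii * pixel_size - (extent / 2 + geom.center[1])
    r = np.hypot(x, y)
    heights = geom.height_nm(r)
    return HeightMap(heights, pixel_size)


# ---------------------------------------------------------------------------
# cell scenes
# ---------------------------------------------------------------------------

PROFILE_KINDS = ("adhered", "single_lift", "undulating", "pole_tilt")

#: Bound (nm) on basal lift/undulation parameters and on the fluctuation
#: random walk; gliding cells stay within a couple of fringe orders of glass.
MAX_LIFT_NM = 200.0


@dataclass
class CellSpec:
    """One rod-shaped cell: centerline, width and basal height profile.

    ``centerline`` is a polyline in μm, leading pole first. ``profile``
    selects the basal shape; ``params`` carries its parameters in nm (or
    degrees for ``pole_tilt``):

    * ``adhered`` — fully attached, z = 0 everywhere;
    * ``single_lift`` — attached at the leading pole, linear ramp to
      ``lift_nm`` (default 180) at the lagging pole;
    * ``undulating`` — attached at the leading pole, rising to ``high_nm``
      (180), dipping to ``low_nm`` (90), rising again to ``high_nm``;
    * ``pole_tilt`` — attached at the leading pole, body projecting upward
      at ``angle_deg`` (default 60) into the medium.
    """

    centerline: np.ndarray
    width: float = 0.5
    profile: str = "adhered"
    params: dict = field(default_factory=dict)
    velocity: float = 0.0         # μm/min along the centerline direction
    cell_id: int = 0

    def __post_init__(self) -> None:
        self.centerline = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        if self.centerline.shape[0] < 2 or self.centerline.shape[1] != 2:
            raise ValueError("centerline must be an (n>=2, 2) polyline in μm")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.profile not in PROFILE_KINDS:
            raise ValueError(f"profile must be one of {PROFILE_KINDS}, got {self.profile!r}")
        for key in ("lift_nm", "high_nm", "low_nm"):
            v = self.params.get(key)
            if v is not None and not (0.0 <= v <= 500.0):
                raise ValueError(f"{key}={v} outside the plausible [0, 500] nm band")
        ang = self.params.get("angle_deg")
        if ang is not None and not (0.0 < ang <= 90.0):
            raise ValueError("pole_tilt angle must be in (0, 90] degrees")

    @property
    def length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.centerline, axis=0).T)))


@dataclass
class CellScene:
    """A set of cells plus acquisition timing and the height-fluctuation
    process (a reflected Gaussian random walk on the lift parameters)."""

    cells: list
    frame_interval: float = 10.0       # s
    fluctuation_step: float = 20.0     # nm per frame, sd of the random walk

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.fluctuation_step < 0:
            raise ValueError("fluctuation_step must be >= 0")


def basal_profile(kind: str, u, length_um: float, params: dict | None = None):
    """Basal gap height (nm) at normalised arclength ``u`` ∈ [0, 1] from the
    leading pole, for each profile kind (see :class:`CellSpec`)."""
    params = params or {}
    u = np.asarray(u, dtype=float)
    if kind == "adhered":
        return np.zeros_like(u)
    if kind == "single_lift":
        return u * params.get("lift_nm", 180.0)
    if kind == "undulating":
        high = params.get("high_nm", 180.0)
        low = params.get("low_nm", 90.0)
        return np.interp(u, [0.0, 1 / 3, 2 / 3, 1.0], [0.0, high, low, high])
    if kind == "pole_tilt":
        angle = math.radians(params.get("angle_deg", 60.0))
        return u * length_um * 1000.0 * math.tan(angle)
    raise ValueError(f"unknown profile kind {kind!r}")


def _rasterize_cell(cell: CellSpec, shape, pixel_size):
    """Footprint mask and per-pixel heights of one cell.

    Returns (mask, heights) on the full image grid; pixels within width/2 of
    the centerline belong to the cell and carry the basal profile evaluated
    at the arclength of their centerline projection.
    """
    h, w = shape
    pts = cell.centerline
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    half = cell.width / 2.0

    xmin = max(int((pts[:, 0].min() - half) / pixel_size) - 1, 0)
    xmax = min(int((pts[:, 0].max() + half) / pixel_size) + 2, w)
    ymin = max(int((pts[:, 1].min() - half) / pixel_size) - 1, 0)
    ymax = min(int((pts[:, 1].max() + half) / pixel_size) + 2, h)
    mask = np.zeros(shape, dtype=bool)
    heights = np.zeros(shape, dtype=float)
    if xmin >= xmax or ymin >= ymax or total == 0:
        return mask, heights

    ii, jj = np.mgrid[ymin:ymax, xmin:xmax]
    px = jj * pixel_size
    py = ii * pixel_size
    best_d = np.full(px.shape, np.inf)
    best_s = np.zeros(px.shape)
    for k in range(len(seg)):
        if seg_len[k] == 0:
            continue
        dx = px - pts[k, 0]
        dy = py - pts[k, 1]
        t = np.clip((dx * seg[k, 0] + dy * seg[k, 1]) / seg_len[k] ** 2, 0.0, 1.0)
        d = np.hypot(dx - t * seg[k, 0], dy - t * seg[k, 1])
        closer = d < best_d
        best_d = np.where(closer, d, best_d)
        best_s = np.where(closer, cum[k] + t * seg_len[k], best_s)
    inside = best_d <= half
    u = best_s / total
    z = basal_profile(cell.profile, u, total, cell.params)
    mask[ymin:ymax, xmin:xmax] = inside
    heights[ymin:ymax, xmin:xmax] = np.where(inside, z, 0.0)
    return mask, heights


def cell_height_map(scene: CellScene, shape, pixel_size: float = CELL_PIXEL_SIZE) -> HeightMap:
    """Rasterize a :class:`CellScene` into a gap-height map.

    Overlapping cells are resolved last-cell-wins with a warning; off-cell
    pixels are masked out (pure glass–medium reflection).
    """
    mask = np.zeros(shape, dtype=bool)
    heights = np.zeros(shape, dtype=float)
    for cell in scene.cells:
        m, z = _rasterize_cell(cell, shape, pixel_size)
        overlap = mask & m
        if overlap.any():
            warnings.warn(
                f"cell {cell.cell_id} overlaps an earlier cell on "
                f"{int(overlap.sum())} pixels; later cell wins",
                stacklevel=2,
            )
        heights[m] = z[m]
        mask |= m
    return HeightMap(heights, pixel_size, mask)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _background_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative background: 1 + amplitude × a normalised sum of
    2–4 low-order 2D cosine terms."""
    if amplitude == 0:
        return np.ones(shape)
    h, w = shape
    ii, jj = np.mgrid[0:h, 0:w]
    n_terms = int(rng.integers(2, 5))
    s = np.zeros(shape)
    for _ in range(n_terms):
        fy, fx = rng.integers(0, 3, size=2)
        if fx == 0 and fy == 0:
            fx = 1
        a = rng.uniform(0.5, 1.0)
        phase = rng.uniform(0, 2 * math.pi)
        s += a * np.cos(2 * math.pi * (fx * jj / w + fy * ii / h) + phase)
    s /= np.max(np.abs(s))
    return 1.0 + amplitude * s


def render_irm(
    hm: HeightMap,
    cfg: OpticalConfig,
    background_amplitude: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    na: float | None = None,
    timestamp: float = 0.0,
) -> IRMFrame:
    """Render a height map into a multiwavelength IRM frame.

    Per channel, specimen pixels carry the two-beam interference intensity at
    their gap height and background pixels the bare glass–medium reflectance.
    If ``na`` is given, channels are blurred with a diffraction-limited
    Gaussian (FWHM = 0.51 λ/NA). The image is then multiplied by a smooth
    background field of relative amplitude ``background_amplitude`` and
    perturbed by zero-mean Gaussian noise with sd ``noise_sd`` × the channel
    dynamic range. Fixed seeds give bit-identical output.
    """
    if not (0.0 <= background_amplitude < 1.0) or not (0.0 <= noise_sd < 1.0):
        raise ValueError("background_amplitude and noise_sd must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    i_gm = cfg.i_glass_medium
    channels = []
    bg = _background_field(hm.heights.shape, background_amplitude, rng)
    for lam in cfg.wavelengths:
        img = np.full(hm.heights.shape, i_gm)
        img[hm.mask] = interference_intensity(hm.heights[hm.mask], lam, cfg)
        if na is not None:
            fwhm_um = 0.51 * (lam / 1000.0) / na
            sigma_px = fwhm_um / 2.35482 / hm.pixel_size
            img = gaussian_filter(img, sigma_px, mode="nearest")
        img = img * bg
        if noise_sd > 0:
            dyn = float(img.max() - img.min())
            img = img + rng.normal(0.0, noise_sd * dyn, img.shape)
        channels.append(np.clip(img, 0.0, None))
    return IRMFrame(np.stack(channels), cfg.wavelengths, hm.pixel_size, timestamp)


# ---------------------------------------------------------------------------
# gliding movies
# ---------------------------------------------------------------------------

@dataclass
class GlidingMovie:
    """Rendered time series plus its ground truth.

    ``truth`` has one row per cell per frame: frame, time_s, cell_id,
    centroid_x_um, centroid_y_um, lift_nm (current value of the fluctuating
    lift parameter) and velocity_um_per_min. ``polylines`` maps frame index
    to {cell_id: centerline} for profile extraction without segmentation.
    """

    frames: list
    truth: pd.DataFrame
    polylines: list

    def write(self, stack_path: str, truth_path: str) -> None:
        from .frames import write_stack
        write_stack(self.frames, stack_path)
        self.truth.to_csv(truth_path, index=False)


def _reflect(value: float, lo: float, hi: float) -> float:
    """Fold ``value`` back into [lo, hi] (reflecting random walk)."""
    span = hi - lo
    v = (value - lo) % (2 * span)
    return lo + (span - abs(v - span))


def _centerline_midpoint(pts: np.ndarray) -> np.ndarray:
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    half = cum[-1] / 2
    k = int(np.searchsorted(cum, half, side="right")) - 1
    k = min(k, len(seg) - 1)
    t = (half - cum[k]) / seg_len[k] if seg_len[k] else 0.0
    return pts[k] + t * seg[k]


def gliding_movie(
    scene: CellScene,
    n_frames: int,
    cfg: OpticalConfig,
    seed: int = 0,
    shape: tuple[int, int] = (150, 150),
    pixel_size: float = CELL_PIXEL_SIZE,
    background_amplitude: float = 0.0,
    noise_sd: float = 0.0,
    na: float | None = CELL_NA,
) -> GlidingMovie:
    """Simulate a gliding time series.

    Each cell translates along its centerline direction at its velocity;
    lift/undulation parameters evolve by a seeded Gaussian random walk
    reflected into [0, 200] nm. Ground-truth centroids and lift heights per
    frame are returned alongside the rendered frames.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    frames, rows, polylines = [], [], []
    lifts = {}
    for cell in scene.cells:
        if cell.profile == "single_lift":
            lifts[cell.cell_id] = cell.params.get("lift_nm", 180.0)
        elif cell.profile == "undulating":
            lifts[cell.cell_id] = cell.params.get("high_nm", 180.0)
    for f in range(n_frames):
        t = f * scene.frame_interval
        moved = []
        frame_lines = {}
        for cell in scene.cells:
            pts = cell.centerline
            direction = pts[-1] - pts[0]
            norm = np.hypot(*direction)
            step = (direction / norm) * cell.velocity / 60.0 * t if norm else 0.0
            new_pts = pts + step
            params = dict(cell.params)
            if cell.cell_id in lifts:
                key = "lift_nm" if cell.profile == "single_lift" else "high_nm"
                params[key] = lifts[cell.cell_id]
            moved.append(replace(cell, centerline=new_pts, params=params))
            frame_lines[cell.cell_id] = new_pts
            cx, cy = _centerline_midpoint(new_pts)
            rows.append({
                "frame": f, "time_s": t, "cell_id": cell.cell_id,
                "centroid_x_um": cx, "centroid_y_um": cy,
                "lift_nm": lifts.get(cell.cell_id, 0.0),
                "velocity_um_per_min": cell.velocity,
            })
        hm = cell_height_map(CellScene(moved, scene.frame_interval,
                                       scene.fluctuation_step), shape, pixel_size)
        frame_seed = int(rng.integers(0, 2 ** 31 - 1))
        frames.append(render_irm(hm, cfg, background_amplitude, noise_sd,
                                 seed=frame_seed, na=na, timestamp=t))
        polylines.append(frame_lines)
        for cid in lifts:
            lifts[cid] = _reflect(lifts[cid] + rng.normal(0.0, scene.fluctuation_step),
                                  0.0, MAX_LIFT_NM)
    return GlidingMovie(frames, pd.DataFrame(rows), polylines)
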