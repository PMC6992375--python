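"""Radial fringe analysis and 3D reconstruction of the calibration lens.

A planoconvex lens on the cover glass produces concentric interference
fringes. Azimuthally averaging the image around the contact point gives a
radial intensity profile whose maxima are the constructive orders. Mapping
peak radii to heights through the known lens sag ``z(x) = R - sqrt(R² - x²)``
yields the experimental axial fringe spacing, which theory predicts to be
λ/(2 n_gap) between consecutive same-kind fringes. The same geometric prior
assigns every pixel a height, giving a 3D point-cloud reconstruction of the
lens from a single 2D image.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .frames import IRMFrame
from .optics import constructive_height
from .simulate import LensGeometry

__all__ = [
    "RadialProfile",
    "FringePeak",
    "FringeSet",
    "estimate_center",
    "radial_profile",
    "detect_fringe_peaks",
    "spacing_from_peaks",
    "percent_deviation",
    "reconstruct_lens",
]

logger = logging.getLogger(__name__)

#: Peaks within this many bins of either profile edge are discarded.
EDGE_MARGIN_BINS = 2


@dataclass
class RadialProfile:
    """Azimuthally averaged intensity vs radius, one trace per wavelength."""

    radii: np.ndarray                       # μm, strictly increasing
    intensities: dict                       # wavelength (nm) -> intensity array
    center: tuple[float, float]             # pixel coordinates (col, row)
    pixel_size: float

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        for lam, trace in self.intensities.items():
            if len(trace) != len(self.radii):
                raise ValueError(f"intensity trace for {lam} nm does not match radii")


@dataclass(frozen=True)
class FringePeak:
    radius: float          # μm
    order: int             # N = 0, 1, 2, ... outward from the contact point
    height: float          # nm, theoretical constructive ladder (N + 1/2)λ/2n


@dataclass
class FringeSet:
    """Detected constructive fringes per channel, plus the estimated axial
    spacing once :func:`spacing_from_peaks` has run."""

    peaks: dict                             # wavelength -> list[FringePeak]
    spacing: dict = field(default_factory=dict)   # wavelength -> (mean nm, sd nm)


def estimate_center(frame: IRMFrame) -> tuple[float, float]:
    """Estimate the lens contact point as the intensity-weighted centroid of
    the darkest disc (the contact point is a destructive minimum)."""
    img = frame.data[0]
    lo, hi = float(img.min()), float(img.max())
    sel = img <= lo + 0.1 * (hi - lo)
    weights = (hi - img)[sel]
    rows, cols = np.nonzero(sel)
    return (float(np.average(cols, weights=weights)),
            float(np.average(rows, weights=weights)))


def radial_profile(frame: IRMFrame, center: tuple[float, float] | None = None) -> RadialProfile:
    """Azimuthal mean intensity in 1-pixel-wide annuli around ``center``.

    ``center`` is in pixel coordinates (col, row); when omitted it is
    estimated from the dark contact disc. Radii are reported in μm at annulus
    centres.
    """
    if center is None:
        center = estimate_center(frame)
    h, w = frame.shape
    if not (0 <= center[0] < w and 0 <= center[1] < h):
        raise ValueError(f"center {center} lies outside the {h}x{w} image")
    ii, jj = np.mgrid[0:h, 0:w]
    r = np.hypot(jj - center[0], ii - center[1])
    bins = r.astype(int).ravel()
    n_bins = bins.max() + 1
    counts = np.bincount(bins, minlength=n_bins)
    intensities = {}
    for lam in frame.wavelengths:
        sums = np.bincount(bins, weights=frame.channel(lam).ravel(), minlength=n_bins)
        with np.errstate(invalid="ignore"):
            intensities[lam] = sums / counts
    radii = (np.arange(n_bins) + 0.5) * frame.pixel_size
    keep = counts > 0
    return RadialProfile(radii[keep],
                         {lam: tr[keep] for lam, tr in intensities.items()},
                         center, frame.pixel_size)


def _parabolic_refine(x: np.ndarray, y: np.ndarray, idx: int) -> float:
    """Sub-bin peak position by fitting a parabola through three samples."""
    if idx <= 0 or idx >= len(y) - 1:
        return float(x[idx])
    y0, y1, y2 = y[idx - 1], y[idx], y[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[idx])
    shift = 0.5 * (y0 - y2) / denom
    step = x[idx + 1] - x[idx] if shift >= 0 else x[idx] - x[idx - 1]
    return float(x[idx] + np.clip(shift, -0.5, 0.5) * step)


def detect_fringe_peaks(profile: RadialProfile, min_prominence: float = 0.1,
                        gap_index: float = 1.0) -> FringeSet:
    """Locate constructive-fringe maxima in each channel of a radial profile.

    Peaks must have prominence >= ``min_prominence`` × the channel's dynamic
    range; peaks within two bins of either edge are discarded; surviving
    peaks are assigned consecutive orders N = 0, 1, 2, ... outward and the
    theoretical ladder height (N + 1/2) λ/(2 gap_index). Positions are
    refined to sub-bin precision with a parabolic fit.
    """
    if len(profile.radii) < 3:
        raise ValueError("profile needs at least 3 samples")
    peaks = {}
    for lam, trace in profile.intensities.items():
        dyn = float(np.nanmax(trace) - np.nanmin(trace))
        idx, _ = find_peaks(trace, prominence=min_prominence * dyn if dyn > 0 else None)
        idx = idx[(idx >= EDGE_MARGIN_BINS) & (idx < len(trace) - EDGE_MARGIN_BINS)]
        chan = [
            FringePeak(
                radius=_parabolic_refine(profile.radii, trace, i),
                order=n,
                height=constructive_height(n, gap_index, lam),
            )
            for n, i in enumerate(idx)
        ]
        if not chan:
            warnings.warn(f"no fringe peaks found in the {lam} nm channel", stacklevel=2)
        peaks[lam] = chan
    return FringeSet(peaks)


def spacing_from_peaks(fs: FringeSet, geom: LensGeometry) -> FringeSet:
    """Experimental axial fringe spacing from peak radii and lens geometry.

    Each peak radius x maps to a height z(x) = R - sqrt(R² - x²); consecutive
    constructive fringes are subtracted from their neighbours and the mean
    and sd of the differences stored per channel. Requires >= 2 peaks.
    """
    for lam, chan in fs.peaks.items():
        if len(chan) < 2:
            raise ValueError(
                f"channel {lam} nm has {len(chan)} peak(s); >= 2 needed for a spacing"
            )
        z = geom.height_nm(np.array([p.radius for p in chan]))
        diffs = np.diff(z)
        fs.spacing[lam] = (float(diffs.mean()), float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0)
    return fs


def percent_deviation(experimental: float, theoretical: float) -> float:
    """Percent deviation 100·|exp − theory|/theory of a measured spacing."""
    if theoretical <= 0:
        raise ValueError("theoretical spacing must be > 0")
    return 100.0 * abs(experimental - theoretical) / theoretical


def reconstruct_lens(frame: IRMFrame, geom: LensGeometry,
                     center: tuple[float, float] | None = None) -> pd.DataFrame:
    """Assign every pixel its geometric height for 3D rendering.

    Returns a point cloud DataFrame with columns x_um, y_um, z_nm and one
    intensity column per channel (``I_<nm>``). Pixels beyond the lens
    aperture radius are excluded and their count logged.
    """
    if center is None:
        center = estimate_center(frame)
    h, w = frame.shape
    ii, jj = np.mgrid[0:h, 0:w]
    x_um = (jj - center[0]) * frame.pixel_size
    y_um = (ii - center[1]) * frame.pixel_size
    r = np.hypot(x_um, y_um)
    keep = r <= geom.aperture * 1000.0 / 2
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluded %d pixels beyond the lens aperture", n_excluded)
    cols = {
        "x_um": x_um[keep].ravel(),
        "y_um": y_um[keep].ravel(),
        "z_nm": geom.height_nm(r[keep].ravel()),
    }
    for lam in frame.wavelengths:
        cols[f"I_{int(round(lam))}"] = frame.channel(lam)[keep].ravel()
    return pd.DataFrame(cols)
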