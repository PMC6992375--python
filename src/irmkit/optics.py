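"""Three-layer thin-film image-formation model for interference reflection
microscopy (IRM).

The model treats the sample as a stack of three media — cover glass (g),
aqueous medium (m) and cell body (c) — with the medium acting as a thin film
of variable thickness ``z`` (the gap between the glass and the basal cell
surface). Light reflected at the glass–medium and medium–cell interfaces
interferes; at normal incidence the detected intensity is

    I(z) = I_gm + I_mc + 2*sqrt(I_gm * I_mc) * cos(4*pi*n_m*z/lambda + delta)

where the interface reflectances follow the Fresnel normal-incidence formula
``I_r = I_0 ((n1 - n2)/(n1 + n2))**2``. Because the cell is optically denser
than the medium, the reflection at the medium–cell interface carries a phase
shift ``delta = pi``, so destructive fringes sit at ``z = N * lambda/(2 n_m)``
and constructive fringes at ``z = (N + 1/2) * lambda/(2 n_m)`` for integer
order ``N >= 0``. Inverting that ladder — fringe order to height — is what
turns a 2D fringe image into basal topography.

Heights are in nanometres, wavelengths are vacuum wavelengths in nanometres,
intensities in arbitrary units.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np

__all__ = [
    "OpticalConfig",
    "FringeOrder",
    "fresnel_reflectance",
    "interference_intensity",
    "constructive_height",
    "destructive_height",
    "fringe_spacing",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Optical constants of the three-layer IRM system.

    Parameters
    ----------
    n_glass, n_medium, n_cell : float
        Refractive indices of cover glass, gap medium and specimen. The
        default medium index 1.33 is that of the aqueous growth medium; the
        cell index only scales fringe contrast, never fringe positions, so a
        mid-range bacterial value of 1.38 is used.
    wavelengths : tuple of float
        Vacuum illumination wavelengths in nm, one per acquisition channel.
    incident_intensity : float
        Illumination intensity I0 (arbitrary units).
    phase_shift : float
        Reflection phase shift delta in radians. Must be pi whenever
        ``n_cell > n_medium`` (reflection off a denser medium).
    """

    n_glass: float = 1.515
    n_medium: float = 1.33
    n_cell: float = 1.38
    wavelengths: tuple[float, ...] = (488.0, 635.0)
    incident_intensity: float = 1.0
    phase_shift: float = math.pi

    def __post_init__(self) -> None:
        for name in ("n_glass", "n_medium", "n_cell"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        object.__setattr__(self, "wavelengths", tuple(float(w) for w in self.wavelengths))
        if not self.wavelengths or any(w <= 0 for w in self.wavelengths):
            raise ValueError("wavelengths must be a non-empty sequence of positive nm values")
        if self.incident_intensity <= 0:
            raise ValueError("incident_intensity must be > 0")
        if self.n_cell > self.n_medium and not math.isclose(self.phase_shift, math.pi, rel_tol=0, abs_tol=1e-9):
            raise ValueError(
                "phase_shift must equal pi when n_cell > n_medium "
                "(reflection off the denser medium)"
            )

    # -- reflectances of the two interfaces ---------------------------------
    @property
    def i_glass_medium(self) -> float:
        """Reflected intensity at the glass-medium interface."""
        return fresnel_reflectance(self.n_glass, self.n_medium, self.incident_intensity)

    @property
    def i_medium_cell(self) -> float:
        """Reflected intensity at the medium-cell interface."""
        return fresnel_reflectance(self.n_medium, self.n_cell, self.incident_intensity)

    # -- plain-text serialisation -------------------------------------------
    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "OpticalConfig":
        """Load from a JSON string or a path to a JSON file."""
        text = str(source)
        if not text.lstrip().startswith("{"):
            with open(source) as fh:
                text = fh.read()
        data = json.loads(text)
        data["wavelengths"] = tuple(data["wavelengths"])
        return cls(**data)


@dataclass(frozen=True)
class FringeOrder:
    """One interference fringe: order N, kind, and acquisition wavelength."""

    order: int
    kind: Literal["constructive", "destructive"]
    wavelength: float

    def __post_init__(self) -> None:
        if self.order < 0 or int(self.order) != self.order:
            raise ValueError(f"order must be a non-negative integer, got {self.order}")
        if self.kind not in ("constructive", "destructive"):
            raise ValueError(f"kind must be 'constructive' or 'destructive', got {self.kind!r}")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")


def fresnel_reflectance(n1: float, n2: float, incident: float = 1.0) -> float:
    """Normal-incidence Fresnel reflected intensity at an n1/n2 interface.

    Returns ``incident * ((n1 - n2)/(n1 + n2))**2``; symmetric in its index
    arguments and strictly less than ``incident``.
    """
    if n1 < 1.0 or n2 < 1.0:
        raise ValueError(f"refractive indices must be >= 1, got {n1}, {n2}")
    if incident <= 0:
        raise ValueError(f"incident intensity must be > 0, got {incident}")
    return incident * ((n1 - n2) / (n1 + n2)) ** 2


def interference_intensity(
    z,
    wavelength: float,
    cfg: OpticalConfig,
    i_gm: float | None = None,
    i_mc: float | None = None,
):
    """Two-beam interference intensity at gap height(s) ``z`` (nm).

    ``z`` may be a scalar or an array. The interface reflectances default to
    the Fresnel values implied by ``cfg`` but can be overridden (e.g. for a
    lens specimen where the upper medium is the lens glass).

    The result is bounded by ``(sqrt(I_gm) -/+ sqrt(I_mc))**2``.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("gap height z must be >= 0")
    if wavelength <= 0:
        raise ValueError("wavelength must be > 0")
    if i_gm is None:
        i_gm = cfg.i_glass_medium
    if i_mc is None:
        i_mc = cfg.i_medium_cell
    if i_gm < 0 or i_mc < 0:
        raise ValueError("interface intensities must be >= 0")
    phase = 4.0 * math.pi * cfg.n_medium * z / wavelength + cfg.phase_shift
    out = i_gm + i_mc + 2.0 * math.sqrt(i_gm * i_mc) * np.cos(phase)
    return float(out) if out.ndim == 0 else out


def _order_height(order: FringeOrder | int, n_medium: float, wavelength: float | None,
                  kind: str, offset: float) -> float:
    if isinstance(order, FringeOrder):
        if order.kind != kind:
            raise ValueError(f"expected a {kind} FringeOrder, got {order.kind}")
        n, lam = order.order, order.wavelength
    else:
        n = int(order)
        if n < 0:
            raise ValueError("order must be >= 0")
        if wavelength is None:
            raise ValueError("wavelength required when order is given as an integer")
        lam = wavelength
    if n_medium < 1.0:
        raise ValueError("n_medium must be >= 1")
    return (n + offset) * lam / (2.0 * n_medium)


def constructive_height(order: FringeOrder | int, n_medium: float,
                        wavelength: float | None = None) -> float:
    """Height z (nm) of the N-th constructive fringe: ``(N + 1/2) λ/(2 n_m)``.

    ``order`` is either a constructive :class:`FringeOrder` or a bare integer
    N with ``wavelength`` supplied separately.
    """
    return _order_height(order, n_medium, wavelength, "constructive", 0.5)


def destructive_height(order: FringeOrder | int, n_medium: float,
                       wavelength: float | None = None) -> float:
    """Height z (nm) of the N-th destructive fringe: ``N λ/(2 n_m)``."""
    return _order_height(order, n_medium, wavelength, "destructive", 0.0)


def fringe_spacing(wavelength: float, n: float) -> float:
    """Axial spacing λ/(2n) in nm between consecutive same-kind fringes."""
    if wavelength <= 0:
        raise ValueError("wavelength must be > 0")
    if n < 1.0:
        raise ValueError("refractive index must be >= 1")
    return wavelength / (2.0 * n)
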