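"""Geometric conversions from 2-D microscopy measurements to volumes.

Nuclei are approximated as spheres, cells as prolate ellipsoids. Two
area-to-volume conventions are supported for nuclei:

* ``corrected=False`` (default): ``V = 4/3 * (A/pi)**1.5``. This is the
  convention used for all relative (arbitrary-unit) concentration work in
  this package; it differs from the true sphere volume by a constant factor
  of pi, which cancels in every normalized quantity.
* ``corrected=True``: ``V = 4/3 * pi * (A/pi)**1.5``, the exact volume of a
  sphere whose maximal cross-section has area ``A``.

All lengths are in µm, areas in µm², volumes in µm³.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NucleusGeometry",
    "CellGeometry",
    "nuclear_volume_from_area",
    "nuclear_volume_from_diameter",
    "cell_volume_ellipsoid",
    "nc_ratio",
]


@dataclass(frozen=True)
class NucleusGeometry:
    """A nucleus summarized by projected area, diameter and volume (µm units)."""

    projected_area: float
    diameter: float
    volume: float

    def __post_init__(self) -> None:
        if self.projected_area < 0 or self.diameter < 0 or self.volume < 0:
            raise ValueError("NucleusGeometry fields must be non-negative")


@dataclass(frozen=True)
class CellGeometry:
    """An ellipsoidal cell body with major/minor axes and volume (µm units)."""

    major_axis: float
    minor_axis: float
    volume: float

    def __post_init__(self) -> None:
        if self.minor_axis < 0 or self.volume < 0:
            raise ValueError("CellGeometry fields must be non-negative")
        if self.major_axis < self.minor_axis:
            raise ValueError("major_axis must be >= minor_axis")


def nuclear_volume_from_area(area, corrected: bool = False):
    """Convert a projected nuclear area (µm²) to a nuclear volume (µm³).

    Parameters
    ----------
    area : float or array-like
        Projected (segmented) nuclear area, µm². Must be non-negative.
    corrected : bool
        If False (default), use ``4/3 * (A/pi)**1.5``; if True, include the
        sphere factor pi: ``4/3 * pi * (A/pi)**1.5``.
    """
    a = np.asarray(area, dtype=float)
    if np.any(a < 0):
        raise ValueError("area must be non-negative")
    v = (4.0 / 3.0) * (a / np.pi) ** 1.5
    if corrected:
        v = v * np.pi
    return v if v.ndim else float(v)


def nuclear_volume_from_diameter(d):
    """Sphere volume (µm³) from a measured diameter ``d`` (µm): ``pi*d**3/6``."""
    dd = np.asarray(d, dtype=float)
    if np.any(dd < 0):
        raise ValueError("diameter must be non-negative")
    v = np.pi * dd**3 / 6.0
    return v if v.ndim else float(v)


def cell_volume_ellipsoid(a, b):
    """Cell volume (µm³) from ellipsoid major axis ``a`` and minor axis ``b``.

    Uses ``V = pi*a*b**2/6`` (axes are full lengths, not semi-axes). For
    ``a == b`` this reduces to the sphere formula.
    """
    aa = np.asarray(a, dtype=float)
    bb = np.asarray(b, dtype=float)
    if np.any(aa < 0) or np.any(bb < 0):
        raise ValueError("axes must be non-negative")
    if np.any(aa < bb):
        raise ValueError("major axis a must be >= minor axis b")
    v = np.pi * aa * bb**2 / 6.0
    return v if v.ndim else float(v)


def nc_ratio(total_nuclear_volume, cell_volume):
    """Nucleocytoplasmic ratio N/C.

    ``total_nuclear_volume`` is the sum over all nuclei in the (possibly
    multinucleate) cell; ``cell_volume`` must be positive.
    """
    n = np.asarray(total_nuclear_volume, dtype=float)
    c = np.asarray(cell_volume, dtype=float)
    if np.any(c <= 0):
        raise ValueError("cell_volume must be positive")
    if np.any(n < 0):
        raise ValueError("total_nuclear_volume must be non-negative")
    r = n / c
    return r if r.ndim else float(r)
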