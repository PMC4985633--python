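"""Bragg's-law utilities for lamellar membrane diffraction.

A stack of membranes diffracts at angles satisfying
``n lambda = 2 d sin(theta)``; angles are accepted as 2-theta in
degrees, matching how diffractometer traces are plotted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["LamellarPattern", "d_spacing", "fit_periodicity", "MisindexWarning"]


class MisindexWarning(UserWarning):
    """Raised when an indexed peak series is inconsistent with one periodicity."""


def d_spacing(two_theta_deg: float, order: int = 1, wavelength: float = 4.75) -> float:
    """Lamellar spacing d (A) from one peak: d = n lambda / (2 sin theta)."""
    if not 0.0 < two_theta_deg < 180.0:
        raise ValueError("2-theta must be in (0, 180) degrees")
    if order < 1 or int(order) != order:
        raise ValueError("order must be a positive integer")
    if wavelength <= 0:
        raise ValueError("wavelength must be > 0")
    s = np.sin(np.radians(two_theta_deg / 2.0))
    d = order * wavelength / (2.0 * s)
    return float(d)


@dataclass(frozen=True)
class LamellarPattern:
    """Indexed lamellar peak list: 2-theta (deg), order n, wavelength (A)."""

    two_theta: np.ndarray
    order: np.ndarray
    wavelength: float = 4.75
    intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        tt = np.asarray(self.two_theta, float)
        n = np.asarray(self.order, int)
        object.__setattr__(self, "two_theta", tt)
        object.__setattr__(self, "order", n)
        if tt.shape != n.shape or tt.ndim != 1 or len(tt) == 0:
            raise ValueError("two_theta and order must be matching 1-d arrays")
        if np.any((tt <= 0) | (tt >= 180)):
            raise ValueError("2-theta must be in (0, 180) degrees")
        if np.any(n < 1):
            raise ValueError("orders must be positive integers")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")


def fit_periodicity(
    pattern: LamellarPattern, residual_tolerance: float = 5e-3
) -> tuple[float, float]:
    """Least-squares periodicity d (A) over an indexed peak series.

    Fits ``sin(theta_n) = n lambda / (2 d)`` through the origin; for a
    single peak this reduces to :func:`d_spacing`.  Emits
    :class:`MisindexWarning` when sin(theta) residuals exceed
    ``residual_tolerance`` (suggesting wrong order assignment).
    Returns (d, sigma_d).
    """
    tt, n = pattern.two_theta, pattern.order
    s = np.sin(np.radians(tt / 2.0))
    x = n.astype(float)
    # slope m = lambda/(2d) through the origin
    m = float(np.sum(x * s) / np.sum(x * x))
    if m <= 0:
        raise ValueError("non-physical peak series")
    resid = s - m * x
    dof = len(s) - 1
    if dof > 0:
        m_var = float(np.sum(resid**2) / dof / np.sum(x * x))
    else:
        m_var = 0.0
    if np.any(np.abs(resid) > residual_tolerance):
        warnings.warn(
            "peak series inconsistent with a single periodicity; check order "
            "indexing", MisindexWarning, stacklevel=2,
        )
    d = pattern.wavelength / (2.0 * m)
    d_err = d * np.sqrt(m_var) / m
    if np.any(x * pattern.wavelength > 2.0 * d + 1e-9):
        raise ValueError("n lambda > 2d: unphysical order for this spacing")
    return float(d), float(d_err)
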