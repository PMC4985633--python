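"""Liquids diffraction: S(Q) <-> g(r), intramolecular subtraction,
peak extraction and water H-bond geometry.

The radial distribution function is the sine-Fourier partner of the
structure factor,

    g(r) = 1 + 1/(2 pi^2 rho0 r) * int_0^Qmax Q [S(Q)-1] W(Q) sin(Qr) dQ

with ``rho0`` the atomic number density (atoms/A^3) and ``W`` an
optional Lorch window that damps the ripples caused by truncating the
integral at the instrument's Qmax.  H-bond geometry between two
adjacent water molecules follows from the peak distances by the law of
cosines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "StructureFactor",
    "RadialDistribution",
    "IntraMolecularPair",
    "HBondGeometry",
    "lorch_window",
    "sq_to_gr",
    "gr_to_sq",
    "subtract_intramolecular",
    "peak_positions",
    "water_intra_angle",
    "hbond_beta",
    "hbond_theta",
    "hbond_geometry",
    "number_density",
    "DEFAULT_R_GRID",
]

#: default real-space grid, A (analysis range ~< 4 A; solute-solute
#: correlations fall beyond ~4 A, and 10 A caps the transform cheaply)
DEFAULT_R_GRID = np.arange(0.01, 10.0 + 1e-9, 0.01)


@dataclass(frozen=True)
class StructureFactor:
    """Static structure factor S(Q) with its atomic number density."""

    q: np.ndarray  # 1/A
    s: np.ndarray  # dimensionless
    rho0: float  # atoms/A^3
    label: str = ""

    def __post_init__(self) -> None:
        q = np.asarray(self.q, float)
        s = np.asarray(self.s, float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "s", s)
        if q.shape != s.shape or q.ndim != 1:
            raise ValueError("q and s must be 1-d arrays of equal length")
        if np.any(np.diff(q) <= 0):
            raise ValueError("Q must be strictly increasing")
        if self.rho0 <= 0:
            raise ValueError("rho0 must be > 0")

    def check_large_q_limit(self, tol: float = 0.05) -> bool:
        """True when S(Q) -> 1 within tol over the last decade of Q."""
        tail = self.q >= 0.8 * self.q[-1]
        return bool(np.all(np.abs(self.s[tail] - 1.0) < tol))


@dataclass(frozen=True)
class RadialDistribution:
    """g(r) with provenance of the transform that produced it."""

    r: np.ndarray  # A
    g: np.ndarray
    rho0: float
    q_max: float | None = None
    window: str = "none"

    def __post_init__(self) -> None:
        r = np.asarray(self.r, float)
        g = np.asarray(self.g, float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "g", g)
        if r.shape != g.shape:
            raise ValueError("r and g must have equal length")


@dataclass(frozen=True)
class IntraMolecularPair:
    """One bonded/geminal pair of the solute: label, distance (A),
    weight (contribution to S(Q)), Gaussian width gamma (A^2)."""

    label: str
    distance: float
    weight: float
    gamma: float

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("pair distance must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


def lorch_window(q: np.ndarray, q_max: float) -> np.ndarray:
    """Lorch modification function sin(pi Q/Qmax)/(pi Q/Qmax)."""
    x = np.pi * np.asarray(q, float) / q_max
    return np.where(x == 0, 1.0, np.sin(x) / np.where(x == 0, 1.0, x))


def sq_to_gr(
    sf: StructureFactor,
    r_grid: np.ndarray | None = None,
    window: str = "lorch",
) -> RadialDistribution:
    """Transform S(Q) to g(r) by trapezoidal quadrature.

    ``window`` is ``"lorch"`` (default — suppresses truncation ripples)
    or ``"none"`` (plain truncation at Qmax).
    """
    if window not in ("lorch", "none"):
        raise ValueError("window must be 'lorch' or 'none'")
    r = DEFAULT_R_GRID if r_grid is None else np.asarray(r_grid, float)
    q = sf.q
    w = lorch_window(q, q[-1]) if window == "lorch" else np.ones_like(q)
    kernel = q * (sf.s - 1.0) * w  # integrand without sin(Qr)
    # analytic r -> 0 limit: sin(Qr)/r -> Q
    sin_qr = np.sin(np.outer(r, q))
    integral = np.trapezoid(kernel[None, :] * sin_qr, q, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = 1.0 + integral / (2.0 * np.pi**2 * sf.rho0 * r)
    small = r < 1e-12
    if np.any(small):
        g[small] = 1.0 + np.trapezoid(kernel * q, q) / (2.0 * np.pi**2 * sf.rho0)
    return RadialDistribution(r=r, g=g, rho0=sf.rho0, q_max=float(q[-1]), window=window)


def gr_to_sq(
    rdf: RadialDistribution,
    rho0: float | None = None,
    q_grid: np.ndarray | None = None,
    tail_tol: float = 0.05,
) -> StructureFactor:
    """Forward transform g(r) -> S(Q) (inverse sine transform).

    Requires g(r) -> 1 at the end of the r grid (within ``tail_tol``),
    otherwise the truncated integral diverges from the true transform.
    """
    rho = rdf.rho0 if rho0 is None else rho0
    if q_grid is None:
        q_grid = np.arange(0.02, 23.5 + 1e-9, 0.02)
    q = np.asarray(q_grid, float)
    r = rdf.r
    tail = r >= r[-1] * 0.9
    if np.any(np.abs(rdf.g[tail] - 1.0) > tail_tol):
        raise ValueError("g(r) does not approach 1 at the end of the r grid")
    kernel = r * (rdf.g - 1.0)
    sin_qr = np.sin(np.outer(q, r))
    integral = np.trapezoid(kernel[None, :] * sin_qr, r, axis=1)
    s = 1.0 + 4.0 * np.pi * rho * integral / q
    return StructureFactor(q=q, s=s, rho0=rho)


def subtract_intramolecular(
    sf: StructureFactor, model: Sequence[IntraMolecularPair]
) -> StructureFactor:
    """Remove Gaussian-broadened solute self-correlations from S(Q):

    S'(Q) = S(Q) - sum_ij w_ij sin(Q r_ij)/(Q r_ij) exp(-gamma_ij Q^2/2)
    """
    s = sf.s.copy()
    for pair in model:
        x = sf.q * pair.distance
        s = s - pair.weight * np.sin(x) / x * np.exp(-pair.gamma * sf.q**2 / 2.0)
    return StructureFactor(q=sf.q, s=s, rho0=sf.rho0, label=sf.label)


def peak_positions(
    rdf: RadialDistribution,
    r_window: tuple[float, float] | None = None,
    min_height: float = 0.0,
) -> list[tuple[float, float]]:
    """Local maxima of g(r), refined by 3-point quadratic interpolation.

    Returns (r_peak, height) pairs, ascending in r; merged peaks closer
    than the grid step appear as a single maximum.
    """
    r, g = rdf.r, rdf.g
    if r_window is not None:
        lo, hi = r_window
        if lo < r[0] - 1e-9 or hi > r[-1] + 1e-9:
            raise ValueError("r_window outside the r grid")
        sel = (r >= lo) & (r <= hi)
        r, g = r[sel], g[sel]
    peaks = []
    for k in range(1, len(r) - 1):
        if g[k] > g[k - 1] and g[k] >= g[k + 1] and g[k] > min_height:
            denom = g[k - 1] - 2 * g[k] + g[k + 1]
            if denom < 0:
                delta = 0.5 * (g[k - 1] - g[k + 1]) / denom
                delta = float(np.clip(delta, -0.5, 0.5))
            else:
                delta = 0.0
            step = r[k + 1] - r[k]
            r_pk = r[k] + delta * step
            h = g[k] - 0.25 * (g[k - 1] - g[k + 1]) * delta
            peaks.append((float(r_pk), float(h)))
    return peaks


# ---------------------------------------------------------------------------
# water H-bond geometry (law of cosines)


def _check_triangle(a: float, b: float, c: float) -> None:
    for x in (a, b, c):
        if x <= 0:
            raise ValueError("distances must be > 0")
    eps = 1e-9 * (a + b + c)  # degenerate (collinear) triangles are allowed
    if a + b < c - eps or a + c < b - eps or b + c < a - eps:
        raise ValueError(f"distances ({a}, {b}, {c}) violate the triangle inequality")


def water_intra_angle(d_od: float, d_dd: float) -> float:
    """D-O-D angle (deg) of a water molecule from its O-D and D-D
    distances (isosceles triangle)."""
    if d_od <= 0 or d_dd <= 0:
        raise ValueError("distances must be > 0")
    if 2.0 * d_od <= d_dd:
        raise ValueError("2 d_OD must exceed d_DD (triangle inequality)")
    return float(np.degrees(np.arccos(1.0 - d_dd**2 / (2.0 * d_od**2))))


def hbond_beta(d_od_intra: float, d_oo: float, d_od_inter: float) -> float:
    """Angle (deg) between the donor's O-D bond and the O-O vector."""
    _check_triangle(d_od_intra, d_oo, d_od_inter)
    cosb = (d_od_intra**2 + d_oo**2 - d_od_inter**2) / (2.0 * d_od_intra * d_oo)
    return float(np.degrees(np.arccos(np.clip(cosb, -1.0, 1.0))))


def hbond_theta(d_od_intra: float, d_oo: float, d_od_inter: float) -> float:
    """O-D...O hydrogen-bond angle (deg) at the D atom."""
    _check_triangle(d_od_intra, d_oo, d_od_inter)
    cost = (d_od_intra**2 + d_od_inter**2 - d_oo**2) / (
        2.0 * d_od_intra * d_od_inter
    )
    return float(np.degrees(np.arccos(np.clip(cost, -1.0, 1.0))))


@dataclass(frozen=True)
class HBondGeometry:
    """Distances and derived angles of the water-water H-bond triangle."""

    d_od_intra: float
    d_dd: float
    d_oo: float
    d_od_inter: float
    alpha: float  # D-O-D intramolecular angle, deg
    beta: float  # O-D vs O-O angle, deg
    theta: float  # H-bond angle at D, deg

    def summary(self) -> str:
        return (
            "Water H-bond geometry\n"
            f"  O-D (intra)  {self.d_od_intra:.2f} A\n"
            f"  D-D          {self.d_dd:.2f} A\n"
            f"  O-O          {self.d_oo:.2f} A\n"
            f"  O-D (inter)  {self.d_od_inter:.2f} A\n"
            f"  alpha (D-O-D)        {self.alpha:.1f} deg\n"
            f"  beta (O-D vs O-O)    {self.beta:.2f} deg\n"
            f"  theta (O-D...O)      {self.theta:.1f} deg"
        )


def hbond_geometry(
    d_od_intra: float, d_dd: float, d_oo: float, d_od_inter: float
) -> HBondGeometry:
    """All three angles from the four measured distances."""
    return HBondGeometry(
        d_od_intra=d_od_intra, d_dd=d_dd, d_oo=d_oo, d_od_inter=d_od_inter,
        alpha=water_intra_angle(d_od_intra, d_dd),
        beta=hbond_beta(d_od_intra, d_oo, d_od_inter),
        theta=hbond_theta(d_od_intra, d_oo, d_od_inter),
    )


def number_density(
    molarity: float,
    waters_per_solute: float,
    atoms_per_solute: int = 20,
    atoms_per_water: int = 3,
) -> float:
    """Atomic number density (atoms/A^3) of an aqueous solute solution.

    Counts all atoms of ``molarity`` mol/L of solute plus
    ``waters_per_solute`` waters per solute molecule in one litre
    (1e27 A^3).
    """
    from .constants import AVOGADRO

    if molarity <= 0:
        raise ValueError("molarity must be > 0")
    atoms = molarity * AVOGADRO * (atoms_per_solute + waters_per_solute * atoms_per_water)
    return atoms / 1e27
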