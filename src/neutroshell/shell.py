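"""Hydration-shell decomposition of SANS contrast-variation data.

The scattering particle is protein plus a shell of dense water.  Two
fits extract the shell:

* the ratio of particle amplitudes between two contrast conditions,
  ``R(X) = [(drV)_P,A + X V dr_H,A] / [(drV)_P,B + X V dr_H,B]``,
  solved for the shell-to-protein volume ratio ``X``;
* the parallel-axes decomposition ``Rg^2 = f1 R_Prot^2 + (1-f1)
  R_Hyd^2`` where ``f1`` is the fractional protein contribution to the
  particle amplitude at each condition — a straight line in ``f1``
  whose extrapolations to 1 and 0 give the protein and shell radii of
  gyration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sld import ContrastCondition

__all__ = [
    "contrast_ratio_model",
    "fit_shell_ratio",
    "f1_fraction",
    "rg_decomposition",
    "shell_geometry",
    "ShellGeometry",
    "HydrationShellModel",
    "HydrationShellResults",
]


def contrast_ratio_model(
    x, cond_a: ContrastCondition, cond_b: ContrastCondition
):
    """Predicted amplitude ratio A/B as a function of the volume ratio X."""
    va, vb = cond_a.protein_volume, cond_b.protein_volume
    if abs(va - vb) > 1e-9 * max(va, vb):
        raise ValueError("conditions must share the same protein volume")
    x = np.asarray(x, dtype=float)
    num = cond_a.protein_excess_cm + cond_a.hydration_excess_cm(1.0) * x
    den = cond_b.protein_excess_cm + cond_b.hydration_excess_cm(1.0) * x
    return num / den


def fit_shell_ratio(
    observed_ratio: float,
    cond_a: ContrastCondition,
    cond_b: ContrastCondition,
    sigma_ratio: float = 0.0,
    x_grid: np.ndarray | None = None,
) -> tuple[float, float]:
    """Solve the amplitude-ratio model for X; returns (X, sigma_X).

    A grid search over ``x_grid`` (default [0, 1] step 0.005) followed
    by local quadratic refinement keeps the solver robust near the pole
    where the denominator amplitude crosses zero; grid points beyond a
    sign change of the denominator are excluded and the pole is
    reported if no admissible solution remains.
    """
    if x_grid is None:
        x_grid = np.arange(0.0, 1.0 + 1e-12, 0.005)
    x_grid = np.asarray(x_grid, dtype=float)
    den = cond_b.protein_excess_cm + cond_b.hydration_excess_cm(1.0) * x_grid
    bad = (np.sign(den) != np.sign(den[0])) | (den == 0)
    if np.any(bad):
        first_bad = int(np.argmax(bad))
        x_grid = x_grid[:first_bad]
        if len(x_grid) < 3:
            raise ValueError("amplitude denominator crosses zero at the start of the grid")
    r = contrast_ratio_model(x_grid, cond_a, cond_b)
    misfit = np.abs(r - observed_ratio)
    k = int(np.argmin(misfit))
    x_best = x_grid[k]
    # local refinement: R(X) is smooth and monotone between poles, so a
    # bisection on R(X)-observed between the bracketing grid points is
    # exact when a sign change exists
    if 0 < k < len(x_grid) - 1:
        from scipy.optimize import brentq

        lo, hi = x_grid[k - 1], x_grid[k + 1]
        f = lambda x: float(contrast_ratio_model(x, cond_a, cond_b)) - observed_ratio
        if f(lo) * f(hi) < 0:
            x_best = brentq(f, lo, hi, xtol=1e-10)
    elif misfit[k] > 1e-6 * max(1.0, abs(observed_ratio)):
        raise ValueError(
            "observed ratio not attainable on the X grid (best misfit "
            f"{misfit[k]:.3g} at X = {x_best:.3g})"
        )
    # uncertainty from the local slope dR/dX
    eps = 1e-6
    dr_dx = float(
        (contrast_ratio_model(x_best + eps, cond_a, cond_b)
         - contrast_ratio_model(max(x_best - eps, 0.0), cond_a, cond_b))
        / (eps + min(eps, x_best))
    )
    sigma_x = abs(sigma_ratio / dr_dx) if dr_dx != 0 else np.inf
    return float(x_best), float(sigma_x)


def f1_fraction(cond: ContrastCondition, x: float) -> float:
    """Fractional protein contribution to the particle amplitude."""
    particle = cond.protein_excess_cm + cond.hydration_excess_cm(x)
    if abs(particle) < 1e-12 * max(abs(cond.protein_excess_cm), 1e-30):
        raise ValueError(
            f"condition {cond.label!r} is at overall contrast match; "
            "f1 is undefined"
        )
    return cond.protein_excess_cm / particle


def rg_decomposition(
    rg2: Sequence[float],
    f1: Sequence[float],
    sigma_rg2: Sequence[float] | None = None,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Weighted line fit of Rg^2 vs f1; returns ((R_Prot, s), (R_Hyd, s)).

    R_Prot is the square root of the fitted value at f1 = 1, R_Hyd at
    f1 = 0.  Raises when the design is degenerate (all f1 equal) or an
    extrapolated value is negative (imaginary radius).
    """
    y = np.asarray(rg2, dtype=float)
    x = np.asarray(f1, dtype=float)
    if len(x) < 2 or np.ptp(x) < 1e-12:
        raise ValueError("need >= 2 points with distinct f1")
    if sigma_rg2 is not None:
        s = np.asarray(sigma_rg2, dtype=float)
        with np.errstate(divide="ignore"):
            w = np.where(s > 0, 1.0 / s**2, 0.0)
        if np.all(w == 0):
            w = np.ones_like(y)
    else:
        w = np.ones_like(y)
    from .guinier import _weighted_line

    a, b, cov = _weighted_line(x, y, w)
    at1, at0 = a + b, a
    var1 = cov[0, 0] + 2 * cov[0, 1] + cov[1, 1]
    var0 = cov[0, 0]
    for name, v in (("f1=1", at1), ("f1=0", at0)):
        if v < 0:
            raise ValueError(f"extrapolated Rg^2 at {name} is negative: {v:.3g}")
    r_prot = float(np.sqrt(at1))
    r_hyd = float(np.sqrt(at0))
    s_prot = float(np.sqrt(max(var1, 0.0)) / (2 * r_prot)) if r_prot > 0 else np.inf
    s_hyd = float(np.sqrt(max(var0, 0.0)) / (2 * r_hyd)) if r_hyd > 0 else np.inf
    return (r_prot, s_prot), (r_hyd, s_hyd)


@dataclass(frozen=True)
class ShellGeometry:
    """Sphere-equivalent geometry of the protein + shell particle."""

    protein_radius: float  # A, sphere-equivalent
    shell_thickness: float  # A
    shell_rg: float  # A


def shell_geometry(r_prot: float, x: float) -> ShellGeometry:
    """Sphere-equivalent shell geometry from protein Rg and volume ratio X.

    The protein is mapped to a uniform sphere (R = sqrt(5/3) Rg); the
    shell occupies X times the protein volume, so its outer radius
    solves (R+t)^3 = (1+X) R^3; the shell Rg uses the uniform
    spherical-shell formula Rg^2 = (3/5)(R2^5-R1^5)/(R2^3-R1^3).
    """
    if r_prot <= 0:
        raise ValueError("r_prot must be > 0")
    if x < 0:
        raise ValueError("X must be >= 0")
    r1 = np.sqrt(5.0 / 3.0) * r_prot
    r2 = r1 * (1.0 + x) ** (1.0 / 3.0)
    if x == 0:
        return ShellGeometry(r1, 0.0, float(np.sqrt(3.0 / 5.0) * r1))
    rg2 = 0.6 * (r2**5 - r1**5) / (r2**3 - r1**3)
    return ShellGeometry(float(r1), float(r2 - r1), float(np.sqrt(rg2)))


@dataclass(frozen=True)
class HydrationShellResults:
    """Fitted shell parameters with uncertainties and diagnostics."""

    x: float
    x_err: float
    observed_ratio: float
    ratio_err: float
    ratio_pair: tuple[str, str]
    r_prot: float
    r_prot_err: float
    r_hyd: float
    r_hyd_err: float
    f1: pd.Series = field(repr=False)
    geometry: ShellGeometry
    conditions: pd.DataFrame = field(repr=False)

    def summary(self) -> str:
        g = self.geometry
        lines = [
            "Hydration-shell decomposition",
            "=" * 34,
            f"amplitude ratio {self.ratio_pair[0]} / {self.ratio_pair[1]}: "
            f"{self.observed_ratio:.4g} +/- {self.ratio_err:.2g}",
            f"X = V_Hydration/V_Protein      {self.x:.3f} +/- {self.x_err:.3f}",
            f"R_Prot (f1 = 1)                {self.r_prot:.2f} +/- {self.r_prot_err:.2f} A",
            f"R_Hyd  (f1 = 0)                {self.r_hyd:.2f} +/- {self.r_hyd_err:.2f} A",
            f"sphere-equivalent radius       {g.protein_radius:.2f} A",
            f"shell thickness                {g.shell_thickness:.2f} A",
            f"uniform-shell Rg               {g.shell_rg:.2f} A",
            "",
            "per-condition protein fraction f1:",
        ]
        for label, v in self.f1.items():
            lines.append(f"  {label:28s} {v:8.4f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Rg^2 vs f1 with the fitted decomposition line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.conditions
        ax.errorbar(self.f1, t["rg"] ** 2, yerr=2 * t["rg"] * t["rg_err"], fmt="o")
        xs = np.linspace(0, max(1.05, float(self.f1.max())), 50)
        line = self.r_hyd**2 + (self.r_prot**2 - self.r_hyd**2) * xs
        ax.plot(xs, line, "-")
        ax.set_xlabel(r"$f_1$")
        ax.set_ylabel(r"$R_g^2$ ($\AA^2$)")
        return ax


class HydrationShellModel:
    """Protein + dense-water-shell model of a contrast-variation table.

    Parameters
    ----------
    conditions
        DataFrame with one row per contrast condition and columns
        ``label``, ``i0_over_n`` (cm2, on any common scale),
        ``i0_over_n_err``, ``rg`` (A), ``rg_err`` and a
        :class:`~neutroshell.sld.ContrastCondition` in ``condition``.
    ratio_pair
        Labels of the two conditions whose amplitude ratio determines
        X (numerator, denominator).
    """

    def __init__(self, conditions: pd.DataFrame, ratio_pair: tuple[str, str]):
        req = {"label", "i0_over_n", "i0_over_n_err", "rg", "rg_err", "condition"}
        missing = req - set(conditions.columns)
        if missing:
            raise ValueError(f"conditions table is missing columns {sorted(missing)}")
        self.conditions = conditions.set_index("label", drop=False)
        for lab in ratio_pair:
            if lab not in self.conditions.index:
                raise ValueError(f"ratio_pair label {lab!r} not in conditions")
        self.ratio_pair = ratio_pair

    def observed_ratio(self) -> tuple[float, float]:
        """Signed amplitude ratio between the two ratio_pair conditions.

        Magnitude from sqrt(I(0)/N); signs from the computed contrasts
        at X = 0 (the spec forbids inferring signs from intensities).
        """
        a = self.conditions.loc[self.ratio_pair[0]]
        b = self.conditions.loc[self.ratio_pair[1]]
        sign = np.sign(a["condition"].protein_excess_cm) * np.sign(
            b["condition"].protein_excess_cm
        )
        r = sign * np.sqrt(a["i0_over_n"] / b["i0_over_n"])
        # relative errors add in quadrature, halved through the sqrt
        rel = 0.5 * np.sqrt(
            (a["i0_over_n_err"] / a["i0_over_n"]) ** 2
            + (b["i0_over_n_err"] / b["i0_over_n"]) ** 2
        )
        return float(r), float(abs(r) * rel)

    def fit(self, x_grid: np.ndarray | None = None) -> HydrationShellResults:
        robs, rerr = self.observed_ratio()
        ca = self.conditions.loc[self.ratio_pair[0], "condition"]
        cb = self.conditions.loc[self.ratio_pair[1], "condition"]
        x, x_err = fit_shell_ratio(robs, ca, cb, rerr, x_grid)
        f1 = pd.Series(
            {lab: f1_fraction(row["condition"], x)
             for lab, row in self.conditions.iterrows()},
            name="f1",
        )
        rg = self.conditions["rg"].to_numpy(float)
        rg_err = self.conditions["rg_err"].to_numpy(float)
        (r_prot, sp), (r_hyd, sh) = rg_decomposition(
            rg**2, f1.to_numpy(), sigma_rg2=2 * rg * rg_err
        )
        return HydrationShellResults(
            x=x, x_err=x_err, observed_ratio=robs, ratio_err=rerr,
            ratio_pair=self.ratio_pair,
            r_prot=r_prot, r_prot_err=sp, r_hyd=r_hyd, r_hyd_err=sh,
            f1=f1, geometry=shell_geometry(r_prot, x),
            conditions=self.conditions,
        )
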