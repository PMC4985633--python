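"""Guinier analysis of SANS curves and Stuhrmann contrast-variation fits.

In the Guinier regime a dilute monodisperse solution scatters as
``I(Q) = I(0) exp(-Q^2 Rg^2 / 3)``, so a weighted linear regression of
``ln I`` on ``Q^2`` inside a window with ``Qmax.Rg`` below a validity
bound yields the forward intensity and radius of gyration.  Dividing
I(0) by the number concentration N puts curves at different protein
concentrations on a common scale, and the signed square roots of I(0)/N
— equal to the particle excess scattering lengths (delta-rho x V) —
plotted against solvent SLD form the Stuhrmann line whose x-intercept
is the particle's contrast-match SLD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import AVOGADRO

__all__ = [
    "ScatteringCurve",
    "GuinierModel",
    "GuinierResult",
    "guinier_fit",
    "normalize_forward",
    "StuhrmannModel",
    "StuhrmannResult",
]


@dataclass(frozen=True)
class ScatteringCurve:
    """One SANS curve on absolute scale: Q (1/A), I (1/cm), optional sigma."""

    q: np.ndarray
    i: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""
    concentration: float | None = None  # g/cm3
    solvent_sld: float | None = None  # cm-2

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.i, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "i", i)
        if q.ndim != 1 or q.shape != i.shape:
            raise ValueError("q and i must be 1-d arrays of equal length")
        if np.any(q <= 0) or np.any(np.diff(q) <= 0):
            raise ValueError("Q must be strictly increasing and positive")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", s)
            if s.shape != q.shape:
                raise ValueError("sigma must match q in length")
            if np.any(s < 0):
                raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class GuinierResult:
    """Forward intensity and radius of gyration from one curve."""

    i0: float
    i0_err: float
    rg: float
    rg_err: float
    q_window: tuple[float, float]
    n_points: int
    qmax_rg: float
    curve: ScatteringCurve = field(repr=False)
    i0_over_n: float | None = None  # cm2, set when concentration known

    def normalized_forward(self, molar_mass: float) -> float:
        if self.curve.concentration is None:
            raise ValueError("curve carries no concentration")
        return normalize_forward(self.i0, self.curve.concentration, molar_mass)

    def summary(self) -> str:
        lines = [
            f"Guinier fit: {self.curve.label or '<curve>'}",
            f"  I(0)    = {self.i0:.6g} +/- {self.i0_err:.2g} 1/cm",
            f"  Rg      = {self.rg:.4g} +/- {self.rg_err:.2g} A",
            f"  window  = [{self.q_window[0]:.4g}, {self.q_window[1]:.4g}] 1/A "
            f"({self.n_points} pts, Qmax.Rg = {self.qmax_rg:.3g})",
        ]
        if self.i0_over_n is not None:
            lines.append(f"  I(0)/N  = {self.i0_over_n:.6g} cm2")
        return "\n".join(lines)

    def plot(self, ax=None):
        """ln I vs Q^2 with the fitted line over the window."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.curve
        ax.plot(c.q**2, np.log(c.i), ".", label=c.label or "data")
        qs = np.linspace(*self.q_window, 50)
        ax.plot(qs**2, np.log(self.i0) - qs**2 * self.rg**2 / 3.0, "-",
                label=f"Rg = {self.rg:.1f} A")
        ax.set_xlabel(r"$Q^2$ (1/$\AA^2$)")
        ax.set_ylabel(r"$\ln I$")
        ax.legend()
        return ax


def _weighted_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least-squares line y = a + b x; returns a, b, cov(2x2)."""
    A = np.vstack([np.ones_like(x), x]).T
    Aw = A * np.sqrt(w)[:, None]
    yw = y * np.sqrt(w)
    beta, *_ = np.linalg.lstsq(Aw, yw, rcond=None)
    cov = np.linalg.inv(A.T @ (A * w[:, None]))
    return beta[0], beta[1], cov


class GuinierModel:
    """Guinier fit of one scattering curve.

    The fit window is iterated self-consistently: fit, recompute Rg,
    move the high-Q edge to where ``Qmax.Rg`` meets ``validity_bound``
    (default 1.3), repeat until stable.
    """

    def __init__(self, curve: ScatteringCurve, validity_bound: float = 1.3,
                 min_points: int = 5):
        self.curve = curve
        self.validity_bound = float(validity_bound)
        self.min_points = int(min_points)

    def _fit_window(self, hi: int):
        c = self.curve
        q = c.q[:hi]
        y = np.log(c.i[:hi])
        if c.sigma is not None and np.all(c.sigma[:hi] > 0):
            w = (c.i[:hi] / c.sigma[:hi]) ** 2  # sigma(ln I) = sigma/I
        else:
            w = np.ones_like(q)
        a, b, cov = _weighted_line(q**2, y, w)
        if b >= 0:
            raise ValueError("non-Guinier curve: ln I does not decrease with Q^2")
        return q, y, w, a, b, cov

    def fit(self) -> GuinierResult:
        """Iterate the window from the low-Q end: fit, update Rg, and
        extend/shrink until Qmax.Rg sits at the validity bound."""
        c = self.curve
        if np.any(c.i <= 0):
            raise ValueError("intensities must be positive for a log-linear fit")
        n = len(c.q)
        if n < self.min_points:
            raise ValueError(f"need >= {self.min_points} points")
        hi = n
        seen: set[int] = set()
        for _ in range(200):
            q, y, w, a, b, cov = self._fit_window(hi)
            rg = float(np.sqrt(-3.0 * b))
            k = int(np.searchsorted(c.q, self.validity_bound / rg, side="right"))
            k = min(max(k, self.min_points), n)
            if k == hi:
                break
            if k in seen:  # oscillating between windows: take the tighter one
                hi = min(hi, k)
                q, y, w, a, b, cov = self._fit_window(hi)
                rg = float(np.sqrt(-3.0 * b))
                break
            seen.add(hi)
            hi = k
        while c.q[hi - 1] * rg > self.validity_bound and hi > self.min_points:
            hi -= 1
            q, y, w, a, b, cov = self._fit_window(hi)
            rg = float(np.sqrt(-3.0 * b))
        if q[-1] * rg > self.validity_bound * 1.5:
            raise ValueError(
                "cannot satisfy the Guinier validity bound with >= "
                f"{self.min_points} points"
            )
        # scale parameter covariance by reduced chi^2 when dof > 0 and
        # the curve carries real uncertainties; otherwise use residual
        # variance so noiseless synthetic curves report ~0 error.
        resid = y - (a + b * q**2)
        dof = len(q) - 2
        chi2 = float(np.sum(w * resid**2))
        scale = chi2 / dof if dof > 0 else 0.0
        if c.sigma is None:
            cov = cov * scale
        else:
            cov = cov * max(scale, 1.0)
        i0 = float(np.exp(a))
        i0_err = i0 * float(np.sqrt(max(cov[0, 0], 0.0)))
        rg_err = float(np.sqrt(max(cov[1, 1], 0.0)) * 3.0 / (2.0 * rg))
        i0_over_n = None
        return GuinierResult(
            i0=i0, i0_err=i0_err, rg=rg, rg_err=rg_err,
            q_window=(float(q[0]), float(q[-1])), n_points=len(q),
            qmax_rg=float(q[-1] * rg), curve=c, i0_over_n=i0_over_n,
        )


def guinier_fit(curve: ScatteringCurve, validity_bound: float = 1.3,
                min_points: int = 5) -> GuinierResult:
    """Functional wrapper around :class:`GuinierModel`."""
    return GuinierModel(curve, validity_bound, min_points).fit()


def normalize_forward(i0: float, concentration: float, molar_mass: float) -> float:
    """I(0)/N in cm2, with N = c NA / M particles per cm3."""
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    if molar_mass <= 0:
        raise ValueError("molar_mass must be > 0")
    n = concentration * AVOGADRO / molar_mass
    return i0 / n


@dataclass(frozen=True)
class StuhrmannResult:
    """Signed-amplitude line vs solvent SLD."""

    slope: float  # cm per (cm-2) = cm3
    intercept: float  # cm
    slope_err: float
    intercept_err: float
    match_point_sld: float  # cm-2
    match_point_err: float
    residuals: np.ndarray

    def summary(self) -> str:
        return (
            "Stuhrmann line (signed sqrt(I(0)/N) vs solvent SLD)\n"
            f"  slope        = {self.slope:.6g} +/- {self.slope_err:.2g} cm3\n"
            f"  intercept    = {self.intercept:.6g} +/- {self.intercept_err:.2g} cm\n"
            f"  match point  = {self.match_point_sld:.6g} +/- "
            f"{self.match_point_err:.2g} cm-2"
        )


class StuhrmannModel:
    """Weighted line fit of signed particle amplitudes vs solvent SLD.

    ``signs`` must be supplied from computed contrasts (+1/-1 per
    condition) — the sign of an amplitude is not inferable from the
    measured intensity alone.
    """

    def __init__(self, solvent_slds, i0_over_n, signs, sigma=None):
        self.solvent_slds = np.asarray(solvent_slds, dtype=float)
        self.i0_over_n = np.asarray(i0_over_n, dtype=float)
        signs = np.asarray(signs, dtype=float)
        if signs.shape != self.solvent_slds.shape:
            raise ValueError("one sign per condition is required")
        if np.any(np.abs(signs) != 1):
            raise ValueError("signs must be +1 or -1 (from the contrast model)")
        self.signs = signs
        self.sigma = None if sigma is None else np.asarray(sigma, dtype=float)
        if len(self.solvent_slds) < 2:
            raise ValueError("need at least 2 conditions for a Stuhrmann line")
        if np.any(self.i0_over_n < 0):
            raise ValueError("I(0)/N must be >= 0")

    def fit(self) -> StuhrmannResult:
        amp = self.signs * np.sqrt(self.i0_over_n)
        if self.sigma is not None:
            # sigma(sqrt(y)) = sigma_y / (2 sqrt(y))
            with np.errstate(divide="ignore"):
                s_amp = self.sigma / (2.0 * np.sqrt(self.i0_over_n))
            with np.errstate(divide="ignore"):
                w = np.where(s_amp > 0, 1.0 / s_amp**2, 0.0)
            if np.all(w == 0):
                w = np.ones_like(amp)
        else:
            w = np.ones_like(amp)
        a, b, cov = _weighted_line(self.solvent_slds, amp, w)
        if b == 0:
            raise ValueError("zero slope: no contrast dependence")
        mp = -a / b
        # first-order propagation of the intercept/slope covariance
        grad = np.array([-1.0 / b, a / b**2])
        mp_var = float(grad @ cov @ grad)
        resid = amp - (a + b * self.solvent_slds)
        return StuhrmannResult(
            slope=float(b), intercept=float(a),
            slope_err=float(np.sqrt(max(cov[1, 1], 0.0))),
            intercept_err=float(np.sqrt(max(cov[0, 0], 0.0))),
            match_point_sld=float(mp),
            match_point_err=float(np.sqrt(max(mp_var, 0.0))),
            residuals=resid,
        )
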