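"""Mean-square displacements and resilience from elastic incoherent scans.

In the Gaussian approximation the elastic intensity falls off as
``ln I_el(Q^2, T) = const - Q^2 <u^2>(T) / d`` where the divisor ``d``
is a literature convention (6 for the full 3-D MSD, the default here;
3 in the alternative convention — always state which one a number was
computed with).  The effective force constant ("resilience") is
``<k'> = 2 kB / (d<u^2>/dT)``; with the slope in A^2/K this is
``0.002761 / slope`` N/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import TWO_KB_OVER_A2

__all__ = [
    "ElasticScan",
    "ElasticScanModel",
    "MSDResults",
    "msd_from_scan",
    "resilience",
    "DEFAULT_Q2_WINDOW",
]

#: Q^2 fit window (1/A^2) within which the Gaussian approximation holds
#: for hydrated membrane samples.
DEFAULT_Q2_WINDOW = (0.18, 1.33)


@dataclass(frozen=True)
class ElasticScan:
    """Long-format elastic-intensity scan: (T, Q^2, I, sigma)."""

    temperature: np.ndarray  # K
    q2: np.ndarray  # 1/A^2
    intensity: np.ndarray  # normalized
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, float)
        q2 = np.asarray(self.q2, float)
        i = np.asarray(self.intensity, float)
        for name, arr in (("temperature", t), ("q2", q2), ("intensity", i)):
            object.__setattr__(self, name, arr)
        if not (t.shape == q2.shape == i.shape):
            raise ValueError("temperature, q2 and intensity must have equal shape")
        if np.any(i <= 0):
            raise ValueError("elastic intensities must be > 0")
        if np.any(q2 <= 0):
            raise ValueError("Q^2 must be > 0")
        if self.sigma is not None:
            s = np.asarray(self.sigma, float)
            object.__setattr__(self, "sigma", s)
            if s.shape != t.shape:
                raise ValueError("sigma must match the data in shape")

    def temperatures(self) -> np.ndarray:
        return np.unique(self.temperature)


@dataclass(frozen=True)
class MSDResults:
    """Temperature-indexed MSDs plus the resilience from their slope."""

    table: pd.DataFrame = field(repr=False)  # T, msd, msd_err, clamped
    msd_divisor: float
    q2_window: tuple[float, float]
    resilience: float | None = None  # N/m
    resilience_err: float | None = None
    msd_slope: float | None = None  # A^2/K
    msd_slope_err: float | None = None
    slope_residuals: np.ndarray | None = None

    def summary(self) -> str:
        lines = [
            "Elastic-scan MSD analysis "
            f"(Gaussian approximation, divisor {self.msd_divisor:g}, "
            f"Q^2 window [{self.q2_window[0]:g}, {self.q2_window[1]:g}] 1/A^2)",
            f"{'T (K)':>8s} {'<u2> (A2)':>12s} {'err':>8s}",
        ]
        for _, row in self.table.iterrows():
            flag = "  (clamped)" if row.get("clamped", False) else ""
            lines.append(f"{row['T']:8.1f} {row['msd']:12.4f} {row['msd_err']:8.4f}{flag}")
        if self.resilience is not None:
            lines.append(
                f"d<u2>/dT = {self.msd_slope:.3g} +/- {self.msd_slope_err:.2g} A2/K"
            )
            lines.append(
                f"<k'>     = {self.resilience:.3g} +/- {self.resilience_err:.2g} N/m"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table
        ax.errorbar(t["T"], t["msd"], yerr=t["msd_err"], fmt="o")
        if self.msd_slope is not None:
            ts = np.linspace(t["T"].min(), t["T"].max(), 20)
            ax.plot(ts, self._intercept() + self.msd_slope * ts, "-")
        ax.set_xlabel("T (K)")
        ax.set_ylabel(r"$\langle u^2\rangle$ ($\AA^2$)")
        return ax

    def _intercept(self) -> float:
        t = self.table
        w = 1.0 / np.clip(t["msd_err"].to_numpy(), 1e-12, None) ** 2
        return float(np.average(t["msd"], weights=w)
                     - self.msd_slope * np.average(t["T"], weights=w))


class ElasticScanModel:
    """Per-temperature Gaussian fits of an elastic scan.

    Temperatures are binned (default 5 K) before fitting, since ramp
    acquisitions log a quasi-continuous temperature column; set
    ``temperature_bin=None`` to fit each distinct temperature.
    """

    def __init__(
        self,
        scan: ElasticScan,
        q2_window: tuple[float, float] = DEFAULT_Q2_WINDOW,
        msd_divisor: float = 6.0,
        temperature_bin: float | None = 5.0,
        min_points: int = 4,
    ):
        if msd_divisor not in (3.0, 6.0):
            raise ValueError("msd_divisor must be 3 or 6 (state your convention)")
        self.scan = scan
        self.q2_window = (float(q2_window[0]), float(q2_window[1]))
        self.msd_divisor = float(msd_divisor)
        self.temperature_bin = temperature_bin
        self.min_points = int(min_points)

    def _bins(self) -> np.ndarray:
        t = self.scan.temperature
        if self.temperature_bin is None:
            return t
        return np.round(t / self.temperature_bin) * self.temperature_bin

    def fit(self) -> MSDResults:
        from .guinier import _weighted_line

        scan = self.scan
        lo, hi = self.q2_window
        tbin = self._bins()
        rows = []
        for tv in np.unique(tbin):
            sel = (tbin == tv) & (scan.q2 >= lo) & (scan.q2 <= hi)
            if np.count_nonzero(sel) < self.min_points:
                raise ValueError(
                    f"fewer than {self.min_points} points in the Q^2 window at T = {tv:g} K"
                )
            q2 = scan.q2[sel]
            y = np.log(scan.intensity[sel])
            if scan.sigma is not None and np.all(scan.sigma[sel] > 0):
                w = (scan.intensity[sel] / scan.sigma[sel]) ** 2
            else:
                w = np.ones_like(q2)
            a, b, cov = _weighted_line(q2, y, w)
            resid = y - (a + b * q2)
            dof = len(q2) - 2
            scale = float(np.sum(w * resid**2) / dof) if dof > 0 else 0.0
            if scan.sigma is None:
                cov = cov * scale
            else:
                cov = cov * max(scale, 1.0)
            msd = -self.msd_divisor * b
            clamped = False
            if msd < 0:
                msd, clamped = 0.0, True
            rows.append(
                dict(T=float(tv), msd=float(msd),
                     msd_err=float(self.msd_divisor * np.sqrt(max(cov[1, 1], 0.0))),
                     clamped=clamped)
            )
        table = pd.DataFrame(rows).sort_values("T").reset_index(drop=True)
        res = MSDResults(
            table=table, msd_divisor=self.msd_divisor, q2_window=self.q2_window
        )
        if len(table) >= 3:
            try:
                k, k_err, slope, slope_err, resid = resilience(
                    table["T"], table["msd"], table["msd_err"], full=True
                )
            except ValueError:
                return res
            res = MSDResults(
                table=table, msd_divisor=self.msd_divisor, q2_window=self.q2_window,
                resilience=k, resilience_err=k_err,
                msd_slope=slope, msd_slope_err=slope_err, slope_residuals=resid,
            )
        return res


def msd_from_scan(
    scan: ElasticScan,
    q2_window: tuple[float, float] = DEFAULT_Q2_WINDOW,
    msd_divisor: float = 6.0,
    temperature_bin: float | None = 5.0,
) -> pd.DataFrame:
    """Per-temperature MSD table (columns T, msd, msd_err, clamped)."""
    return ElasticScanModel(scan, q2_window, msd_divisor, temperature_bin).fit().table


def resilience(temperature, msd, msd_err=None, full: bool = False):
    """Effective force constant <k'> (N/m) from the MSD-vs-T slope.

    Weighted linear regression of <u^2> on T; <k'> = 2 kB / slope with
    the slope converted from A^2/K.  Raises for a non-positive slope.
    """
    from .guinier import _weighted_line

    t = np.asarray(temperature, float)
    u = np.asarray(msd, float)
    if len(t) < 3:
        raise ValueError("need >= 3 temperatures for a resilience estimate")
    if msd_err is not None:
        s = np.asarray(msd_err, float)
        with np.errstate(divide="ignore"):
            w = np.where(s > 0, 1.0 / s**2, 0.0)
        if np.all(w == 0):
            w = np.ones_like(u)
    else:
        w = np.ones_like(u)
    a, b, cov = _weighted_line(t, u, w)
    resid = u - (a + b * t)
    dof = len(t) - 2
    scale = float(np.sum(w * resid**2) / dof) if dof > 0 else 0.0
    if msd_err is None:
        cov = cov * scale
    else:
        cov = cov * max(scale, 1.0)
    if b <= 0 or b * np.ptp(t) < 1e-9 * max(np.max(np.abs(u)), 1e-30):
        raise ValueError("MSD does not increase with temperature; resilience undefined")
    k = TWO_KB_OVER_A2 / b
    slope_err = float(np.sqrt(max(cov[1, 1], 0.0)))
    k_err = k * slope_err / b
    if full:
        return float(k), float(k_err), float(b), slope_err, resid
    return float(k), float(k_err)
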