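"""Scattering length densities for solvents and labeled proteins.

Everything downstream of the SANS contrast-variation analysis rests on
four quantities computed here: the solvent SLD, the protein SLD in that
solvent (labile hydrogens take the solvent's H/D ratio at a configurable
exchange fraction), the protein's contrast-match point, and the excess
scattering length (delta-rho x V) of the protein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .composition import MolecularComposition, ECTOINE
from .constants import (
    AVOGADRO,
    COHERENT_B_FM,
    D2O_DENSITY,
    D2O_MOLAR_MASS,
    FM_TO_CM,
    H2O_DENSITY,
    H2O_MOLAR_MASS,
)

__all__ = [
    "SolventSpec",
    "ContrastCondition",
    "water_sld",
    "solvent_sld",
    "protein_sld",
    "match_point",
    "particle_volume",
    "contrast_condition",
    "calibrate_matchout_deuteration",
]


def water_sld(d2o_fraction: float, temperature: float = 25.0,
              h2o_density: float = H2O_DENSITY,
              d2o_density: float = D2O_DENSITY) -> float:
    """SLD (cm-2) of an H2O/D2O mixture, linear in D2O mole fraction.

    The endpoint SLDs are computed from the coherent scattering lengths
    and the mass densities of the isotopic waters (defaults are the
    25 degC values; pass other densities for other temperatures).
    """
    f = float(d2o_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"d2o_fraction {f} outside [0, 1]")
    bH, bD, bO = (COHERENT_B_FM[s] for s in ("H", "D", "O"))
    sld_h2o = (2 * bH + bO) * FM_TO_CM * h2o_density * AVOGADRO / H2O_MOLAR_MASS
    sld_d2o = (2 * bD + bO) * FM_TO_CM * d2o_density * AVOGADRO / D2O_MOLAR_MASS
    return (1.0 - f) * sld_h2o + f * sld_d2o


@dataclass(frozen=True)
class SolventSpec:
    """One aqueous solvent: isotopic water plus an optional osmolyte.

    ``d2o_fraction`` is the D2O mole fraction of the water component;
    ``molarity`` the osmolyte concentration (mol/L); the osmolyte's
    exchangeable H take the solvent H/D ratio and its non-labile H are
    deuterated at ``osmolyte_deuteration``.
    """

    d2o_fraction: float
    molarity: float = 0.0
    osmolyte_deuteration: float = 0.0
    temperature: float = 25.0
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.d2o_fraction <= 1.0:
            raise ValueError("d2o_fraction outside [0, 1]")
        if self.molarity < 0:
            raise ValueError("molarity must be >= 0")
        if not 0.0 <= self.osmolyte_deuteration <= 1.0:
            raise ValueError("osmolyte_deuteration outside [0, 1]")


def solvent_sld(spec: SolventSpec, osmolyte: MolecularComposition = ECTOINE) -> float:
    """Volume-additive solvent SLD (cm-2).

    Per litre, the osmolyte contributes its scattering length at
    ``molarity`` mol and occupies ``molarity x molar_volume`` cm3; water
    fills the remaining volume at the SLD of the given isotopic mix.
    """
    f = spec.d2o_fraction
    n = spec.molarity
    if n == 0.0:
        return water_sld(f, spec.temperature)
    v_osm = n * osmolyte.volume_cm3_per_mol  # cm3 per litre
    if v_osm >= 1000.0:
        raise ValueError(
            f"infeasible composition: {n} M x {osmolyte.volume_cm3_per_mol} cm3/mol "
            "exceeds one litre"
        )
    b_osm = n * AVOGADRO * osmolyte.scattering_length_cm(
        deuteration=spec.osmolyte_deuteration, labile_d_occupancy=f
    )
    return (b_osm + water_sld(f, spec.temperature) * (1000.0 - v_osm)) / 1000.0


def protein_sld(
    comp: MolecularComposition,
    deuteration: float = 0.0,
    exchange_fraction: float = 0.85,
    solvent_d2o_fraction: float = 0.0,
) -> float:
    """Protein SLD (cm-2) in a solvent of given D2O fraction.

    Non-labile H carry D at ``deuteration``; labile H carry D at
    ``exchange_fraction x solvent_d2o_fraction``.  The volume is the dry
    partial volume M.vbar/NA of the protiated formula (deuteration is
    assumed not to change the partial volume).
    """
    for name, x in (("deuteration", deuteration),
                    ("exchange_fraction", exchange_fraction),
                    ("solvent_d2o_fraction", solvent_d2o_fraction)):
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"{name} {x} outside [0, 1]")
    b = comp.scattering_length_cm(
        deuteration=deuteration,
        labile_d_occupancy=exchange_fraction * solvent_d2o_fraction,
    )
    return b / comp.volume_cm3


def match_point(
    comp: MolecularComposition,
    deuteration: float = 0.0,
    exchange_fraction: float = 0.85,
    search_max: float = 1.05,
) -> float:
    """Contrast-match point as % D2O.

    Root of protein SLD minus water SLD over D2O fraction in
    [0, search_max] (the water SLD line is extrapolated linearly above
    100%).  Raises ``ValueError`` when the protein never matches the
    solvent in range; returns 0.0 for the degenerate always-matched
    case.
    """

    def diff(f: float) -> float:
        b = comp.scattering_length_cm(
            deuteration=deuteration,
            labile_d_occupancy=min(1.0, exchange_fraction * f),
        )
        w = water_sld(0.0) + f * (water_sld(1.0) - water_sld(0.0))
        return b / comp.volume_cm3 - w

    lo, hi = diff(0.0), diff(search_max)
    scale = abs(water_sld(1.0))
    if abs(lo) < 1e-6 * scale and abs(hi) < 1e-6 * scale:
        return 0.0  # degenerate: matched everywhere
    if lo * hi > 0:
        raise ValueError("no contrast match point in [0, %g] D2O fraction" % search_max)
    return 100.0 * brentq(diff, 0.0, search_max, xtol=1e-12)


def calibrate_matchout_deuteration(
    comp: MolecularComposition,
    target_d2o_fraction: float = 1.0,
    exchange_fraction: float = 0.85,
) -> float:
    """Non-labile deuteration level that matches the protein out at the
    given D2O fraction (SLD equal to the water SLD there)."""
    target = water_sld(target_d2o_fraction)

    def diff(d: float) -> float:
        return protein_sld(comp, d, exchange_fraction, target_d2o_fraction) - target

    if diff(0.0) * diff(1.0) > 0:
        raise ValueError("no deuteration level matches out at the requested D2O fraction")
    return brentq(diff, 0.0, 1.0, xtol=1e-12)


def particle_volume(molar_mass: float, partial_specific_volume: float) -> float:
    """Volume of one particle, cm3: M.vbar/NA."""
    if molar_mass <= 0 or partial_specific_volume <= 0:
        raise ValueError("molar_mass and partial_specific_volume must be > 0")
    return molar_mass * partial_specific_volume / AVOGADRO


@dataclass(frozen=True)
class ContrastCondition:
    """One (sample, solvent) pairing of the contrast-variation series.

    ``protein_excess_cm`` is (delta-rho x V) of the bare protein;
    ``hydration_contrast`` the SLD contrast of the (denser-water)
    hydration shell against this solvent.  ``f1`` — the fractional
    protein contribution to the particle amplitude — is computed by the
    hydration-shell model once X is known, not stored here.
    """

    label: str
    solvent_sld: float  # cm-2
    protein_sld: float  # cm-2
    protein_volume: float  # cm3
    hydration_contrast: float  # cm-2
    d2o_fraction: float

    @property
    def protein_contrast(self) -> float:
        return self.protein_sld - self.solvent_sld

    @property
    def protein_excess_cm(self) -> float:
        """(delta-rho x V) of the protein component, cm."""
        return self.protein_contrast * self.protein_volume

    def hydration_excess_cm(self, shell_to_protein_volume_ratio: float) -> float:
        """(delta-rho x V) of the shell at volume ratio X, cm."""
        return (
            shell_to_protein_volume_ratio
            * self.protein_volume
            * self.hydration_contrast
        )


def contrast_condition(
    comp: MolecularComposition,
    solvent_sld_value: float,
    d2o_fraction: float,
    deuteration: float = 0.0,
    exchange_fraction: float = 0.85,
    shell_density_factor: float = 1.1,
    label: str = "",
) -> ContrastCondition:
    """Build a :class:`ContrastCondition` from first principles.

    The hydration shell is assumed to be pure water of the solvent's
    isotopic composition, ``shell_density_factor`` denser than bulk, so
    its SLD is that factor times the bulk-water SLD; its contrast is
    taken against the full (osmolyte-containing) solvent SLD.
    """
    if shell_density_factor <= 0:
        raise ValueError("shell_density_factor must be > 0")
    rho_p = protein_sld(comp, deuteration, exchange_fraction, d2o_fraction)
    shell_sld = shell_density_factor * water_sld(d2o_fraction)
    return ContrastCondition(
        label=label or comp.name,
        solvent_sld=solvent_sld_value,
        protein_sld=rho_p,
        protein_volume=comp.volume_cm3,
        hydration_contrast=shell_sld - solvent_sld_value,
        d2o_fraction=d2o_fraction,
    )
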