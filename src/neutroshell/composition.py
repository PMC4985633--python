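"""Molecular compositions for scattering-length-density bookkeeping.

A :class:`MolecularComposition` is the single source of every SLD
computed in this package: element counts per formula unit, the number of
labile (solvent-exchangeable) hydrogens, the molar mass and a partial
specific (cm3/g) or partial molar (cm3/mol) volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

from .constants import AVOGADRO, COHERENT_B_FM, FM_TO_CM


@dataclass(frozen=True)
class MolecularComposition:
    """Element counts plus the bookkeeping needed for SLD work.

    Parameters
    ----------
    elements
        Mapping element symbol -> count per formula unit.  ``H`` counts
        *all* hydrogens (labile and non-labile); deuteration is applied
        at SLD-computation time, not stored here.
    labile_h
        Number of hydrogens that exchange with solvent (0 <= labile_h
        <= elements['H']).
    molar_mass
        g/mol of the protiated formula unit.
    specific_volume
        Partial specific volume, cm3/g.  Exactly one of
        ``specific_volume`` / ``molar_volume`` must be given.
    molar_volume
        Partial molar volume, cm3/mol.
    name
        Free-text label carried through reports.
    """

    elements: dict[str, float]
    labile_h: float = 0.0
    molar_mass: float = 0.0
    specific_volume: float | None = None
    molar_volume: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        for sym, n in self.elements.items():
            if sym not in COHERENT_B_FM:
                raise ValueError(f"no scattering length for element {sym!r}")
            if n < 0:
                raise ValueError(f"negative count for element {sym!r}")
        if self.labile_h < 0:
            raise ValueError("labile_h must be >= 0")
        if self.labile_h > self.elements.get("H", 0.0) + 1e-9:
            raise ValueError("labile_h exceeds total H count")
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be > 0")
        if (self.specific_volume is None) == (self.molar_volume is None):
            raise ValueError("give exactly one of specific_volume / molar_volume")
        vol = self.volume_cm3_per_mol
        if not vol > 0:
            raise ValueError("volume must be > 0")

    @property
    def volume_cm3_per_mol(self) -> float:
        if self.molar_volume is not None:
            return self.molar_volume
        assert self.specific_volume is not None
        return self.specific_volume * self.molar_mass

    @property
    def volume_cm3(self) -> float:
        """Volume of one formula unit, cm3."""
        return self.volume_cm3_per_mol / AVOGADRO

    def scattering_length_cm(
        self,
        deuteration: float = 0.0,
        labile_d_occupancy: float = 0.0,
    ) -> float:
        """Total coherent scattering length of one formula unit, cm.

        ``deuteration`` is the D occupancy of non-labile H sites;
        ``labile_d_occupancy`` that of labile sites (usually
        exchange_fraction x solvent D2O fraction).
        """
        if not 0.0 <= deuteration <= 1.0:
            raise ValueError("deuteration outside [0, 1]")
        if not 0.0 <= labile_d_occupancy <= 1.0:
            raise ValueError("labile_d_occupancy outside [0, 1]")
        bH, bD = COHERENT_B_FM["H"], COHERENT_B_FM["D"]
        total = 0.0
        for sym, n in self.elements.items():
            if sym == "H":
                continue
            total += n * COHERENT_B_FM[sym]
        n_h = self.elements.get("H", 0.0)
        n_lab = self.labile_h
        n_fix = n_h - n_lab
        total += n_fix * ((1.0 - deuteration) * bH + deuteration * bD)
        total += n_lab * ((1.0 - labile_d_occupancy) * bH + labile_d_occupancy * bD)
        return total * FM_TO_CM

    def with_name(self, name: str) -> "MolecularComposition":
        return replace(self, name=name)


# ---------------------------------------------------------------------------
# stock compositions

#: Ectoine, C6H10N2O2 (zwitterion; the two amidinium N-H exchange).
#: The partial molar volume is calibrated once, by least squares, so the
#: volume-additive solvent model reproduces the four published solvent
#: SLDs of the 2 M / 3 M ectoine H2O / D2O series; the implied density
#: 1.38 g/cm3 agrees with ectoine's crystal density (~1.37).
ECTOINE = MolecularComposition(
    elements={"C": 6, "H": 10, "N": 2, "O": 2},
    labile_h=2,
    molar_mass=142.16,
    molar_volume=102.87,
    name="ectoine",
)

# Swiss-Prot average amino-acid frequencies give, per residue, roughly
# C 4.86, H 7.58, N 1.36, O 1.48, S 0.042 and ~1.76 chemically
# exchangeable H (backbone amides less proline, plus side-chain
# OH/NH/SH).  The effective exchangeable count actually realised in a
# folded protein is smaller; CALIBRATED_LABILE_H_PER_RESIDUE is chosen
# so that the computed contrast-match point of a protiated average
# protein (85% exchange) equals the measured 40% D2O.
AVERAGE_RESIDUE_ELEMENTS = {"C": 4.86, "H": 7.58, "N": 1.36, "O": 1.48, "S": 0.042}
CHEMICAL_LABILE_H_PER_RESIDUE = 1.76
CALIBRATED_LABILE_H_PER_RESIDUE = 1.356


def average_protein(
    n_residues: int,
    molar_mass: float,
    specific_volume: float = 0.75,
    labile_h_per_residue: float = CALIBRATED_LABILE_H_PER_RESIDUE,
    name: str = "average protein",
) -> MolecularComposition:
    """Generic globular-protein composition from residue count and mass.

    Element counts scale the Swiss-Prot average residue; use this when
    the exact sequence is unknown.  Match points computed from it are
    approximate at the level of a few percent D2O.
    """
    if n_residues <= 0:
        raise ValueError("n_residues must be > 0")
    els = {sym: n * n_residues for sym, n in AVERAGE_RESIDUE_ELEMENTS.items()}
    return MolecularComposition(
        elements=els,
        labile_h=labile_h_per_residue * n_residues,
        molar_mass=molar_mass,
        specific_volume=specific_volume,
        name=name,
    )


def mbp_like(labile_h_per_residue: float = CALIBRATED_LABILE_H_PER_RESIDUE):
    """Average-composition stand-in for maltose binding protein.

    387 residues, 42490 g/mol, partial specific volume 0.75 cm3/g.
    """
    return average_protein(387, 42490.0, 0.75, labile_h_per_residue, name="MBP (average composition)")


# ---------------------------------------------------------------------------
# key=value composition files

def read_composition(path: str | Path) -> MolecularComposition:
    """Read a composition from simple ``key = value`` text.

    Recognised keys: element symbols (counts), ``labile_h``, ``mass``
    (g/mol), ``vsp`` (cm3/g), ``vmol`` (cm3/mol), ``name``.  Lines
    starting with ``#`` are comments.
    """
    elements: dict[str, float] = {}
    kw: dict[str, object] = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected 'key = value'")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key == "name":
            kw["name"] = val
            continue
        try:
            num = float(val)
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: non-numeric value {val!r}") from exc
        if key in COHERENT_B_FM:
            elements[key] = num
        elif key == "labile_h":
            kw["labile_h"] = num
        elif key == "mass":
            kw["molar_mass"] = num
        elif key == "vsp":
            kw["specific_volume"] = num
        elif key == "vmol":
            kw["molar_volume"] = num
        else:
            raise ValueError(f"{path}:{ln}: unknown key {key!r}")
    return MolecularComposition(elements=elements, **kw)  # type: ignore[arg-type]


def write_composition(comp: MolecularComposition, path: str | Path) -> None:
    lines = [f"# composition: {comp.name}" if comp.name else "# composition"]
    if comp.name:
        lines.append(f"name = {comp.name}")
    for sym, n in comp.elements.items():
        lines.append(f"{sym} = {n:g}")
    lines.append(f"labile_h = {comp.labile_h:g}")
    lines.append(f"mass = {comp.molar_mass:g}")
    if comp.specific_volume is not None:
        lines.append(f"vsp = {comp.specific_volume:g}")
    else:
        lines.append(f"vmol = {comp.molar_volume:g}")
    Path(path).write_text("\n".join(lines) + "\n")
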