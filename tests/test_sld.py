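"""Scattering-length-density bookkeeping: solvents, proteins, match points."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neutroshell.composition import (
    ECTOINE,
    CHEMICAL_LABILE_H_PER_RESIDUE,
    MolecularComposition,
    average_protein,
    mbp_like,
)
from neutroshell.constants import AVOGADRO, COHERENT_B_FM, FM_TO_CM
from neutroshell.sld import (
    SolventSpec,
    calibrate_matchout_deuteration,
    contrast_condition,
    match_point,
    particle_volume,
    protein_sld,
    solvent_sld,
    water_sld,
)


class TestWaterSLD:
    def test_pure_h2o_endpoint(self):
        # sum b(H2O) = -1.675 fm at density 0.99707 g/cm3
        assert water_sld(0.0) == pytest.approx(-0.56e10, abs=0.01e10)

    def test_pure_d2o_endpoint(self):
        # sum b(D2O) = +19.15 fm at density 1.1044 g/cm3
        assert water_sld(1.0) == pytest.approx(6.36e10, abs=0.01e10)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_monotone_in_d2o_fraction(self, f1, f2):
        lo, hi = sorted([f1, f2])
        assert water_sld(lo) <= water_sld(hi)

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            water_sld(bad)


class TestSolventSLD:
    @pytest.mark.parametrize(
        "molarity,f,published_1e10",
        [(2, 0.0, -0.074), (3, 0.0, 0.205), (2, 1.0, 5.70), (3, 1.0, 5.36)],
    )
    def test_computed_mode_reproduces_published_series(self, molarity, f, published_1e10):
        """Volume-additive mixing with the calibrated ectoine molar volume
        matches the four published ectoine solvent SLDs."""
        got = solvent_sld(SolventSpec(f, molarity), ECTOINE)
        assert got == pytest.approx(published_1e10 * 1e10, abs=0.03e10)

    def test_zero_molarity_is_water(self):
        assert solvent_sld(SolventSpec(0.7, 0.0)) == water_sld(0.7)

    def test_linear_in_d2o_fraction_at_fixed_molarity(self):
        a, m, b = (solvent_sld(SolventSpec(f, 2.0)) for f in (0.0, 0.5, 1.0))
        assert m == pytest.approx(0.5 * (a + b), rel=1e-12)

    def test_infeasible_composition(self):
        big = MolecularComposition({"C": 1, "H": 1}, 0, 13.0, molar_volume=600.0)
        with pytest.raises(ValueError, match="infeasible"):
            solvent_sld(SolventSpec(0.0, 2.0), big)


class TestProteinSLD:
    def test_brute_force_oracle(self, mbp):
        """At zero deuteration and zero exchange the SLD equals a direct
        sum(count x b)/volume evaluation."""
        total_fm = sum(n * COHERENT_B_FM[sym] for sym, n in mbp.elements.items())
        vol = mbp.molar_mass * 0.75 / AVOGADRO
        oracle = total_fm * FM_TO_CM / vol
        got = protein_sld(mbp, deuteration=0.0, exchange_fraction=0.0,
                          solvent_d2o_fraction=1.0)
        assert got == pytest.approx(oracle, rel=1e-6)

    def test_protiated_protein_band(self, mbp):
        assert 1.7e10 < protein_sld(mbp, 0.0, 0.85, 0.0) < 2.0e10

    def test_zero_exchange_solvent_independent(self, mbp):
        vals = [protein_sld(mbp, 0.3, 0.0, f) for f in (0.0, 0.5, 1.0)]
        assert np.ptp(vals) == 0.0

    def test_matchout_definition(self, mbp, matchout_deuteration):
        got = protein_sld(mbp, matchout_deuteration, 0.85, 1.0)
        assert got == pytest.approx(water_sld(1.0), rel=1e-9)


class TestMatchPoint:
    def test_protiated_generic_protein(self, mbp):
        assert 40.0 - 0.5 < match_point(mbp) < 45.0

    def test_chemical_labile_count_still_in_band(self):
        comp = average_protein(387, 42490.0,
                               labile_h_per_residue=CHEMICAL_LABILE_H_PER_RESIDUE)
        assert 40.0 < match_point(comp) < 45.0

    def test_matchout_labeled_protein(self, mbp, matchout_deuteration):
        assert match_point(mbp, matchout_deuteration) == pytest.approx(100.0, abs=0.01)

    def test_residual_at_match(self, mbp):
        f = match_point(mbp) / 100.0
        resid = protein_sld(mbp, 0.0, 0.85, f) - water_sld(f)
        assert abs(resid) < 1e-4 * abs(water_sld(1.0))

    def test_fully_deuterated_never_matches(self, mbp):
        with pytest.raises(ValueError, match="no contrast match"):
            match_point(mbp, deuteration=1.0)

    def test_degenerate_always_matched(self):
        """A composition whose SLD tracks the water line exactly matches
        at every D2O fraction; reported as 0 rather than an arbitrary root."""
        labile = 2.0
        slope = water_sld(1.0) - water_sld(0.0)
        vol = 0.85 * labile * (COHERENT_B_FM["D"] - COHERENT_B_FM["H"]) * FM_TO_CM / slope
        b0_fm = water_sld(0.0) * vol / FM_TO_CM
        o_count = (b0_fm - 2 * COHERENT_B_FM["H"]) / COHERENT_B_FM["O"]
        comp = MolecularComposition(
            {"H": 2, "O": o_count}, labile_h=labile, molar_mass=20.0,
            molar_volume=vol * AVOGADRO,
        )
        assert match_point(comp) == 0.0


class TestParticleVolume:
    def test_published_mass(self):
        # 42490 g/mol at 0.75 cm3/g
        assert particle_volume(42490.0, 0.75) == pytest.approx(5.29e-20, rel=2e-3)

    def test_linearity_and_errors(self):
        assert particle_volume(2000.0, 0.75) == 2 * particle_volume(1000.0, 0.75)
        with pytest.raises(ValueError):
            particle_volume(0.0, 0.75)


class TestContrastCondition:
    def test_excess_identity(self, mbp):
        cond = contrast_condition(mbp, 0.205e10, 0.0, label="h2o")
        assert cond.protein_excess_cm == pytest.approx(
            (cond.protein_sld - cond.solvent_sld) * cond.protein_volume
        )

    def test_shell_contrast_sign(self, mbp):
        """Dense-water shell is below an ectoine-H2O solvent in SLD and
        above an ectoine-D2O solvent."""
        h2o = contrast_condition(mbp, 0.205e10, 0.0)
        d2o = contrast_condition(mbp, 5.36e10, 1.0)
        assert h2o.hydration_contrast < 0 < d2o.hydration_contrast

    def test_calibrated_deuteration_plausible(self, matchout_deuteration):
        """Growth on protiated glycerol in 85% D2O yields partial non-labile
        deuteration; the match-out-pinned level must sit well inside (0, 1)."""
        assert 0.6 < matchout_deuteration < 0.9
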