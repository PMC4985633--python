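"""Structure-factor transforms, peak extraction and H-bond geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neutroshell.liquids import (
    IntraMolecularPair,
    RadialDistribution,
    StructureFactor,
    gr_to_sq,
    hbond_beta,
    hbond_geometry,
    hbond_theta,
    number_density,
    peak_positions,
    sq_to_gr,
    subtract_intramolecular,
    water_intra_angle,
)
from neutroshell.synthetic import make_structure_factor

RHO0 = 0.1  # atoms/A^3, water-like
Q_INSTRUMENT = np.arange(0.22, 23.5 + 1e-9, 0.02)  # measured range


def gaussian_rdf(distances, amps=None, width=0.08):
    r = np.arange(0.005, 12.0, 0.005)
    g = np.ones_like(r)
    amps = amps or [1.0] * len(distances)
    for d, a in zip(distances, amps):
        g = g + a * np.exp(-((r - d) ** 2) / (2 * width**2))
    return RadialDistribution(r=r, g=g, rho0=RHO0)


class TestTransforms:
    def test_unit_structure_factor_fixed_point(self):
        sf = StructureFactor(q=Q_INSTRUMENT, s=np.ones_like(Q_INSTRUMENT), rho0=RHO0)
        for window in ("lorch", "none"):
            rdf = sq_to_gr(sf, window=window)
            assert np.allclose(rdf.g, 1.0, atol=1e-12)

    def test_unit_rdf_fixed_point(self):
        r = np.arange(0.01, 10.0, 0.01)
        sf = gr_to_sq(RadialDistribution(r=r, g=np.ones_like(r), rho0=RHO0))
        assert np.allclose(sf.s, 1.0, atol=1e-12)

    def test_round_trip_max_deviation(self):
        """gr -> sq -> gr over the instrument Q range deviates < 0.02 in
        max norm for a smooth single-shell g(r).

        Plain truncation is used for the fidelity check: the peak decays
        inside Qmax, and the Lorch window would deliberately broaden it.
        """
        rdf = gaussian_rdf([2.80], width=0.12)
        sf = gr_to_sq(rdf, q_grid=Q_INSTRUMENT)
        back = sq_to_gr(sf, r_grid=rdf.r, window="none")
        sel = rdf.r > 0.5  # low-r region is limited by Qmin truncation
        assert np.max(np.abs(back.g[sel] - rdf.g[sel])) < 0.02

    def test_linearity_in_g_minus_one(self):
        rdf1 = gaussian_rdf([2.80], amps=[0.5])
        rdf2 = gaussian_rdf([2.80], amps=[1.0])
        s1 = gr_to_sq(rdf1, q_grid=Q_INSTRUMENT).s - 1.0
        s2 = gr_to_sq(rdf2, q_grid=Q_INSTRUMENT).s - 1.0
        assert np.allclose(s2, 2.0 * s1, atol=1e-10)

    def test_lorch_suppresses_truncation_ripple(self):
        """Ripple amplitude away from the real peak is at least 3x smaller
        with the Lorch window than with plain truncation."""
        rdf = gaussian_rdf([2.80], width=0.04)
        sf = gr_to_sq(rdf, q_grid=np.arange(0.22, 12.0, 0.02))  # harsh cutoff
        ripple_region = (rdf.r > 4.0) & (rdf.r < 9.0)
        g_none = sq_to_gr(sf, r_grid=rdf.r, window="none").g
        g_lorch = sq_to_gr(sf, r_grid=rdf.r, window="lorch").g
        a_none = np.max(np.abs(g_none[ripple_region] - 1.0))
        a_lorch = np.max(np.abs(g_lorch[ripple_region] - 1.0))
        assert a_lorch < a_none / 3.0

    def test_divergent_tail_rejected(self):
        r = np.arange(0.01, 10.0, 0.01)
        with pytest.raises(ValueError, match="approach 1"):
            gr_to_sq(RadialDistribution(r=r, g=1.0 + 0.2 * r / r[-1], rho0=RHO0))

    def test_non_monotone_q_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            StructureFactor(q=np.array([1.0, 0.5]), s=np.array([1.0, 1.0]), rho0=RHO0)


class TestIntramolecularSubtraction:
    def test_empty_model_identity(self):
        sf, _ = make_structure_factor([2.80])
        out = subtract_intramolecular(sf, [])
        assert np.array_equal(out.s, sf.s)

    def test_single_pair_removes_peak(self):
        """Adding the sinc term of one broadened distance and subtracting
        the same pair restores a featureless g(r)."""
        pair = IntraMolecularPair("OD", 0.98, 0.5, 0.005)
        q = Q_INSTRUMENT
        s = 1.0 + pair.weight * np.sin(q * pair.distance) / (q * pair.distance) * np.exp(
            -pair.gamma * q**2 / 2
        )
        sf = StructureFactor(q=q, s=s, rho0=RHO0)
        g_before = sq_to_gr(sf).g
        g_after = sq_to_gr(subtract_intramolecular(sf, [pair])).g
        assert np.max(np.abs(g_after - 1.0)) < 1e-10
        assert np.max(np.abs(g_before - 1.0)) > 0.05

    def test_weight_linearity(self):
        sf, _ = make_structure_factor([2.80])
        p1 = [IntraMolecularPair("a", 1.5, 0.1, 0.005)]
        p2 = [IntraMolecularPair("a", 1.5, 0.2, 0.005)]
        d1 = sf.s - subtract_intramolecular(sf, p1).s
        d2 = sf.s - subtract_intramolecular(sf, p2).s
        assert np.allclose(d2, 2 * d1, atol=1e-14)


class TestPeakPositions:
    def test_water_like_distances_recovered(self):
        """Peaks of a synthetic S(Q) built from the measured water distance
        set come back within 0.02 A over the instrument Q range."""
        distances = [0.98, 1.51, 1.93, 2.80]
        sf, _ = make_structure_factor(distances, rho0=RHO0, q_grid=Q_INSTRUMENT)
        rdf = sq_to_gr(sf, window="lorch")
        peaks = peak_positions(rdf, r_window=(0.5, 4.0), min_height=1.1)
        got = [p for p, _ in peaks]
        assert len(got) == len(distances)
        for want, have in zip(distances, got):
            assert have == pytest.approx(want, abs=0.02)

    def test_flat_rdf_empty(self):
        r = np.arange(0.01, 5.0, 0.01)
        rdf = RadialDistribution(r=r, g=np.ones_like(r), rho0=RHO0)
        assert peak_positions(rdf) == []

    def test_merged_peaks_single_maximum(self):
        """Two distances closer than the resolution of the grid+width merge
        into one reported maximum."""
        rdf = gaussian_rdf([2.00, 2.005], width=0.08)
        peaks = peak_positions(rdf, r_window=(1.5, 2.5), min_height=1.1)
        assert len(peaks) == 1

    def test_window_outside_grid(self):
        rdf = gaussian_rdf([2.0])
        with pytest.raises(ValueError, match="window"):
            peak_positions(rdf, r_window=(0.0, 20.0))


class TestHBondGeometry:
    def test_right_angle_case(self):
        assert water_intra_angle(1.0, np.sqrt(2.0)) == pytest.approx(90.0)

    def test_collinear_beta_zero(self):
        assert hbond_beta(0.98, 2.80, 2.80 - 0.98) == pytest.approx(0.0, abs=1e-6)

    def test_collinear_theta_straight(self):
        assert hbond_theta(0.98, 2.80 + 0.98 - 1e-12, 2.80) == pytest.approx(180.0, abs=1e-3)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0.8, 1.2), st.floats(10.0, 170.0), st.floats(1.2, 3.5))
    def test_triangle_angle_sum(self, d_od, theta_deg, d_oo_scale):
        """For any valid O-D...O triangle the three internal angles sum to
        180 deg (beta at O, theta at D, remainder at the acceptor O)."""
        # build a consistent triangle from two sides and the included angle
        d_inter = d_oo_scale
        d_oo = np.sqrt(
            d_od**2 + d_inter**2 - 2 * d_od * d_inter * np.cos(np.radians(theta_deg))
        )
        beta = hbond_beta(d_od, d_oo, d_inter)
        theta = hbond_theta(d_od, d_oo, d_inter)
        gamma = np.degrees(
            np.arccos(
                np.clip((d_oo**2 + d_inter**2 - d_od**2) / (2 * d_oo * d_inter), -1, 1)
            )
        )
        assert beta + theta + gamma == pytest.approx(180.0, abs=1e-6)
        assert theta == pytest.approx(theta_deg, abs=1e-6)

    def test_triangle_violation(self):
        with pytest.raises(ValueError, match="triangle"):
            hbond_beta(0.5, 3.0, 1.0)
        with pytest.raises(ValueError, match="triangle"):
            water_intra_angle(0.7, 1.5)

    def test_geometry_bundle_consistency(self):
        g = hbond_geometry(0.98, 1.51, 2.80, 1.93)
        assert g.alpha == water_intra_angle(0.98, 1.51)
        assert g.beta == hbond_beta(0.98, 2.80, 1.93)
        assert g.theta == hbond_theta(0.98, 2.80, 1.93)
        # theta from the measured distances is near (but below) the
        # nominal straight H-bond figure
        assert 145.0 < g.theta < 148.5


class TestNumberDensity:
    def test_ectoine_solution(self):
        """1.5 mol/L solute (20 atoms) with 31 waters per solute gives a
        water-like 0.102 atoms/A^3."""
        assert number_density(1.5, 31.0) == pytest.approx(0.102, abs=0.001)

    def test_requires_positive_molarity(self):
        with pytest.raises(ValueError):
            number_density(0.0, 31.0)
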