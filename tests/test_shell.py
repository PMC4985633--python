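"""Hydration-shell decomposition: ratio model, X fit, Rg decomposition,
shell geometry and the synthetic round trip."""

import numpy as np
import pytest

from neutroshell.shell import (
    HydrationShellModel,
    contrast_ratio_model,
    f1_fraction,
    fit_shell_ratio,
    rg_decomposition,
    shell_geometry,
)
from neutroshell.sld import ContrastCondition
from neutroshell.synthetic import make_contrast_series


def cond(protein_contrast, hydration_contrast, volume=5.29e-20, label="c"):
    return ContrastCondition(
        label=label, solvent_sld=0.0, protein_sld=protein_contrast,
        protein_volume=volume, hydration_contrast=hydration_contrast,
        d2o_fraction=0.0,
    )


class TestContrastRatioModel:
    def test_x_zero_is_bare_protein_ratio(self):
        a, b = cond(5e10, -1e10), cond(1e10, 2e10)
        assert contrast_ratio_model(0.0, a, b) == pytest.approx(5.0)

    def test_no_hydration_contrast_is_constant(self):
        a, b = cond(5e10, 0.0), cond(1e10, 0.0)
        xs = np.linspace(0, 1, 11)
        assert np.ptp(contrast_ratio_model(xs, a, b)) == 0.0

    def test_monotone_when_contrasts_oppose(self):
        """With hydration contrasts of opposite signs the ratio is strictly
        monotone in X (no interior extremum), checked by finite differences."""
        a, b = cond(5e10, -0.8e10), cond(1e10, 1.6e10)
        xs = np.linspace(0, 1, 201)
        diffs = np.diff(contrast_ratio_model(xs, a, b))
        assert np.all(diffs < 0) or np.all(diffs > 0)

    def test_volume_mismatch_rejected(self):
        with pytest.raises(ValueError, match="volume"):
            contrast_ratio_model(0.1, cond(1e10, 0.0), cond(1e10, 0.0, volume=1e-20))


class TestFitShellRatio:
    def test_round_trip_exact(self):
        a, b = cond(5e10, -0.8e10), cond(1e10, 1.6e10)
        target = float(contrast_ratio_model(0.5, a, b))
        x, _ = fit_shell_ratio(target, a, b)
        assert x == pytest.approx(0.5, abs=1e-8)

    def test_zero_sigma_gives_zero_uncertainty(self):
        a, b = cond(5e10, -0.8e10), cond(1e10, 1.6e10)
        _, sx = fit_shell_ratio(float(contrast_ratio_model(0.3, a, b)), a, b, 0.0)
        assert sx == 0.0

    def test_sigma_propagates_through_local_slope(self):
        a, b = cond(5e10, -0.8e10), cond(1e10, 1.6e10)
        r = float(contrast_ratio_model(0.3, a, b))
        _, sx1 = fit_shell_ratio(r, a, b, 0.01)
        _, sx2 = fit_shell_ratio(r, a, b, 0.02)
        assert sx2 == pytest.approx(2 * sx1, rel=1e-6)

    def test_out_of_range_ratio(self):
        a, b = cond(5e10, 0.0), cond(1e10, 0.0)  # R constant = 5
        with pytest.raises(ValueError, match="not attainable"):
            fit_shell_ratio(2.0, a, b)

    def test_denominator_pole_detected(self):
        # denominator amplitude crosses zero almost immediately
        a, b = cond(5e10, -0.8e10), cond(0.01e10, -2e10)
        with pytest.raises(ValueError, match="zero"):
            fit_shell_ratio(3.0, a, b)


class TestF1:
    def test_x_zero(self):
        assert f1_fraction(cond(3e10, -1e10), 0.0) == 1.0

    def test_opposing_contrasts_exceed_one(self):
        assert f1_fraction(cond(3e10, -1e10), 0.3) > 1.0

    def test_equal_terms_give_half(self):
        c = cond(1e10, 1e10)
        assert f1_fraction(c, 1.0) == pytest.approx(0.5)

    def test_overall_match_flagged(self):
        c = cond(1e10, -1e10)
        with pytest.raises(ValueError, match="match"):
            f1_fraction(c, 1.0)


class TestRgDecomposition:
    def test_exact_two_point_recovery(self):
        rp, rh = 25.0, 33.0
        f1 = np.array([0.4, 1.1])
        rg2 = f1 * rp**2 + (1 - f1) * rh**2
        (got_p, _), (got_h, _) = rg_decomposition(rg2, f1)
        assert got_p == pytest.approx(rp, rel=1e-10)
        assert got_h == pytest.approx(rh, rel=1e-10)

    def test_degenerate_design(self):
        with pytest.raises(ValueError, match="distinct"):
            rg_decomposition([600.0, 600.0], [0.8, 0.8])

    def test_imaginary_radius(self):
        with pytest.raises(ValueError, match="negative"):
            rg_decomposition([100.0, 1.0], [1.0, 0.99])


class TestShellGeometry:
    def test_limits_at_x_zero(self):
        g = shell_geometry(25.0, 0.0)
        assert g.shell_thickness == 0.0
        assert g.shell_rg == pytest.approx(25.0)

    def test_volume_identity(self):
        g = shell_geometry(25.0, 0.30)
        r1 = g.protein_radius
        r2 = r1 + g.shell_thickness
        assert r2**3 == pytest.approx(1.30 * r1**3, rel=1e-12)

    def test_monolayer_thickness(self):
        g = shell_geometry(25.0, 0.30)
        assert g.shell_thickness == pytest.approx(2.95, abs=0.05)
        assert g.shell_rg == pytest.approx(33.8, abs=0.15)

    def test_thickness_increasing_in_x(self):
        ts = [shell_geometry(25.0, x).shell_thickness for x in np.linspace(0, 1, 21)]
        assert np.all(np.diff(ts) > 0)


class TestSyntheticRoundTrip:
    def test_noiseless_recovery(self):
        """Forward-model a contrast series from known (X, R_Prot, R_Hyd) and
        recover all three within 1%."""
        table, truth = make_contrast_series(x_true=0.30, r_prot_true=25.0)
        res = HydrationShellModel(
            table, ("D 3M ect H2O", "D 3M ect D2O")
        ).fit()
        assert res.x == pytest.approx(truth["x"], rel=0.01)
        assert res.r_prot == pytest.approx(truth["r_prot"], rel=0.01)
        assert res.r_hyd == pytest.approx(truth["r_hyd"], rel=0.01)

    def test_f1_weighted_identity(self):
        """Particle Rg^2 equals f1 R_P^2 + (1-f1) R_H^2 exactly under the
        forward model."""
        table, truth = make_contrast_series(x_true=0.25, r_prot_true=24.0)
        for _, row in table.iterrows():
            f1 = f1_fraction(row["condition"], truth["x"])
            expect = f1 * truth["r_prot"] ** 2 + (1 - f1) * truth["r_hyd"] ** 2
            assert row["rg"] ** 2 == pytest.approx(expect, rel=1e-12)

    def test_noisy_recovery_ensemble(self):
        """2% noise, 100 replicates: mean recovered X within 0.05 and mean
        radii within 1 A of truth."""
        xs, rps, rhs = [], [], []
        for k in range(100):
            table, truth = make_contrast_series(
                x_true=0.30, r_prot_true=25.0, noise=0.02, seed=1000 + k
            )
            res = HydrationShellModel(table, ("D 3M ect H2O", "D 3M ect D2O")).fit()
            xs.append(res.x)
            rps.append(res.r_prot)
            rhs.append(res.r_hyd)
        table, truth = make_contrast_series(x_true=0.30, r_prot_true=25.0)
        assert abs(np.mean(xs) - truth["x"]) < 0.05
        assert abs(np.mean(rps) - truth["r_prot"]) < 1.0
        assert abs(np.mean(rhs) - truth["r_hyd"]) < 1.0
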