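"""Generators: physical closed forms, determinism, parameter validation."""

import math

import numpy as np
import pandas as pd
import pytest

from tenomech import (InvalidParameterError, ProbeConfig, SLSMaterial,
                      delta_ct, fold_change_ddct, first_detection_day,
                      segment_phases, simulate_ct_table, simulate_diameters,
                      simulate_elastic_curve, simulate_orientations,
                      simulate_relaxation_record)
from tenomech.errors import ConfigurationError


class TestElasticCurve:
    def test_matches_hertz_closed_form(self):
        """F(h=1 um) = (4/3)*1000*sqrt(25 um)*(1 um)^1.5 = 6.67 nN."""
        probe = ProbeConfig(R_tip=25.0)
        rec = simulate_elastic_curve(1000.0, probe, max_depth=2.0)
        h = (rec.z - probe.z_contact) - rec.F / probe.k_cant
        F_at_1um = np.interp(1.0, h, rec.F)
        assert F_at_1um * 1e3 == pytest.approx(6.6667, rel=1e-3)  # nN

    def test_zero_force_before_contact(self, probe):
        rec = simulate_elastic_curve(1300.0, probe)
        pre = rec.z < probe.z_contact
        assert np.all(rec.F[pre] == 0.0)

    def test_base_advances_at_constant_speed(self, probe):
        rec = simulate_elastic_curve(1300.0, probe)
        assert np.allclose(np.diff(rec.z) * probe.rate, probe.speed)

    def test_seeded_determinism(self):
        probe = ProbeConfig(noise_sd=1.0, seed=42)
        a = simulate_elastic_curve(1300.0, probe)
        b = simulate_elastic_curve(1300.0, probe)
        assert np.array_equal(a.F, b.F) and np.array_equal(a.z, b.z)
        c = simulate_elastic_curve(1300.0, ProbeConfig(noise_sd=1.0, seed=43))
        assert not np.array_equal(a.F, c.F)

    @pytest.mark.parametrize("bad", [0.0, -5.0])
    def test_nonpositive_modulus_rejected(self, probe, bad):
        with pytest.raises(InvalidParameterError):
            simulate_elastic_curve(bad, probe)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(InvalidParameterError):
            ProbeConfig(R_tip=0.0)


class TestSLSMaterial:
    def test_invariants_enforced(self):
        with pytest.raises(InvalidParameterError):
            SLSMaterial(E0=-1.0, E_inf=0.5, tau=1.0)
        with pytest.raises(InvalidParameterError):
            SLSMaterial(E0=1.0, E_inf=2.0, tau=1.0)  # E_inf > E0
        with pytest.raises(InvalidParameterError):
            SLSMaterial(E0=1.0, E_inf=0.5, tau=0.0)

    def test_from_relaxation_round_trip(self):
        for target in (35.0, 24.0, 23.0):
            mat = SLSMaterial.from_relaxation(target, tau=2.0)
            assert mat.relaxation_percentage(10.0) == pytest.approx(target)

    def test_alpha_0648_tau_2_gives_35pct(self):
        mat = SLSMaterial(E0=1000.0, E_inf=648.0, tau=2.0)
        expect = 100 * (1 - 0.648) * (1 - math.exp(-5))
        assert mat.relaxation_percentage() == pytest.approx(expect)
        assert expect == pytest.approx(35.0, abs=0.05)


class TestRelaxationRecord:
    def test_elastic_limit_flat_hold(self, probe):
        mat = SLSMaterial(E0=1300.0, E_inf=1300.0, tau=2.0)
        rec = simulate_relaxation_record(mat, probe)
        seg = segment_phases(rec)
        Fh = rec.F[seg.hold.start:seg.hold.stop]
        assert np.allclose(Fh, Fh[0])

    def test_instantaneous_relaxation_limit(self, probe):
        mat = SLSMaterial(E0=1300.0, E_inf=650.0, tau=1e-4)
        rec = simulate_relaxation_record(mat, probe)
        seg = segment_phases(rec)
        Fh = rec.F[seg.hold.start:seg.hold.stop]
        # after a few tau the hold force sits at alpha * F_max
        assert Fh[10:].max() == pytest.approx(0.5 * Fh[0], rel=1e-3)

    def test_hold_follows_sls_closed_form(self, probe, sls_day0):
        rec = simulate_relaxation_record(sls_day0, probe)
        seg = segment_phases(rec)
        t = rec.t[seg.hold.start:seg.hold.stop]
        F = rec.F[seg.hold.start:seg.hold.stop]
        a = sls_day0.alpha
        model = F[0] * (a + (1 - a) * np.exp(-(t - t[0]) / sls_day0.tau))
        assert np.allclose(F, model, rtol=1e-12)

    def test_coupled_mode_relaxes_less_than_rigid(self, probe, sls_day0):
        """Open-loop compliance feeds indentation back as force decays, so
        the force loses less than in the ideal rigid hold."""
        rigid = simulate_relaxation_record(sls_day0, probe, mode="rigid")
        coupled = simulate_relaxation_record(sls_day0, probe, mode="coupled")
        drop = lambda r: (r.F[segment_phases(r).hold.start]
                          - r.F[segment_phases(r).hold.stop - 1])
        assert 0 < drop(coupled) < drop(rigid)

    def test_invalid_material_rejected(self, probe):
        with pytest.raises(InvalidParameterError):
            simulate_relaxation_record(
                SLSMaterial(1300.0, 650.0, 2.0), probe, mode="viscous")


class TestCtTable:
    def test_null_simulation_gives_fold_one(self):
        effects = {"COL1A1": {d: 0.0 for d in (0, 2, 4, 7, 14, 21)}}
        ct = simulate_ct_table(effects, n_reps=4, noise_sd=0.0)
        fc = fold_change_ddct(delta_ct(ct), control_day=0)
        assert np.allclose(fc["fold"], 1.0)

    def test_injected_log2_effect_recovered_exactly(self):
        effects = {"GENE": {0: 0.0, 7: 1.0}}
        ct = simulate_ct_table(effects, n_reps=3, noise_sd=0.0,
                               days=(0, 7))
        fc = fold_change_ddct(delta_ct(ct), control_day=0)
        assert np.allclose(fc.loc[fc["day"] == 7, "fold"], 2.0)

    def test_undetected_until_day4_detection_call(self):
        effects = {"MKX": {0: math.nan, 2: math.nan, 4: 0.0, 7: 1.0,
                           14: 1.5, 21: 2.0}}
        ct = simulate_ct_table(effects, n_reps=4, noise_sd=0.0)
        assert first_detection_day(ct, "MKX") == 4
        assert not ct.loc[(ct.gene == "MKX") & (ct.day < 4),
                          "detected"].any()

    def test_reference_gene_present_and_protected(self):
        ct = simulate_ct_table({"G": {0: 0.0}}, n_reps=3, days=(0,))
        assert (ct["gene"] == "YWHAZ").sum() == 3
        with pytest.raises(ConfigurationError):
            simulate_ct_table({"YWHAZ": {0: 0.0}}, n_reps=3)

    def test_seeded_determinism(self):
        eff = {"G": {0: 0.0, 7: 1.0}}
        a = simulate_ct_table(eff, n_reps=3, seed=7)
        b = simulate_ct_table(eff, n_reps=3, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestOrientations:
    def test_zero_dispersion_all_aligned(self):
        df = simulate_orientations({0: 0.0}, n_cells=20)
        assert np.allclose(df["angle_deg"], 0.0)

    def test_uniform_mean_45_degrees(self):
        df = simulate_orientations({0: 0.0}, n_cells=200, n_constructs=20,
                                   seed=5, distribution="uniform")
        assert df["angle_deg"].mean() == pytest.approx(45.0, abs=1.5)
        assert df["angle_deg"].between(0, 90).all()

    def test_angles_folded_into_quadrant(self):
        df = simulate_orientations({0: 500.0}, n_cells=100, seed=3)
        assert df["angle_deg"].between(0, 90).all()

    def test_seeded_determinism(self):
        a = simulate_orientations({0: 20.0}, seed=9)
        b = simulate_orientations({0: 20.0}, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestDiameters:
    def test_zero_sd_gives_exact_means(self):
        df = simulate_diameters({0: 2.08}, {0: 0.0}, n_per_day=5)
        assert np.allclose(df["diameter_mm"], 2.08)

    def test_defaults_match_printed_day0_mean(self):
        df = simulate_diameters(n_per_day=4000, seed=11)
        d0 = df.loc[df["day"] == 0, "diameter_mm"]
        assert d0.mean() == pytest.approx(2.08, abs=0.01)
        assert d0.std(ddof=1) == pytest.approx(0.08, abs=0.01)

    def test_seeded_determinism_and_positivity(self):
        a = simulate_diameters(seed=2)
        b = simulate_diameters(seed=2)
        pd.testing.assert_frame_equal(a, b)
        assert (a["diameter_mm"] > 0).all()
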