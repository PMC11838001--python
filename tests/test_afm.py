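"""Contact-model evaluation, contact-point detection, and E extraction."""

import math

import numpy as np
import pytest

from cellmech.afm import (
    ContactFitResult,
    ForceCurve,
    ForceMap,
    ProbeGeometry,
    compute_indentation,
    eval_cone,
    eval_sphere_dmt,
    find_contact_point,
    fit_contact_model,
    fit_force_map,
    summarize_force_map,
)
from cellmech.simulate import gen_force_curve


def oracle_sphere_dmt(E, R, nu, gamma, delta):
    """Independent arithmetic evaluation via the reduced modulus form."""
    E_star = E / (1.0 - nu * nu)
    hertz = (4.0 / 3.0) * E_star * math.sqrt(R * delta * delta * delta)
    return hertz - 2.0 * math.pi * gamma * R


def oracle_cone(E, theta, nu, delta):
    E_star = E / (1.0 - nu * nu)
    return (2.0 / math.pi) * E_star * math.tan(theta) * delta * delta


class TestClosedForms:
    def test_sphere_dmt_printed_value(self):
        # 10 kPa, R=2.5 um, nu=0.5, gamma=0, delta=100 nm -> ~0.889 nN
        P = eval_sphere_dmt(10e3, 2.5e-6, 0.5, 0.0, 100e-9)
        assert P == pytest.approx(0.889e-9, rel=5e-3)
        assert P == pytest.approx(oracle_sphere_dmt(10e3, 2.5e-6, 0.5, 0.0, 100e-9),
                                  rel=1e-12)

    def test_cone_printed_value(self):
        # 10 kPa, theta=3.9 deg, nu=0.5, delta=1 um -> ~0.579 nN
        theta = math.radians(3.9)
        P = eval_cone(10e3, theta, 0.5, 1e-6)
        assert P == pytest.approx(0.579e-9, rel=5e-3)
        assert P == pytest.approx(oracle_cone(10e3, theta, 0.5, 1e-6), rel=1e-12)

    @pytest.mark.parametrize(
        "E,R,nu,gamma,delta",
        [(8e3, 2.5e-6, 0.5, 0.0, 50e-9),
         (30e3, 1e-6, 0.3, 1e-3, 200e-9),
         (0.5e3, 5e-6, 0.5, 2e-3, 1e-6)],
    )
    def test_sphere_matches_oracle(self, E, R, nu, gamma, delta):
        assert eval_sphere_dmt(E, R, nu, gamma, delta) == pytest.approx(
            oracle_sphere_dmt(E, R, nu, gamma, delta), rel=1e-12)

    def test_adhesion_only_offset(self):
        # delta=0: pure DMT adhesion term -2 pi gamma R
        P = eval_sphere_dmt(10e3, 2.5e-6, 0.5, 1e-3, 0.0)
        assert P == pytest.approx(-2 * math.pi * 1e-3 * 2.5e-6, rel=1e-12)
        assert eval_sphere_dmt(10e3, 2.5e-6, 0.5, 0.0, 0.0) == 0.0

    def test_sphere_gamma_zero_is_hertz(self):
        delta = np.linspace(0, 300e-9, 20)
        dmt = eval_sphere_dmt(12e3, 2.5e-6, 0.5, 0.0, delta)
        hertz = 4.0 * 12e3 * np.sqrt(2.5e-6) / (3 * 0.75) * delta**1.5
        np.testing.assert_allclose(dmt, hertz, rtol=1e-12)

    def test_cone_quadratic_law(self):
        theta = math.radians(20)
        assert eval_cone(5e3, theta, 0.5, 2e-7) == pytest.approx(
            4 * eval_cone(5e3, theta, 0.5, 1e-7), rel=1e-12)
        assert eval_cone(5e3, theta, 0.5, 0.0) == 0.0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            eval_sphere_dmt(1e3, 1e-6, 1.0, 0.0, 1e-9)
        with pytest.raises(ValueError):
            eval_cone(1e3, math.pi / 2, 0.5, 1e-9)
        with pytest.raises(ValueError, match="supported"):
            ProbeGeometry(kind="pyramid", spring_constant=0.03)


class TestContactPoint:
    def test_noiseless_within_one_sample(self, sphere_probe):
        curve = gen_force_curve(8e3, sphere_probe, noise_sd=0, seed=0)
        dz = np.diff(curve.z).max()
        assert abs(find_contact_point(curve) - 5e-6) <= dz

    def test_flat_curve_no_contact(self, sphere_probe):
        z = np.linspace(0, 1e-6, 200)
        curve = ForceCurve(z=z, force=np.zeros_like(z), probe=sphere_probe,
                           trigger_force=2e-9)
        with pytest.raises(ValueError, match="no contact"):
            find_contact_point(curve)

    def test_noisy_detection_within_50nm(self, sphere_probe):
        # 2% of the 2 nN trigger as force noise, 100 seeds
        errs = []
        for seed in range(100):
            curve = gen_force_curve(8e3, sphere_probe, noise_sd=0.02 * 2e-9,
                                    seed=seed)
            errs.append(abs(find_contact_point(curve) - 5e-6))
        assert np.median(errs) < 50e-9
        assert np.max(errs) < 100e-9


class TestIndentation:
    def test_rigid_substrate_zero_indentation(self, sphere_probe):
        # force rises exactly with cantilever deflection: delta == 0
        k = sphere_probe.spring_constant
        z = np.linspace(0, 2e-6, 500)
        zc = 1e-6
        force = np.where(z > zc, (z - zc) * k, 0.0)
        curve = ForceCurve(z=z, force=force, probe=sphere_probe, trigger_force=1e-8)
        delta, _ = compute_indentation(curve, zc)
        np.testing.assert_allclose(delta, 0.0, atol=1e-18)

    def test_recovers_generated_indentation(self, sphere_probe):
        curve = gen_force_curve(8e3, sphere_probe, noise_sd=0, seed=0)
        delta, P = compute_indentation(curve, curve.truth["contact_z"])
        in_contact = delta > 1e-12
        np.testing.assert_allclose(
            P[in_contact],
            eval_sphere_dmt(8e3, sphere_probe.R, 0.5, 0.0, delta[in_contact]),
            rtol=1e-9)

    def test_monotone_nondecreasing(self, sphere_probe):
        curve = gen_force_curve(20e3, sphere_probe, noise_sd=0, seed=1)
        delta, _ = compute_indentation(curve, curve.truth["contact_z"])
        assert np.all(np.diff(delta) >= -1e-15)


class TestFit:
    def test_sphere_roundtrip_with_adhesion(self, sphere_probe):
        curve = gen_force_curve(8e3, sphere_probe, adhesion_work=0.5e-3,
                                noise_sd=0, seed=3)
        r = fit_contact_model(curve, "sphere_dmt")
        assert r.E == pytest.approx(8e3, rel=1e-3)
        assert r.gamma == pytest.approx(0.5e-3, rel=1e-3)
        assert r.contact_point < r.transition_point

    def test_cone_roundtrip(self, cone_probe):
        curve = gen_force_curve(3e3, cone_probe, max_force=10e-9, noise_sd=0,
                                seed=4)
        r = fit_contact_model(curve, "cone")
        assert r.E == pytest.approx(3e3, rel=1e-3)
        assert r.r_squared > 0.9999

    def test_random_parameter_roundtrip(self, sphere_probe, rng):
        # physiological range sweep, noiseless: 0.1% recovery
        for i in range(20):
            E = rng.uniform(0.3e3, 100e3)
            gamma = rng.uniform(0.0, 2e-3)
            curve = gen_force_curve(E, sphere_probe, adhesion_work=gamma,
                                    noise_sd=0, seed=100 + i)
            r = fit_contact_model(curve, "sphere_dmt")
            assert r.E == pytest.approx(E, rel=1e-3)
            if gamma > 1e-5:
                assert r.gamma == pytest.approx(gamma, rel=1e-3)

    def test_monotone_in_true_stiffness(self, sphere_probe):
        fitted = [fit_contact_model(
            gen_force_curve(E, sphere_probe, noise_sd=0, seed=7), "sphere_dmt").E
            for E in (2e3, 8e3, 32e3)]
        assert fitted[0] < fitted[1] < fitted[2]

    def test_excess_indentation_flagged(self, sphere_probe):
        # indentation fraction > 0.2 violates the thin-sample QC rule
        curve = gen_force_curve(0.5e3, sphere_probe, noise_sd=0, seed=5,
                                sample_thickness=3e-6)
        r = fit_contact_model(curve, "sphere_dmt")
        assert r.indentation_fraction > 0.2
        assert not r.accepted

    def test_model_probe_mismatch(self, sphere_probe):
        curve = gen_force_curve(8e3, sphere_probe, noise_sd=0, seed=6)
        with pytest.raises(ValueError, match="cone"):
            fit_contact_model(curve, "cone")


class TestUnitsInvariance:
    def test_fit_invariant_under_unit_rescaling(self, sphere_probe, tmp_path):
        from cellmech.io import read_force_curve
        import json
        import pandas as pd

        curve = gen_force_curve(8e3, sphere_probe, adhesion_work=0.3e-3,
                                noise_sd=0, seed=8)
        meta = {"probe_kind": "sphere", "R_m": 2.5e-6,
                "spring_constant_N_per_m": 0.03, "trigger_force_N": 2e-9}
        for name, zcol, zs, fcol, fs in (
                ("si", "z_m", 1.0, "force_N", 1.0),
                ("afm", "z_nm", 1e9, "force_nN", 1e9)):
            pd.DataFrame({zcol: curve.z * zs, fcol: curve.force * fs}).to_csv(
                tmp_path / f"{name}.csv", index=False)
            (tmp_path / f"{name}.json").write_text(json.dumps(meta))
        fits = [fit_contact_model(read_force_curve(tmp_path / f"{n}.csv"),
                                  "sphere_dmt") for n in ("si", "afm")]
        assert fits[0].E == pytest.approx(fits[1].E, rel=1e-9)
        assert fits[0].gamma == pytest.approx(fits[1].gamma, rel=1e-6, abs=1e-12)


class TestForceMap:
    def _make_map(self, sphere_probe, E_field):
        curves = [[gen_force_curve(E_field[i][j], sphere_probe, noise_sd=0,
                                   seed=10 * i + j)
                   for j in range(len(E_field[0]))] for i in range(len(E_field))]
        return ForceMap(curves=curves)

    def test_constant_field(self, sphere_probe):
        fmap = self._make_map(sphere_probe, [[8e3] * 3] * 2)
        fit_force_map(fmap, "sphere_dmt")
        s = summarize_force_map(fmap)
        assert s["E_mean"] == pytest.approx(8e3, rel=1e-3)
        assert s["E_sd"] == pytest.approx(0.0, abs=10.0)

    def test_two_level_field_mean(self, sphere_probe):
        fmap = self._make_map(sphere_probe, [[8e3, 8e3, 32e3, 32e3]] * 2)
        fit_force_map(fmap, "sphere_dmt")
        assert summarize_force_map(fmap)["E_mean"] == pytest.approx(20e3, rel=1e-3)

    def test_flagged_cell_excluded(self, sphere_probe):
        fmap = self._make_map(sphere_probe, [[8e3, 8e3]])
        # make one cell fail thin-sample QC
        fmap.curves[0][1] = gen_force_curve(0.5e3, sphere_probe, noise_sd=0,
                                            seed=99, sample_thickness=3e-6)
        fit_force_map(fmap, "sphere_dmt")
        s = summarize_force_map(fmap)
        assert s["n_accepted"] == 1
        assert s["n_rejected"] == 1
        assert s["E_mean"] == pytest.approx(8e3, rel=1e-3)

    def test_empty_map_errors(self, sphere_probe):
        fmap = self._make_map(sphere_probe, [[0.5e3]])
        fmap.curves[0][0].sample_thickness = 1e-6
        fit_force_map(fmap, "sphere_dmt")
        with pytest.raises(ValueError, match="empty map"):
            summarize_force_map(fmap)
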