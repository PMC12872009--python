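import dataclasses

import numpy as np
import pytest
from scipy import integrate

from cordpop.geometry import GeometryConfig, build_cross_section, voxelize
from cordpop.morphology import PopulationSpec, make_subject, sample_population
from cordpop.surrogate import (DEFAULT_EFFECTS, CalibrationError,
                               ImpactProtocol, SurrogateEffects,
                               calibrate_effects, simulate_impact,
                               simulate_peak_force)

NOISELESS = dataclasses.replace(DEFAULT_EFFECTS, noise_sd_N=0.0,
                                strain_noise_sd=0.0)


def build_mesh(subject, cfg=None, voxel=0.15):
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return voxelize(build_cross_section(subject, cfg or GeometryConfig()),
                        voxel_size=voxel)


class TestPeakForce:
    def test_monotone_in_occlusion_at_fixed_csf(self):
        """Same CSF area, higher occlusion => strictly higher peak force
        (noise-free)."""
        # SCO/SC = 40/70 vs 50/80: CSF area 30 mm^2 in both
        lo = make_subject("lo", scow=4 * 40 / (np.pi * 6), scod=6.0,
                          scw=4 * 70 / (np.pi * 8), scd=8.0)
        hi = make_subject("hi", scow=4 * 50 / (np.pi * 6), scod=6.0,
                          scw=4 * 80 / (np.pi * 8), scd=8.0)
        assert lo.csf_area == pytest.approx(hi.csf_area)
        assert hi.occ_area > lo.occ_area
        assert simulate_peak_force(hi, NOISELESS) > \
            simulate_peak_force(lo, NOISELESS)

    def test_degenerate_effects_give_constant_force(self, mean_subject):
        eff = dataclasses.replace(NOISELESS, coef_occ_area_N=0.0,
                                  coef_csf_area_N=0.0, intercept_N=10.0)
        assert simulate_peak_force(mean_subject, eff) == 10.0

    def test_floor_applied(self, mean_subject):
        eff = dataclasses.replace(NOISELESS, intercept_N=-100.0)
        assert simulate_peak_force(mean_subject, eff) == eff.force_floor_N


class TestSimulateImpact:
    def test_force_curve_contract(self, mean_subject, mean_mesh):
        proto = ImpactProtocol()
        result, field = simulate_impact(mean_subject, mean_mesh, proto,
                                        NOISELESS)
        assert proto.impact_duration_ms == pytest.approx(8.0)
        assert result.peak_force == pytest.approx(result.force_N.max())
        assert np.all(result.force_N >= 0)
        # preload plateau before the pulse
        assert result.force_N[0] == pytest.approx(proto.preload_force)
        # peak at full displacement (end of the 8-ms impact phase)
        t_peak = result.time_ms[np.argmax(result.force_N)]
        assert t_peak == pytest.approx(0.25 * 8.0 + 8.0, abs=0.1)

    def test_impulse_matches_independent_quadrature(self, mean_subject,
                                                    mean_mesh):
        result, _ = simulate_impact(mean_subject, mean_mesh, eff=NOISELESS)
        t, f = result.time_ms, result.force_N
        mask = (t >= 2.0) & (t <= 10.0)
        ref = integrate.simpson(f[mask], x=t[mask]) * 1e-3
        assert result.impulse == pytest.approx(ref, rel=5e-3)

    def test_impulse_monotone_in_peak_force(self, mean_subject, mean_mesh):
        effs = [dataclasses.replace(NOISELESS, intercept_N=c,
                                    coef_occ_area_N=0.0, coef_csf_area_N=0.0)
                for c in (10.0, 20.0, 30.0)]
        impulses = [simulate_impact(mean_subject, mean_mesh,
                                    eff=e)[0].impulse for e in effs]
        assert impulses == sorted(impulses)

    def test_seed_determinism_and_order_independence(self, mean_mesh):
        subjects = sample_population(PopulationSpec(n_subjects=4, rng_seed=3))
        meshes = {s.subject_id: build_mesh(s) for s in subjects}

        def run(order):
            return {s.subject_id:
                    simulate_impact(s, meshes[s.subject_id])[0].peak_force
                    for s in order}

        assert run(subjects) == run(list(reversed(subjects)))
        a = simulate_impact(subjects[0], meshes[subjects[0].subject_id])
        b = simulate_impact(subjects[0], meshes[subjects[0].subject_id])
        assert a[0].peak_force == b[0].peak_force
        assert np.array_equal(a[1].min_lep, b[1].min_lep)

    def test_strain_compressive_and_concentrated_ipsilaterally(
            self, mean_subject, mean_mesh):
        _, field = simulate_impact(mean_subject, mean_mesh, eff=NOISELESS)
        assert np.all(field.min_lep <= 0)
        tissue = np.isin(mean_mesh.label, (0, 1))
        ipsi = tissue & (mean_mesh.x > 1.0)
        contra = tissue & (mean_mesh.x < -1.0)
        assert field.min_lep[ipsi].mean() < field.min_lep[contra].mean()
        # dorsal (near-surface, under impactor) worse than far ventral edge
        under = tissue & (np.abs(mean_mesh.x - 0.5) < 1.0)
        dorsal = under & (mean_mesh.y > 2.0)
        ventral = under & (mean_mesh.y < -2.5)
        assert field.min_lep[dorsal].mean() <= field.min_lep[ventral].mean()

    def test_lateral_spread_increases_with_ml_occlusion(self):
        """Tighter ML fit => compressive strain reaches further laterally."""
        loose = make_subject("loose", scow=8.6, scod=6.3, scw=12.0, scd=8.1)
        tight = make_subject("tight", scow=10.8, scod=6.3, scw=11.0, scd=8.1)
        out = {}
        for s in (loose, tight):
            mesh = build_mesh(s)
            _, field = simulate_impact(s, mesh, eff=NOISELESS)
            white_edge = (mesh.label == 1) & (mesh.x > 0.9 * mesh.cord_rx)
            out[s.subject_id] = field.min_lep[white_edge].mean()
        assert out["tight"] < out["loose"]

    def test_overhang_reduces_engagement(self):
        """An impactor overhanging the cord laterally lowers the strain
        amplitude (slippage)."""
        narrow = make_subject("n", scow=5.4, scod=5.2, scw=11.6, scd=8.1)
        cfg = GeometryConfig(
            gray_template=__import__("cordpop.geometry", fromlist=["g"]
                                     ).default_gray_template(4.0))
        mesh = build_mesh(narrow, cfg)
        eff_slip = dataclasses.replace(NOISELESS, coef_occ_area_N=0.0,
                                       coef_csf_area_N=0.0, intercept_N=24.3)
        eff_noslip = dataclasses.replace(eff_slip, slippage_gain=0.0)
        _, f_slip = simulate_impact(narrow, mesh, eff=eff_slip, geom_cfg=cfg)
        _, f_noslip = simulate_impact(narrow, mesh, eff=eff_noslip,
                                      geom_cfg=cfg)
        assert f_slip.footprint.overhang_ipsi
        assert f_slip.min_lep.min() > f_noslip.min_lep.min()

    def test_mirror_equivariance(self, mean_subject):
        """Reflecting the subject and negating the impactor offset mirrors
        the strain field exactly (noise-free)."""
        cfg_r = GeometryConfig(impactor_lateral_offset=0.5)
        cfg_l = GeometryConfig(impactor_lateral_offset=-0.5)
        mesh_r = build_mesh(mean_subject, cfg_r)
        mesh_l = build_mesh(mean_subject, cfg_l)
        _, fr = simulate_impact(mean_subject, mesh_r, eff=NOISELESS,
                                geom_cfg=cfg_r)
        _, fl = simulate_impact(mean_subject, mesh_l, eff=NOISELESS,
                                geom_cfg=cfg_l)
        key_r = np.lexsort((mesh_r.y, mesh_r.x * mesh_r.ipsi_sign))
        key_l = np.lexsort((mesh_l.y, mesh_l.x * mesh_l.ipsi_sign))
        np.testing.assert_allclose(fr.min_lep[key_r], fl.min_lep[key_l],
                                   atol=1e-12)


@pytest.fixture(scope="module")
def population():
    return sample_population(PopulationSpec(n_subjects=40, rng_seed=11))


class TestCalibration:
    def test_noise_free_moments_exact(self, population):
        eff = calibrate_effects(24.3, 3.8, population, morph_var_fraction=1.0)
        assert eff.noise_sd_N == 0.0
        forces = np.array([simulate_peak_force(s, eff) for s in population])
        assert forces.mean() == pytest.approx(24.3, rel=1e-9)
        assert forces.std(ddof=1) == pytest.approx(3.8, rel=1e-9)

    def test_default_split_moments_within_tolerance(self, population):
        eff = calibrate_effects(24.3, 3.8, population)
        forces = np.array([simulate_peak_force(s, eff) for s in population])
        # morphology part is exact; realized noise adds sampling wobble
        assert forces.mean() == pytest.approx(24.3, abs=1.2)
        assert forces.std(ddof=1) == pytest.approx(3.8, abs=1.0)

    def test_zero_target_sd(self, population):
        eff = calibrate_effects(24.3, 0.0, population)
        forces = [simulate_peak_force(s, eff) for s in population]
        assert np.std(forces) == pytest.approx(0.0, abs=1e-9)
        assert np.mean(forces) == pytest.approx(24.3)

    def test_effect_recovery_self_consistency(self, population):
        """Re-calibrating to the moments generated by known effects
        recovers those effects."""
        truth = dataclasses.replace(NOISELESS, intercept_N=-5.0,
                                    coef_occ_area_N=36.0,
                                    coef_csf_area_N=-0.2)
        forces = np.array([simulate_peak_force(s, truth)
                           for s in population])
        eff = calibrate_effects(forces.mean(), forces.std(ddof=1),
                                population, base=truth,
                                morph_var_fraction=1.0)
        assert eff.intercept_N == pytest.approx(-5.0, rel=1e-9)
        assert eff.coef_occ_area_N == pytest.approx(36.0, rel=1e-9)
        assert eff.coef_csf_area_N == pytest.approx(-0.2, rel=1e-9)

    def test_degenerate_population_rejected(self):
        spec = PopulationSpec(n_subjects=5,
                              sds={"scow": 0.0, "scod": 0.0,
                                   "scw": 0.0, "scd": 0.0})
        clones = sample_population(spec)
        with pytest.raises(CalibrationError):
            calibrate_effects(24.3, 3.8, clones)
        with pytest.raises(CalibrationError):
            calibrate_effects(24.3, 3.8, clones[:2])

    def test_correlation_signs_recovered(self, population):
        """Generated populations show the built-in correlation structure:
        occlusion raises force, CSF area lowers it."""
        eff = calibrate_effects(24.3, 3.8, population)
        forces = np.array([simulate_peak_force(s, eff) for s in population])
        occ = np.array([s.occ_area for s in population])
        csf = np.array([s.csf_area for s in population])
        assert np.corrcoef(occ, forces)[0, 1] > 0.5
        assert np.corrcoef(csf, forces)[0, 1] < -0.5
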