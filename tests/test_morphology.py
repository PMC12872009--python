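import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from cordpop.morphology import (DIAMETER_FIELDS, MorphologyError,
                                PopulationSpec, SchemaError, derive_metrics,
                                make_subject, read_subject_table,
                                sample_population, write_subject_table)


class TestDeriveMetrics:
    def test_mean_subject_values(self, mean_subject):
        # hand evaluation of pi*a*b on the population-mean diameters
        assert mean_subject.sco_area == pytest.approx(
            math.pi * 4.9 * 3.15, rel=1e-12)
        assert mean_subject.sc_area == pytest.approx(
            math.pi * 5.8 * 4.05, rel=1e-12)
        # hand values: pi*15.435 = 48.490, pi*23.49 = 73.796, diff 25.306
        assert mean_subject.sco_area == pytest.approx(48.490, abs=5e-3)
        assert mean_subject.sc_area == pytest.approx(73.796, abs=5e-3)
        assert mean_subject.csf_area == pytest.approx(25.306, abs=5e-3)
        assert mean_subject.csf_ml == pytest.approx(1.8)
        assert mean_subject.csf_ap == pytest.approx(1.8)

    def test_circles_area_ratio_is_squared_diameter_ratio(self):
        s = make_subject("c", scow=2, scod=2, scw=4, scd=4)
        assert s.occ_area == pytest.approx(0.25, rel=1e-12)
        assert s.occ_ml == pytest.approx(0.5)
        assert s.occ_ap == pytest.approx(0.5)

    def test_near_occlusion_limit(self):
        eps = 1e-9
        s = make_subject("lim", scow=11.6 - eps, scod=8.1 - eps,
                         scw=11.6, scd=8.1)
        assert s.csf_area == pytest.approx(0.0, abs=1e-6)
        assert s.occ_area == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("bad", [
        dict(scow=0.0, scod=6.3, scw=11.6, scd=8.1),
        dict(scow=-2.0, scod=6.3, scw=11.6, scd=8.1),
        dict(scow=12.0, scod=6.3, scw=11.6, scd=8.1),   # cord wider than canal
        dict(scow=9.8, scod=8.2, scw=11.6, scd=8.1),    # cord deeper than canal
        dict(scow=9.8, scod=float("nan"), scw=11.6, scd=8.1),
    ])
    def test_invalid_diameters_raise_naming_field(self, bad):
        with pytest.raises(MorphologyError):
            make_subject("bad", **bad)

    def test_idempotent(self, mean_subject):
        again = derive_metrics(mean_subject)
        assert again == mean_subject

    @given(k=st.floats(0.3, 4.0),
           scow=st.floats(6.0, 11.0), scod=st.floats(4.5, 7.5))
    @settings(max_examples=50, derandomize=True)
    def test_scale_covariance(self, k, scow, scod):
        """Scaling diameters by k scales areas by k^2, fixes occlusions."""
        a = make_subject("a", scow, scod, scow + 2.0, scod + 1.5)
        b = make_subject("b", k * scow, k * scod, k * (scow + 2.0),
                         k * (scod + 1.5))
        assert b.sco_area == pytest.approx(k ** 2 * a.sco_area, rel=1e-9)
        assert b.csf_area == pytest.approx(k ** 2 * a.csf_area, rel=1e-9)
        assert b.occ_area == pytest.approx(a.occ_area, rel=1e-9)
        assert b.occ_ml == pytest.approx(a.occ_ml, rel=1e-9)
        assert b.occ_ap == pytest.approx(a.occ_ap, rel=1e-9)


def oracle_population(spec: PopulationSpec, rng: np.random.Generator):
    """Independent draw of the declared distribution: per-diameter normal
    resampled into the +/- trunc_sd band (SD-corrected), then rejection of
    cord-outside-canal pairs.  Loop-based, shares no code path with
    sample_population."""

    def corrected_sigma(sd):
        z = optimize.brentq(
            lambda s: stats.truncnorm.std(-spec.trunc_sd * sd / s,
                                          spec.trunc_sd * sd / s,
                                          scale=s) - sd, sd, 4 * sd)
        return z

    sigmas = {k: corrected_sigma(spec.sds[k]) for k in DIAMETER_FIELDS}
    out = []
    while len(out) < spec.n_subjects:
        draw = {}
        for k in DIAMETER_FIELDS:
            mu, sd = spec.means[k], spec.sds[k]
            while True:
                v = rng.normal(mu, sigmas[k])
                if abs(v - mu) <= spec.trunc_sd * sd:
                    draw[k] = v
                    break
        if draw["scow"] < draw["scw"] and draw["scod"] < draw["scd"]:
            out.append(draw)
    return pd.DataFrame(out)


class TestSamplePopulation:
    def test_default_population_near_reported_means(self, default_spec):
        subjects = sample_population(default_spec)
        assert len(subjects) == 40
        scw = np.array([s.scw for s in subjects])
        assert abs(scw.mean() - 11.6) < 2 * 0.9 / math.sqrt(40)

    def test_seed_determinism(self, default_spec):
        a = sample_population(default_spec)
        b = sample_population(default_spec)
        assert a == b
        c = sample_population(PopulationSpec(n_subjects=40, rng_seed=2))
        assert c != a

    def test_zero_sd_gives_identical_mean_subjects(self):
        spec = PopulationSpec(n_subjects=5,
                              sds=dict.fromkeys(DIAMETER_FIELDS, 0.0))
        subjects = sample_population(spec)
        for s in subjects:
            assert (s.scow, s.scod, s.scw, s.scd) == (9.8, 6.3, 11.6, 8.1)

    def test_constraint_never_violated_and_moments(self):
        """10^4 draws: no cord-outside-canal subject; empirical moments
        match an independent Monte-Carlo oracle of the same declared
        distribution (means additionally within 1% of the spec values)."""
        spec = PopulationSpec(n_subjects=10_000, rng_seed=7,
                              max_attempts=10_000)
        subjects = sample_population(spec)
        assert all(s.scow < s.scw and s.scod < s.scd for s in subjects)
        got = pd.DataFrame({k: [getattr(s, k) for s in subjects]
                            for k in DIAMETER_FIELDS})
        ref = oracle_population(
            PopulationSpec(n_subjects=10_000, rng_seed=0),
            np.random.default_rng(123))
        for k in DIAMETER_FIELDS:
            assert abs(got[k].mean() - spec.means[k]) < 0.01 * spec.means[k]
            # oracle agreement: ~4 MC standard errors
            se_mean = ref[k].std() / 100.0
            assert abs(got[k].mean() - ref[k].mean()) < 4 * se_mean
            assert abs(got[k].std() - ref[k].std()) < 0.05 * ref[k].std()

    def test_unsatisfiable_bounds_report_parameters(self):
        spec = PopulationSpec(
            n_subjects=3, max_attempts=20,
            means={"scow": 11.0, "scod": 6.3, "scw": 8.0, "scd": 8.1},
            sds=dict.fromkeys(DIAMETER_FIELDS, 0.1))
        with pytest.raises(MorphologyError, match="scow"):
            sample_population(spec)

    def test_subject_ids_follow_s_convention(self, default_spec):
        subjects = sample_population(default_spec)
        assert subjects[0].subject_id == "S1"
        assert subjects[-1].subject_id == "S40"


class TestSubjectTable:
    def test_round_trip_identity(self, tmp_path, default_spec):
        subjects = sample_population(default_spec)[:3]
        path = tmp_path / "subjects.csv"
        write_subject_table(subjects, path)
        back, frame = read_subject_table(path)
        assert back == subjects

    def test_results_columns_pass_through(self, tmp_path, default_spec):
        subjects = sample_population(default_spec)[:3]
        results = pd.DataFrame(
            {"PeakForce_N": [20.0, 25.0, 30.0]},
            index=[s.subject_id for s in subjects])
        path = tmp_path / "subjects.csv"
        write_subject_table(subjects, path, results)
        _, frame = read_subject_table(path)
        assert list(frame["PeakForce_N"]) == [20.0, 25.0, 30.0]

    def test_invariant_breach_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("SubjectID,SCOW,SCOD,SCW,SCD\nS1,12.0,6.3,11.6,8.1\n")
        with pytest.raises(MorphologyError):
            read_subject_table(path)

    def test_schema_error_lists_columns(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("SubjectID,SCOW,SCOD,SCW,Bogus\nS1,9,6,11,8\n")
        with pytest.raises(SchemaError, match="Bogus"):
            read_subject_table(path)

    def test_transcribed_precision_cross_check(self, tmp_path):
        # derived columns printed at 2 decimals must pass the cross-check;
        # a genuinely wrong value must not
        path = tmp_path / "s1.csv"
        path.write_text("SubjectID,SCOW,SCOD,SCW,SCD,SCO,Occ_Area\n"
                        "S1,9.8,6.3,11.6,8.1,48.49,0.66\n")
        subjects, _ = read_subject_table(path)
        assert subjects[0].occ_area == pytest.approx(0.657, abs=5e-3)
        bad = tmp_path / "s2.csv"
        bad.write_text("SubjectID,SCOW,SCOD,SCW,SCD,SCO\n"
                       "S1,9.8,6.3,11.6,8.1,52.0\n")
        with pytest.raises(MorphologyError, match="SCO"):
            read_subject_table(bad)
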