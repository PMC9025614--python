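"""Synthetic study generator: design counts, moments, determinism, images."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tailmorph as tm
from tailmorph.synthetic import frame_to_csv_text


class TestDefaultSpecs:
    def test_seven_groups_in_table_order(self, default_specs):
        assert [s.name for s in default_specs] == [
            "untreated", "white soft paraffin", "tretinoin 0.05%",
            "diclofenac 1%", "diclofenac 2%", "celecoxib 1%", "celecoxib 2%",
        ]

    def test_reported_parameterization(self, default_specs):
        by_name = {s.name: s for s in default_specs}
        assert by_name["untreated"].ok_mean == 17.7
        assert by_name["untreated"].ok_sd == 1.81
        assert by_name["celecoxib 2%"].thick_mean == 32.28
        assert by_name["celecoxib 2%"].thick_sd == 6.18

    def test_design_counts(self, default_specs):
        for s in default_specs:
            assert s.n_animals * s.scales_per_animal == 60
            assert s.n_thickness == 300


class TestGenerateMeasurements:
    def test_record_and_reading_counts(self, default_specs):
        for spec in default_specs[:2]:
            recs = tm.generate_measurements(spec, seed=5)
            assert len(recs) == spec.n_animals * spec.scales_per_animal
            assert all(len(r.thickness_um) == spec.measurements_per_scale for r in recs)

    def test_zero_variance_is_exact(self):
        spec = tm.GroupSpec(name="g", ok_mean=40.0, ok_sd=0.0, thick_mean=25.0, thick_sd=0.0)
        recs = tm.generate_measurements(spec, seed=123)
        assert all(r.degree == pytest.approx(40.0) for r in recs)
        assert all(t == 25.0 for r in recs for t in r.thickness_um)

    def test_determinism_byte_identical_csv(self, default_specs):
        a = frame_to_csv_text(tm.generate_study(default_specs, seed=7))
        b = frame_to_csv_text(tm.generate_study(default_specs, seed=7))
        assert a == b

    def test_sample_mean_within_four_se_most_seeds(self, default_specs):
        """Monte-Carlo coverage of the 4-SE band around the target mean.

        The standard error of a group mean must include the design
        effect of the animal-level intraclass correlation:
        SE = sd * sqrt(icc/n_animals + (1-icc)/n_scales).
        """
        spec = next(s for s in default_specs if s.name == "celecoxib 2%")
        se = spec.ok_sd * np.sqrt(
            spec.animal_icc / spec.n_animals + (1 - spec.animal_icc) / spec.n_scales
        )
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            degs = np.array([r.degree for r in tm.generate_measurements(spec, seed)])
            hits += abs(degs.mean() - spec.ok_mean) < 4 * se
        assert hits / n_seeds > 0.99

    def test_moment_recovery_at_ten_x_size(self):
        """Empirical mean/SD converge to the spec away from truncation.

        With animal_icc = 0 every scale is independent, so growing the
        per-animal scale count alone shrinks the sampling error; with
        clustering the animal count would have to grow as well.
        """
        spec = tm.GroupSpec(name="g", ok_mean=50.0, ok_sd=8.0,
                            thick_mean=30.0, thick_sd=3.0, n_animals=10,
                            scales_per_animal=600, animal_icc=0.0)
        degs = np.array([r.degree for r in tm.generate_measurements(spec, seed=21)])
        assert degs.mean() == pytest.approx(50.0, rel=0.02)
        assert degs.std(ddof=1) == pytest.approx(8.0, rel=0.02)

    def test_rejects_bad_design(self):
        with pytest.raises(tm.ValidationError):
            tm.GroupSpec(name="g", ok_mean=50, ok_sd=1, thick_mean=30, thick_sd=1,
                         animal_icc=1.0)
        with pytest.raises(tm.ValidationError):
            tm.GroupSpec(name="g", ok_mean=50, ok_sd=1, thick_mean=30, thick_sd=1,
                         n_animals=0)

    @settings(max_examples=40, deadline=None)
    @given(
        ok_mean=st.floats(0, 100), ok_sd=st.floats(0, 40),
        thick_mean=st.floats(0.5, 80), thick_sd=st.floats(0, 30),
        icc=st.floats(0, 0.95), seed=st.integers(0, 2**31 - 1),
    )
    def test_truncation_safety(self, ok_mean, ok_sd, thick_mean, thick_sd, icc, seed):
        """Any spec, any seed: degrees in [0,100], lengths positive, A <= B."""
        spec = tm.GroupSpec(name="g", ok_mean=ok_mean, ok_sd=ok_sd,
                            thick_mean=thick_mean, thick_sd=thick_sd,
                            n_animals=2, scales_per_animal=3, animal_icc=icc)
        for r in tm.generate_measurements(spec, seed):
            assert 0.0 <= r.A_um <= r.B_um
            assert r.B_um > 0
            assert 0.0 <= r.degree <= 100.0
            assert all(t > 0 for t in r.thickness_um)


class TestLabelImages:
    def test_full_degree_spans_scale(self):
        img, truth = tm.generate_label_image(400, 100.0, [30] * 5, 2.0, seed=2)
        rec = tm.measure_image(img)[0]
        assert rec.A_um == rec.B_um

    def test_zero_degree_no_granular_pixels(self):
        img, _ = tm.generate_label_image(400, 0.0, [30] * 5, 2.0, seed=2)
        assert (img.grid == tm.CLASS_CODES["granular"]).sum() == 0

    def test_sidecar_and_rasterized_run_length(self):
        img, truth = tm.generate_label_image(400, 50.0, [30] * 5, 2.0, seed=9)
        assert truth["A_um"] == pytest.approx(200.0)
        cols = (img.grid == tm.CLASS_CODES["granular"]).any(axis=0)
        assert abs(int(cols.sum()) - 100) <= 1

    def test_geometry_that_does_not_fit_fails(self):
        with pytest.raises(tm.ValidationError):
            tm.generate_label_image(400, 50.0, [30] * 5, 2.0, seed=0, height_px=10)
        with pytest.raises(tm.ValidationError):
            tm.generate_label_image(400, 50.0, [30] * 5, 2.0, seed=0, width_px=50)
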