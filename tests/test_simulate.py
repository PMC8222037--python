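import dataclasses

import numpy as np
import pytest

import msiquant as mq
from msiquant.images import extract_ion_image, log_transform
from msiquant.quant import normalize_ratio
from msiquant.segment import detect_spots
from msiquant.simulate import (
    ChannelSpec,
    NoiseSpec,
    ResponseSpec,
    SectionSpec,
    SlideSpec,
    SpotSpec,
    default_calibration_spec,
    generate_calibration_only,
    generate_slide,
)

TARGETS = mq.builtin_targets()


def noise_free_spec(**kw):
    spot = SpotSpec(center=(8.0, 8.0), conc_ng_per_ul=20.0, replicate=1, radius=2.5)
    section = SectionSpec("calibration", (2, 2), (13, 13), lipid_mg_per_g=0.0, spots=(spot,))
    return SlideSpec(
        grid_shape=(17, 17),
        sections=[section],
        noise=NoiseSpec(0.0, 0.0, 0.0, 0.0, 0.0),
        response=ResponseSpec(intercept=0.0, slope_per_ng=0.1,
                              intercept_shift_frac={0.0: 0.0}),
        seed=5,
        **kw,
    )


class TestNoiseFree:
    def test_spot_ratio_exactly_one(self):
        """amount 10 ng, alpha=0, beta=0.1 -> analyte/IS = 1 on every spot pixel."""
        grid, truth = generate_slide(noise_free_spec())
        bud = extract_ion_image(grid, TARGETS["BUD-GirP"].mz)
        ta = extract_ion_image(grid, TARGETS["TA-GirP"].mz)
        ratio = normalize_ratio(bud, ta).values
        spot_mask = truth.spot_labels > 0
        assert spot_mask.sum() == 21
        assert np.allclose(ratio[spot_mask], 1.0)

    def test_marker_channels_consistent_with_ground_truth(self):
        grid, truth = generate_slide(noise_free_spec())
        heme = extract_ion_image(grid, TARGETS["hemeB"].mz).values
        tio = extract_ion_image(grid, TARGETS["tiotropium"].mz).values
        assert np.all(heme[truth.tissue_mask()] > 0)
        assert np.all(tio[truth.spot_labels > 0] > 0)
        assert np.all(tio[truth.spot_labels == 0] == 0)
        assert np.all(heme[truth.section_labels == 0] == 0)


class TestDeterminism:
    def test_same_seed_identical_spectra(self):
        spec = default_calibration_spec(seed=3)
        g1, _ = generate_slide(spec)
        g2, _ = generate_slide(default_calibration_spec(seed=3))
        assert len(g1) == len(g2)
        for p, q in zip(g1.pixels, g2.pixels):
            assert (p.x, p.y) == (q.x, q.y)
            assert np.array_equal(p.mz, q.mz)
            assert np.array_equal(p.intensity, q.intensity)

    def test_identical_ibd_payload_bytes(self, tmp_path):
        """Bit-identical binary payloads after the per-file UUID header."""
        from msiquant.imzml import write_imzml

        for i, d in enumerate(("a", "b")):
            grid, _ = generate_slide(default_calibration_spec(seed=3))
            (tmp_path / d).mkdir()
            write_imzml(grid, tmp_path / d / "s.imzML", mode="processed", dtype="float64")
        b1 = (tmp_path / "a" / "s.ibd").read_bytes()[16:]
        b2 = (tmp_path / "b" / "s.ibd").read_bytes()[16:]
        assert b1 == b2

    def test_different_seeds_differ(self):
        g1, _ = generate_slide(default_calibration_spec(seed=3))
        g2, _ = generate_slide(default_calibration_spec(seed=4))
        assert any(
            not np.array_equal(p.intensity, q.intensity)
            for p, q in zip(g1.pixels, g2.pixels)
        )


class TestNoiseModel:
    def test_expected_ratio_matches_analytic_mean(self):
        """Empirical mean of the noisy ratio equals r * exp(sigma_indep^2)
        (ratio of two independent median-one lognormals) within MC error."""
        spot = SpotSpec(center=(50.0, 50.0), conc_ng_per_ul=20.0, replicate=1, radius=49.0)
        section = SectionSpec("calibration", (0, 0), (100, 100), spots=(spot,))
        sigma = 0.15
        spec = SlideSpec(
            grid_shape=(100, 100),
            sections=[section],
            noise=NoiseSpec(sigma, 0.3, 0.0, 0.0, 0.0),
            response=ResponseSpec(intercept=0.0, slope_per_ng=0.1,
                                  intercept_shift_frac={0.0: 0.0}),
            seed=8,
        )
        grid, truth = generate_slide(spec)
        bud = extract_ion_image(grid, TARGETS["BUD-GirP"].mz)
        ta = extract_ion_image(grid, TARGETS["TA-GirP"].mz)
        ratio = normalize_ratio(bud, ta).values
        vals = ratio[truth.spot_labels > 0]
        assert vals.size > 7000
        analytic_mean = 1.0 * np.exp(sigma**2)
        # ratio is lognormal with log-sd sigma*sqrt(2): var = (e^{s2}-1)e^{s2}
        s2 = 2 * sigma**2
        mc_sd = np.sqrt((np.exp(s2) - 1.0) * np.exp(s2) / vals.size) * 3
        assert abs(vals.mean() - analytic_mean) < mc_sd + 1e-3

    def test_shared_noise_cancels_in_ratio(self):
        """With only the shared component active the ratio is exactly the
        configured response on every pixel."""
        spot = SpotSpec(center=(8.0, 8.0), conc_ng_per_ul=20.0, replicate=1)
        section = SectionSpec("calibration", (2, 2), (13, 13), spots=(spot,))
        spec = SlideSpec(
            grid_shape=(17, 17),
            sections=[section],
            noise=NoiseSpec(0.0, 0.5, 0.0, 0.0, 0.0),
            response=ResponseSpec(intercept=0.0, slope_per_ng=0.1,
                                  intercept_shift_frac={0.0: 0.0}),
            seed=2,
        )
        grid, truth = generate_slide(spec)
        bud = extract_ion_image(grid, TARGETS["BUD-GirP"].mz)
        ta = extract_ion_image(grid, TARGETS["TA-GirP"].mz)
        ratio = normalize_ratio(bud, ta).values
        assert np.allclose(ratio[truth.spot_labels > 0], 1.0)


class TestGeometryValidation:
    def test_overlapping_sections_rejected(self):
        spec = SlideSpec(
            grid_shape=(20, 20),
            sections=[
                SectionSpec("a", (2, 2), (10, 10)),
                SectionSpec("b", (5, 5), (10, 10)),
            ],
        )
        with pytest.raises(ValueError, match="overlap"):
            generate_slide(spec)

    def test_overlapping_spots_rejected(self):
        spots = (
            SpotSpec(center=(8.0, 8.0), conc_ng_per_ul=5.0, replicate=1),
            SpotSpec(center=(8.0, 10.0), conc_ng_per_ul=5.0, replicate=2),
        )
        spec = SlideSpec(
            grid_shape=(20, 20),
            sections=[SectionSpec("a", (2, 2), (15, 15), spots=spots)],
        )
        with pytest.raises(ValueError, match="overlap"):
            generate_slide(spec)

    def test_section_outside_grid_rejected(self):
        spec = SlideSpec(grid_shape=(10, 10), sections=[SectionSpec("a", (5, 5), (10, 10))])
        with pytest.raises(ValueError, match="grid"):
            generate_slide(spec)


class TestCalibrationOnly:
    def test_single_spot_detected(self):
        grid, truth = generate_calibration_only(noise_free_spec())
        tio = log_transform(extract_ion_image(grid, TARGETS["tiotropium"].mz))
        assert len(detect_spots(tio)) == 1

    def test_sample_sections_dropped(self):
        spec = noise_free_spec()
        spec.sections.append(SectionSpec("sample", (2, 16), (1, 1), amount_ng=5.0))
        spec.grid_shape = (20, 20)
        _, truth = generate_calibration_only(spec)
        assert all(s.spots for s in truth.sections)

    def test_empty_spot_list_gives_background_only_grid(self):
        spec = SlideSpec(grid_shape=(6, 6), sections=[], seed=1)
        grid, truth = generate_calibration_only(spec)
        assert not truth.tissue_mask().any()
        tio = log_transform(extract_ion_image(grid, TARGETS["tiotropium"].mz))
        assert len(detect_spots(tio)) == 0


def test_default_design_matches_study_conditions():
    """5-point series 0.2-40 ng/uL x 0.5 uL drops x 4 replicates x 3 lipid
    levels, with a +10% intercept shift at the 8 mg/g level."""
    spec = default_calibration_spec()
    _, truth = generate_slide(spec)
    df = truth.design.with_amounts()
    assert sorted(df.conc_ng_per_ul.unique()) == [0.2, 2.0, 5.0, 20.0, 40.0]
    assert sorted(df.amount_ng.unique()) == [0.1, 1.0, 2.5, 10.0, 20.0]
    assert sorted(df.lipid_mg_per_g.unique()) == [0.0, 4.0, 8.0]
    assert df.groupby(["lipid_mg_per_g", "conc_ng_per_ul"]).size().eq(4).all()
    resp = spec.response
    assert resp.expected_ratio(0.0, 8.0) == pytest.approx(1.10 * resp.intercept)
    assert resp.line(8.0)[1] == resp.line(0.0)[1]
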