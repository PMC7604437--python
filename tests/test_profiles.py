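"""Distance bands, infiltration profiles, CIs, IF sections, quadrat test."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, box

import spatialtme as st
from spatialtme.profiles import T_CRITICAL, if_sections, quadrat_chi2


@pytest.fixture(scope="module")
def circle_partition():
    circle = Point(6000, 6000).buffer(5000, quad_segs=256)
    return st.partition_regions(circle, box(0, 0, 12000, 12000), if_width_mm=1.0)


@pytest.fixture(scope="module")
def circle_bands(circle_partition):
    return st.distance_bands(circle_partition)


class TestDistanceBands:
    def test_first_ct_band_annulus_area(self, circle_bands):
        # first CT-side band: 0-150 um inward of the 4.5 mm inner boundary
        areas = circle_bands.areas_mm2()
        want = np.pi * (4.5**2 - 4.35**2)
        assert areas[4] == pytest.approx(want, rel=0.05)

    def test_index_zero_band_is_if(self, circle_bands):
        assert circle_bands.band_region[0] == "IF"

    def test_number_of_ct_bands(self, circle_bands):
        # max CT depth 4.5 mm -> ceil(4.5/0.15) = 30 CT-side bands
        ct_indices = [i for i, r in circle_bands.band_region.items() if r == "CT"]
        assert len(ct_indices) == pytest.approx(30, abs=1)

    def test_signed_index_layout(self, circle_bands):
        reg = circle_bands.band_region
        assert all(reg[i] == "IF" for i in range(-3, 4))
        assert reg[4] == "CT" and reg[-4] == "N"

    def test_bands_cover_foreground(self, circle_partition, circle_bands):
        # band pixels account for ~all foreground area
        total = sum(circle_bands.areas_mm2().values())
        fg = circle_partition.foreground.area / 1e6
        assert total == pytest.approx(fg, rel=0.02)


class TestBandProfile:
    def test_homogeneous_profile_flat(self, circle_partition, circle_bands):
        pat = st.sim_poisson(200.0, box(0, 0, 12000, 12000), seed=5)
        prof = st.band_profile(pat, circle_bands)
        # every sufficiently large band is within 4 SD of the Poisson truth
        lam = 200.0
        big = prof[prof["area_mm2"] > 2.0]
        se = np.sqrt(lam / big["area_mm2"])
        assert (np.abs(big["density_mm2"] - lam) < 4 * se).all()

    def test_phantom_profile_peaks_in_if(self, phantom, phantom_partition):
        _, patterns, truth = phantom
        bands = st.distance_bands(truth)
        prof = st.band_profile(patterns[0], bands)
        peak = prof.loc[prof["density_mm2"].idxmax()]
        assert peak["region"] == "IF"

    def test_small_bands_dropped(self, circle_bands):
        pat = st.PointPattern("m", [(6000.0, 6000.0)], box(0, 0, 12000, 12000))
        prof = st.band_profile(pat, circle_bands)
        assert (prof["area_mm2"] >= 1.1).all()

    def test_empty_band_zero_density(self, circle_bands):
        pat = st.PointPattern("m", [(6000.0, 6000.0)], box(0, 0, 12000, 12000))
        prof = st.band_profile(pat, circle_bands)
        assert (prof.loc[prof["count"] == 0, "density_mm2"] == 0).all()


class TestConfidenceBand:
    def _profile(self, area, density, region="IF"):
        return pd.DataFrame(
            {
                "band_index": [0],
                "distance_mm": [0.0],
                "area_mm2": [area],
                "count": [int(density * area)],
                "density_mm2": [density],
                "region": [region],
            }
        )

    def test_halfwidth_arithmetic(self):
        # A = 1.6 mm2, 0.4 mm windows -> n = 10; half-width = 1.96 sigma / sqrt(10)
        out = st.confidence_band(self._profile(1.6, 100.0), {"IF": 30.0})
        half = T_CRITICAL * 30.0 / np.sqrt(10.0)
        assert out["n_windows"].iloc[0] == pytest.approx(10.0)
        assert out["ci_high"].iloc[0] - out["density_mm2"].iloc[0] == pytest.approx(half)

    def test_zero_sigma_reliable(self):
        out = st.confidence_band(self._profile(2.0, 50.0), {"IF": 0.0})
        assert out["ci_low"].iloc[0] == out["ci_high"].iloc[0] == 50.0
        assert bool(out["reliable"].iloc[0])

    def test_eighty_percent_rule_flags(self):
        # choose sigma so the half-width is 90% of D -> unreliable
        area, d = 1.6, 10.0
        sigma = 0.9 * d * np.sqrt(area / 0.16) / T_CRITICAL
        out = st.confidence_band(self._profile(area, d), {"IF": sigma})
        assert not bool(out["reliable"].iloc[0])
        assert out["ci_low"].iloc[0] == pytest.approx(d - 0.9 * d)

    def test_lower_ci_truncated_at_zero(self):
        # half-width 150% of D: lower bound clamps to zero (and unreliable)
        area, d = 1.6, 10.0
        sigma = 1.5 * d * np.sqrt(area / 0.16) / T_CRITICAL
        out = st.confidence_band(self._profile(area, d), {"IF": sigma})
        assert out["ci_low"].iloc[0] == 0.0
        assert not bool(out["reliable"].iloc[0])

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            st.confidence_band(self._profile(0.0, 1.0), {"IF": 1.0})


class TestIFSections:
    def test_section_count_circle(self, circle_partition):
        secs = if_sections(circle_partition, spacing_mm=0.2)
        # circumference 2*pi*5 mm / 0.2 mm = 157 sections
        assert len(secs) == pytest.approx(157, abs=1)

    def test_sections_partition_if(self, circle_partition):
        secs = if_sections(circle_partition)
        total = sum(s.area_mm2 for s in secs)
        if_area = circle_partition.areas_mm2()["IF"]
        assert total == pytest.approx(if_area, rel=0.01)

    def test_uniform_pattern_equal_densities(self, circle_partition):
        pat = st.sim_poisson(300.0, box(0, 0, 12000, 12000), seed=11)
        secs = if_sections(circle_partition, pat)
        dens = np.array([s.density_mm2 for s in secs])
        assert dens.std() / dens.mean() < 0.5  # Poisson noise only
        assert abs(dens.mean() - 300.0) / 300.0 < 0.1

    def test_indices_start_at_one_leftmost(self, circle_partition):
        secs = if_sections(circle_partition)
        assert secs[0].index == 1
        xs = [s.sample_point[0] for s in secs]
        assert secs[0].sample_point[0] == min(xs)


class TestQuadrat:
    def test_balanced_counts_no_signal(self):
        res = quadrat_chi2([50, 50], [1.0, 1.0])
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_pearson_example(self):
        res = quadrat_chi2([80, 20], [1.0, 1.0])
        assert res.chi2 == pytest.approx(36.0)
        assert res.df == 1

    def test_small_expected_warns(self):
        with pytest.warns(UserWarning):
            res = quadrat_chi2([1, 0, 0, 0, 0], [1.0] * 5)
        assert not res.valid

    def test_type_one_error_calibrated(self):
        # homogeneous allocation: rejection rate near alpha = 0.05
        rng = np.random.default_rng(6)
        areas = np.array([1.0, 2.0, 3.0, 4.0])
        p = areas / areas.sum()
        rej = 0
        nsim = 400
        for _ in range(nsim):
            counts = rng.multinomial(200, p)
            rej += quadrat_chi2(counts, areas).p_value < 0.05
        rate = rej / nsim
        assert 0.02 <= rate <= 0.09
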