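"""CSR testing, Ripley K, Thomas fitting, dispersion statistics."""

import numpy as np
import pytest
from shapely.geometry import box

import spatialtme as st
from spatialtme.pointprocess import ThomasModel, thomas_k


def brute_force_border_k(points, window, r_values):
    """Independent double-loop oracle for the border-corrected K."""
    import shapely

    pts = np.asarray(points, float)
    n = len(pts)
    area = window.area
    out = []
    for r in r_values:
        total = 0
        nv = 0
        for i in range(n):
            bi = shapely.distance(shapely.Point(pts[i]), window.boundary)
            if bi <= r:
                continue
            nv += 1
            for j in range(n):
                if j != i and np.hypot(*(pts[i] - pts[j])) <= r:
                    total += 1
        out.append(area * total / (nv * (n - 1)) if nv else np.nan)
    return np.array(out)


class TestRipleyK:
    def test_matches_brute_force_oracle(self, square_window):
        rng = np.random.default_rng(10)
        pat = st.PointPattern("m", rng.uniform(0, 1000, (100, 2)), square_window)
        r = np.array([25.0, 60.0, 120.0, 250.0])
        got = st.ripley_k(pat, r)
        want = brute_force_border_k(pat.points, square_window, r)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_csr_close_to_pi_r_squared(self, square_window):
        devs = []
        r = np.array([50.0, 100.0, 150.0])
        for seed in range(20):
            pat = st.sim_poisson(300.0, square_window, seed=seed)
            k = st.ripley_k(pat, r)
            devs.append(k / (np.pi * r**2))
        np.testing.assert_allclose(np.mean(devs, axis=0), 1.0, atol=0.1)

    def test_coincident_cluster_jump(self, square_window):
        pts = np.vstack([np.full((20, 2), 500.0), [[100.0, 100.0]]])
        pat = st.PointPattern("m", pts, square_window)
        k = st.ripley_k(pat, np.array([1.0]), warn_truncate=False)
        assert k[0] > np.pi * 1.0  # far above CSR at tiny r

    def test_needs_two_points(self, square_window):
        with pytest.raises(ValueError):
            st.ripley_k(st.PointPattern("m", [(1.0, 1.0)], square_window), np.array([10.0]))


class TestClarkEvans:
    def test_lattice_overdispersed(self, square_window):
        g = np.linspace(50, 950, 10)
        pts = np.array([(x, y) for x in g for y in g])
        res = st.clark_evans(st.PointPattern("m", pts, square_window))
        assert res.clark_evans_R > 1
        assert res.verdict == "not-clustered"

    def test_thomas_clustered(self, thomas_pattern):
        res = st.clark_evans(thomas_pattern)
        assert res.clark_evans_R < 1
        assert res.verdict == "clustered"

    def test_small_n_flagged(self, square_window):
        pat = st.PointPattern("m", [(1, 1), (5, 5), (9, 9)], square_window)
        assert st.clark_evans(pat).insufficient

    def test_one_point_rejected(self, square_window):
        with pytest.raises(ValueError):
            st.clark_evans(st.PointPattern("m", [(1.0, 1.0)], square_window))


class TestThomasFit:
    def test_closed_form_limits(self):
        # kappa large: K -> pi r^2 (Poisson limit of the cluster process)
        r = np.linspace(1, 100, 5)
        np.testing.assert_allclose(thomas_k(r, 1e9, 20.0), np.pi * r**2, rtol=1e-6)

    def test_recovery_single_seed(self, thomas_pattern):
        res = st.fit_thomas(thomas_pattern)
        assert res.converged
        assert 0.3 < res.kappa_mm2 / 10.0 < 3.0
        assert 0.3 < res.sigma_um / 20.0 < 3.0
        assert res.mu == pytest.approx(
            thomas_pattern.intensity_mm2 / res.kappa_mm2, rel=1e-9
        )

    def test_rayleigh_derived_fields(self, thomas_pattern):
        res = st.fit_thomas(thomas_pattern)
        md, r95 = st.rayleigh_summaries(res.sigma_um)
        assert res.mean_dist_um == pytest.approx(md)
        assert res.radius95_um == pytest.approx(r95)
        assert res.mean_dist_um < res.radius95_um
        assert "kappa" in res.summary()

    def test_too_few_points_rejected(self, square_window):
        pat = st.PointPattern("m", np.random.default_rng(0).uniform(0, 1000, (5, 2)), square_window)
        with pytest.raises(ValueError):
            ThomasModel(pat)


class TestRayleigh:
    @pytest.mark.parametrize(
        "sigma,want_mean,want_r95",
        [(1.0, 1.2533, 2.4477), (20.0, 25.066, 48.955)],
    )
    def test_closed_forms(self, sigma, want_mean, want_r95):
        mean, r95 = st.rayleigh_summaries(sigma)
        assert mean == pytest.approx(want_mean, abs=1e-3)
        assert r95 == pytest.approx(want_r95, abs=1e-2)

    def test_sigma_zero_limit(self):
        mean, r95 = st.rayleigh_summaries(0.0)
        assert mean == 0.0 and r95 == 0.0

    @pytest.mark.parametrize("f", [0.0, 100.0, -5.0])
    def test_invalid_f_rejected(self, f):
        with pytest.raises(ValueError):
            st.rayleigh_summaries(1.0, f)

    def test_coverage_simulation(self):
        # Rayleigh radius Q(95, sigma) contains ~95% of offspring
        rng = np.random.default_rng(0)
        d = np.linalg.norm(rng.normal(0, 20.0, (100_000, 2)), axis=1)
        frac = np.mean(d <= st.rayleigh_summaries(20.0)[1])
        assert frac == pytest.approx(0.95, abs=0.005)


class TestDispersion:
    def test_constant_vector(self):
        assert st.qcod([5, 5, 5, 5]) == 0.0
        assert st.cov([5, 5, 5, 5]) == 0.0

    def test_qcod_linear_interpolation(self):
        # {1..5}: Q1 = 2, Q3 = 4 under the type-7 rule
        assert st.qcod([1, 2, 3, 4, 5]) == pytest.approx(2.0 / 6.0)

    def test_cov_sample_sd(self):
        assert st.cov([2.0, 4.0]) == pytest.approx(np.sqrt(2) / 3)

    def test_degenerate_denominators(self):
        with pytest.raises(ValueError):
            st.qcod([-2.0, -1.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            st.cov([-1.0, 1.0])

    def test_region_table_shape(self):
        import pandas as pd

        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "marker": np.repeat(["CD3", "CD8"], 20),
                "region": list(np.tile(np.repeat(["N", "IF"], 10), 2)),
                "density_mm2": rng.uniform(10, 100, 40),
                "mu": rng.uniform(5, 30, 40),
                "mean_dist_um": rng.uniform(10, 40, 40),
                "cluster_area_mm2": rng.uniform(0.001, 0.01, 40),
            }
        )
        tbl = st.region_dispersion_table(df)
        assert len(tbl) == 4  # 2 markers x 2 regions
        qcods = tbl.filter(like="qcod_").to_numpy(float)
        assert ((qcods >= 0) & (qcods <= 1)).all()
        assert not tbl["flagged_small"].any()


class TestGofEnvelope:
    def test_small_nsim_rejected(self, thomas_pattern):
        fit = st.fit_thomas(thomas_pattern)
        with pytest.raises(ValueError):
            st.gof_envelope(thomas_pattern, fit, nsim=5, seed=0)

    def test_model_data_not_rejected(self, thomas_pattern):
        fit = st.fit_thomas(thomas_pattern)
        env = st.gof_envelope(thomas_pattern, fit, nsim=39, seed=1)
        assert env.p_value > 0.05
        assert env.lo.shape == env.hi.shape == env.l_obs.shape

    def test_poisson_data_rejected_against_cluster_fit(self, thomas_pattern, big_window):
        fit = st.fit_thomas(thomas_pattern)
        poisson = st.sim_poisson(thomas_pattern.intensity_mm2, big_window, seed=2)
        env = st.gof_envelope(poisson, fit, nsim=39, seed=3)
        assert env.p_value <= 0.05
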