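"""Kernel assembly and eigen-analysis of the integral projection model."""

import numpy as np
import pytest

from salipm import (
    FixedDemography,
    MeshConfig,
    VitalRateParams,
    build_kernel,
    lambda_and_stable,
    posterior_lambda,
    stable_summaries,
)


class TestMesh:
    def test_default_mesh_layout(self):
        m = MeshConfig()
        assert m.width == pytest.approx(0.65)
        assert len(m.midpoints) == 100
        assert m.midpoints[0] == pytest.approx(0.325)
        assert np.all(np.diff(m.midpoints) > 0)

    def test_invalid_mesh_rejected(self):
        with pytest.raises(ValueError):
            MeshConfig(lower=10, upper=5)


@pytest.fixture(scope="module")
def kernel(table1):
    return build_kernel(table1, season=1)


class TestKernelStructure:
    def test_entries_nonnegative(self, kernel):
        assert np.all(kernel.P >= 0)
        assert np.all(kernel.F >= 0)

    def test_growth_columns_sum_to_one(self, kernel):
        colsums = kernel.growth_columns.sum(axis=0)
        assert np.allclose(colsums, 1.0, atol=1e-10)

    def test_fecundity_zero_below_maturity(self, kernel):
        # cells entirely below the 36-mm threshold produce nothing; the cell
        # straddling the threshold may carry its mature fraction
        x = kernel.mesh.midpoints
        w = kernel.mesh.width
        assert np.all(kernel.F[:, x + w / 2 <= 36.0] == 0.0)
        assert kernel.F[:, x - w / 2 >= 36.0].sum() > 0

    def test_survival_bounds_P_columns(self, kernel, table1):
        # each P column transfers at most the largest annual survival
        from salipm.vital_rates import monthly_survival
        co = table1.resolve("site1", 1)
        smax = (monthly_survival(kernel.mesh.midpoints, co.e, co.f) ** 12).max()
        assert np.all(kernel.P.sum(axis=0) <= smax + 1e-12)

    def test_fecundity_only_kernel_matches_rank_one_closed_form(self, table1):
        """With survival forced to zero the kernel is rank one and lambda has
        the closed form S0 * H * ff * sum_i I_i * E(x_i) weighted correctly."""
        # survival ~ 0 via a huge hazard intercept
        p = table1.replace(e=30.0, season2_e=0.0, site2_e=0.0, site3_e=0.0)
        fixed = FixedDemography()
        k = build_kernel(p, fixed, season=1)
        assert np.allclose(k.P, 0.0, atol=1e-200)
        lam, v = lambda_and_stable(k)
        x = k.mesh.midpoints
        recruit = k.F[:, -1] / k.F[:, -1].sum()
        eggs = k.F.sum(axis=0)
        # rank-1 operator F = r e^T has eigenvalue e . r
        closed = float(eggs @ recruit)
        assert lam == pytest.approx(closed, rel=1e-10)

    def test_coarse_mesh_warns_about_juvenile_resolution(self, table1):
        with pytest.warns(UserWarning, match="juvenile"):
            build_kernel(table1, mesh=MeshConfig(n=30), season=1)

    def test_survival_timing_conventions_differ(self, table1):
        k_end = build_kernel(table1, season=1, survival_at="end")
        k_start = build_kernel(table1, season=1, survival_at="start")
        assert not np.allclose(k_end.P, k_start.P)
        with pytest.raises(ValueError):
            build_kernel(table1, season=1, survival_at="middle")


class TestEigenAnalysis:
    def test_diagonal_matrix(self):
        lam, v = lambda_and_stable(np.array([[0.5, 0.0], [0.0, 0.2]]))
        assert lam == pytest.approx(0.5, abs=1e-10)

    def test_power_iteration_matches_dense_solver(self, table1):
        for season in (1, 2):
            k = build_kernel(table1, season=season)
            lam, v = lambda_and_stable(k)  # raises if solvers disagree > 1e-8
            lam_dense = float(np.max(np.linalg.eigvals(k.A).real))
            assert lam == pytest.approx(lam_dense, abs=1e-8)

    def test_stable_distribution_normalized_nonnegative(self, table1):
        k = build_kernel(table1, season=1)
        _, v = lambda_and_stable(k)
        assert v.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(v >= -1e-12)

    def test_mesh_doubling_changes_lambda_under_half_percent(self, table1):
        for season in (1, 2):
            l100, _ = lambda_and_stable(build_kernel(table1, season=season))
            l200, _ = lambda_and_stable(
                build_kernel(table1, mesh=MeshConfig(n=200), season=season))
            assert abs(l200 - l100) / l100 < 0.005

    @pytest.mark.parametrize("knob", ["recruit_prob", "hatch_prob",
                                      "female_fraction"])
    def test_lambda_monotone_in_recruitment_constants(self, table1, knob):
        lams = []
        for val in (0.3, 0.6, 0.9):
            fixed = FixedDemography(**{knob: val})
            lam, _ = lambda_and_stable(build_kernel(table1, fixed, season=1))
            lams.append(lam)
        assert lams[0] < lams[1] < lams[2]


class TestPosteriorPropagation:
    def test_degenerate_draws_collapse_to_point_estimate(self, table1):
        lp = posterior_lambda([table1] * 5, season=1)
        lam0, _ = lambda_and_stable(build_kernel(table1, season=1))
        assert np.allclose(lp.lam, lam0)
        assert lp.summary()["lambda_2.5%"] == pytest.approx(lam0)

    def test_interval_widens_with_draw_dispersion(self, table1, rng):
        from salipm import posterior_sd_params
        sds = posterior_sd_params().to_vector()
        base = table1.to_vector()

        def draws(scale, n=60):
            out = []
            r = np.random.default_rng(9)
            for _ in range(n):
                vec = base + scale * sds * r.standard_normal(len(base))
                vec[-1] = abs(vec[-1]) + 0.1
                out.append(VitalRateParams.from_vector(vec))
            return out

        lp_small = posterior_lambda(draws(0.2), season=1)
        lp_big = posterior_lambda(draws(0.4), season=1)
        w = lambda lp: lp.summary()["lambda_97.5%"] - lp.summary()["lambda_2.5%"]
        assert w(lp_big) > w(lp_small)

    def test_seasonal_stable_structures_are_close_but_distinct(self, table1):
        """Both seasonal kernels put ~3/4 of stable mass below maturity; the
        two size structures differ in mean size rather than juvenile share."""
        out = {}
        for season in (1, 2):
            k = build_kernel(table1, season=season)
            _, v = lambda_and_stable(k)
            out[season] = stable_summaries(v, k.mesh)
        assert out[1]["prop_juvenile"] == pytest.approx(
            out[2]["prop_juvenile"], abs=0.05)
        assert out[1]["mean_size"] > out[2]["mean_size"]

    def test_maternal_size_link_shifts_recruit_sizes(self, table1):
        fixed = FixedDemography(maternal_link_slope=0.5)
        k = build_kernel(table1, fixed, season=1)
        x = k.mesh.midpoints
        big = np.argmin(np.abs(x - 50.0))
        small = np.argmin(np.abs(x - 37.0))
        mean_big = float((x * k.F[:, big]).sum() / k.F[:, big].sum())
        mean_small = float((x * k.F[:, small]).sum() / k.F[:, small].sum())
        assert mean_big > mean_small
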