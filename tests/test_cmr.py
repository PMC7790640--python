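"""Tests of the joint capture–recapture likelihood and sampler.

The CJS marginal likelihood is checked against closed-form two-occasion
values and against brute-force enumeration over every consistent alive/dead
path on small histories.
"""

import math

import numpy as np
import pandas as pd
import pytest

from salipm import (
    CaptureData,
    CaptureRecaptureModel,
    CaptureRecapturePosterior,
    MCMCConfig,
    PARAM_NAMES,
    SurveyDesign,
    VitalRateParams,
    cjs_history_loglik,
)
from salipm.vital_rates import interval_survival, recapture_prob


def _data_from_histories(histories, times, sizes, season_break=None):
    """Build CaptureData from 0/1 histories with per-individual sizes."""
    rows = []
    for i, (hist, size) in enumerate(zip(histories, sizes)):
        for j, y in enumerate(hist):
            if y:
                rows.append({"id": f"i{i}", "site": "site1", "occasion": j,
                             "month_offset": times[j], "size_mm": size,
                             "eggs": np.nan})
    df = pd.DataFrame(rows)
    brk = {"site1": season_break} if season_break is not None else {}
    return CaptureData(records=df, season_break=brk)


def _brute_force_cjs(y, phi, p):
    """Enumerate death intervals: exact CJS likelihood for one history."""
    y = np.asarray(y, int)
    J = len(y)
    first = int(np.argmax(y))
    last = J - 1 - int(np.argmax(y[::-1]))
    total = 0.0
    for k in range(last, J):          # alive through occasion k, dies after
        prob = 1.0
        for j in range(first, k):     # survived intervals first..k-1
            prob *= phi[j]
        if k < J - 1:
            prob *= 1.0 - phi[k]
        for j in range(first + 1, k + 1):
            prob *= p[j - 1] if y[j] else 1.0 - p[j - 1]
        total += prob
    return math.log(total)


class TestCJSLikelihood:
    def test_two_occasion_closed_forms(self):
        # S_m = 0.9 over one month, p = 0.3: "11" -> 0.27, "10" -> 0.73
        e = math.log(-math.log(0.9))
        g = math.log(0.3 / 0.7)
        params = VitalRateParams(e=e, f=0.0, g=g, h=0.0)
        times = [0.0, 1.0, 2.0, 3.0]
        design = SurveyDesign(occasion_times={"site1": times},
                              season_break={"site1": 2},
                              n_initial={"site1": 1})
        data = _data_from_histories([[1, 1, 1, 1], [1, 1, 1, 0]],
                                    times, [30.0, 30.0], season_break=2)
        model = CaptureRecaptureModel(data, design)
        ll = model.loglik_cjs(params)
        # "1111": phi p three times; "1110": phi p twice then chi = 0.1+0.9*0.7
        expected = 3 * math.log(0.9 * 0.3) + 2 * math.log(0.9 * 0.3) + math.log(0.73)
        assert ll == pytest.approx(expected, abs=1e-10)
        assert cjs_history_loglik([1, 1], [0.9], [0.3]) == pytest.approx(
            math.log(0.27), abs=1e-12)
        assert cjs_history_loglik([1, 0], [0.9], [0.3]) == pytest.approx(
            math.log(0.73), abs=1e-12)

    def test_matches_brute_force_enumeration(self, table1, rng):
        """Model likelihood equals path enumeration on <=6-occasion histories."""
        times = [0.0, 1.5, 2.5, 4.0, 12.0, 13.5]
        brk = 4
        design = SurveyDesign(occasion_times={"site1": times},
                              season_break={"site1": brk},
                              n_initial={"site1": 1})
        histories, sizes = [], []
        for _ in range(25):
            y = rng.integers(0, 2, size=6)
            if y.sum() == 0:
                y[rng.integers(6)] = 1
            histories.append(list(y))
            sizes.append(float(rng.uniform(18, 50)))
        data = _data_from_histories(histories, times, sizes, season_break=brk)
        model = CaptureRecaptureModel(data, design)
        params = table1

        # oracle: per-history phi/p arrays from the same link functions
        total = 0.0
        dts = np.diff(times)
        co1 = params.resolve("site1", 1)
        co2 = params.resolve("site1", 2)
        for hist, size in zip(histories, sizes):
            y = np.asarray(hist)
            x1 = size
            seen1 = y[:brk].any()
            seen2 = y[brk:].any()
            # the model averages observed sizes per season; size is constant
            # here, and season-2 size is imputed at the growth mean when the
            # individual was never measured in season 2
            if seen1 and not seen2:
                x2 = math.exp(-co1.K) * x1 + co1.L * (1 - math.exp(-co1.K))
            else:
                x2 = size
            xo = [x1 if j < brk else x2 for j in range(6)]
            phi = np.array([
                interval_survival(xo[j], co1.e if j < brk else co2.e,
                                  co1.f if j < brk else co2.f, dts[j])
                for j in range(5)])
            p = np.array([
                recapture_prob(xo[j + 1], co1.g if j + 1 < brk else co2.g,
                               co1.h if j + 1 < brk else co2.h)
                for j in range(5)])
            total += _brute_force_cjs(y, phi, p)
            assert cjs_history_loglik(y, phi, p) == pytest.approx(
                _brute_force_cjs(y, phi, p), abs=1e-12)
        assert model.loglik_cjs(params) == pytest.approx(total, abs=1e-9)

    def test_jit_path_agrees_with_numpy_reference(self, small_data, table1):
        model = CaptureRecaptureModel(small_data)
        assert model.loglik_cjs(table1) == pytest.approx(
            model.loglik_cjs_numpy(table1), abs=1e-8)

    def test_growth_term_centered_at_fixed_point(self, table1):
        """An individual measured at L in both seasons contributes the normal
        density at zero residual."""
        times = [0.0, 1.0, 12.0, 13.0]
        design = SurveyDesign(occasion_times={"site1": times},
                              season_break={"site1": 2},
                              n_initial={"site1": 1})
        L = table1.L
        data = _data_from_histories([[1, 1, 1, 1], [1, 0, 1, 0]], times,
                                    [L, L], season_break=2)
        model = CaptureRecaptureModel(data, design)
        var = table1.a + table1.b * L
        expected = 2 * (-0.5 * (math.log(2 * math.pi) + math.log(var)))
        assert model.loglik_growth(table1) == pytest.approx(expected, abs=1e-9)


class TestJointDecomposition:
    def test_removing_egg_records_changes_only_egg_terms(self, small_data, table1):
        model = CaptureRecaptureModel(small_data)
        df = small_data.records.copy()
        df["eggs"] = np.nan
        stripped = CaptureData(records=df)
        model2 = CaptureRecaptureModel(stripped)
        assert model2.loglik_eggs(table1) == 0.0
        assert model.loglik_eggs(table1) != 0.0
        assert model2.loglik_cjs(table1) == pytest.approx(
            model.loglik_cjs(table1), abs=1e-9)
        assert model2.loglik_growth(table1) == pytest.approx(
            model.loglik_growth(table1), abs=1e-9)
        assert model.loglik(table1) == pytest.approx(
            model.loglik_cjs(table1) + model.loglik_growth(table1)
            + model.loglik_eggs(table1), abs=1e-9)

    def test_no_recaptures_aborts_with_message(self):
        times = [0.0, 1.0, 2.0, 12.0]
        df = pd.DataFrame({
            "id": ["a", "b"], "site": ["site1"] * 2, "occasion": [0, 1],
            "month_offset": [0.0, 1.0], "size_mm": [30.0, 40.0],
            "eggs": [np.nan, np.nan]})
        data = CaptureData(records=df, season_break={"site1": 2})
        design = SurveyDesign(occasion_times={"site1": times},
                              season_break={"site1": 2}, n_initial={"site1": 1})
        with pytest.raises(ValueError, match="no recaptured individuals"):
            CaptureRecaptureModel(data, design)


def _synthetic_posterior(draws_by_chain):
    cfg = MCMCConfig(chains=draws_by_chain.shape[0],
                     iterations=2 * draws_by_chain.shape[1],
                     burn_in=draws_by_chain.shape[1], thin=1, seed=0)
    return CaptureRecapturePosterior(
        draws=draws_by_chain, config=cfg,
        accept_rates=np.full((draws_by_chain.shape[0], 4), 0.3))


class TestPosteriorSummary:
    def test_constant_column_collapses(self, rng):
        draws = rng.standard_normal((2, 500, len(PARAM_NAMES)))
        draws[:, :, 0] = 0.473
        post = _synthetic_posterior(draws)
        s = post.summary()
        assert s.loc["K", "mean"] == pytest.approx(0.473)
        assert s.loc["K", "sd"] == pytest.approx(0.0, abs=1e-12)
        assert s.loc["K", "2.5%"] == s.loc["K", "97.5%"] == pytest.approx(0.473)

    def test_normal_column_quantiles_match_closed_form(self, rng):
        draws = rng.standard_normal((2, 5000, len(PARAM_NAMES)))
        post = _synthetic_posterior(draws)
        lo, hi = post.credible_interval("L")
        assert lo == pytest.approx(-1.96, abs=0.08)
        assert hi == pytest.approx(1.96, abs=0.08)

    def test_layout_contains_every_parameter_row(self, rng):
        draws = rng.standard_normal((2, 100, len(PARAM_NAMES)))
        s = _synthetic_posterior(draws).summary()
        assert list(s.index) == list(PARAM_NAMES)
        assert list(s.columns) == ["mean", "sd", "2.5%", "97.5%", "rhat"]


@pytest.fixture(scope="module")
def quick_fit(small_data):
    model = CaptureRecaptureModel(small_data)
    cfg = MCMCConfig(chains=2, iterations=1200, burn_in=600, thin=3, seed=77)
    return model, cfg, model.fit(cfg)


class TestSampler:
    def test_seeded_fit_is_reproducible(self, small_data, quick_fit):
        model, cfg, post = quick_fit
        post2 = CaptureRecaptureModel(small_data).fit(cfg)
        assert np.array_equal(post.draws, post2.draws)

    def test_draw_shape_and_finiteness(self, quick_fit):
        _, cfg, post = quick_fit
        assert post.draws.shape == (2, 200, len(PARAM_NAMES))
        assert np.all(np.isfinite(post.draws))
        assert post.n_draws == 400
        assert (post.draws[:, :, PARAM_NAMES.index("sigma2_egg")] > 0).all()

    def test_diagnostics_and_dataframe_round(self, quick_fit):
        _, _, post = quick_fit
        assert set(post.rhat.index) == set(PARAM_NAMES)
        df = post.to_dataframe()
        assert list(df.columns)[:2] == ["chain", "draw"]
        assert len(df) == 400

    def test_acceptance_rates_in_working_range(self, quick_fit):
        _, _, post = quick_fit
        assert (post.accept_rates > 0.05).all()
        assert (post.accept_rates < 0.8).all()
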