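"""Joint Bayesian capture–mark–recapture model.

A single likelihood combines three data streams from one capture-history
table:

* **CJS survival/recapture** — conditional on first capture, each individual's
  detection history contributes Bernoulli survival transitions (monthly
  survival from the log-log hazard link, raised to the interval length on the
  half-month grid) and Bernoulli detections (logit-linear in size). The
  latent alive states are marginalized analytically with the standard
  chi-recursion, so the likelihood is exact without sampling alive states.
* **von Bertalanffy growth** — seasonal mean size in the second season is
  normal around the Fabens increment prediction with variance linear in
  first-season size. Individuals never measured in season 2 have their
  season-2 survival/recapture covariate imputed at the growth-model mean.
* **egg counts** — one count per gravid female and season, normal around the
  linear size–fecundity prediction with a fitted residual variance.

Priors are vague normals (mean 0, variance 100) on all regression
coefficients and on the log egg residual variance. Sampling is by adaptive
block Metropolis (random-walk proposals with empirically adapted covariance
per coefficient block), with convergence assessed by the Gelman–Rubin
diagnostic (R-hat < 1.01 rule).

Usage follows the fitted-model idiom::

    model = CaptureRecaptureModel(data)
    post = model.fit(MCMCConfig(seed=1))
    post.summary()          # Table-1-style posterior table
    post.params_at_mean()   # VitalRateParams at posterior means
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numba as _numba
import numpy as np
import pandas as pd

from .capture import CaptureData
from .design import SurveyDesign
from .params import PARAM_NAMES, SITES, VitalRateParams
from .vital_rates import EPS_VAR

__all__ = [
    "MCMCConfig",
    "CaptureRecaptureModel",
    "CaptureRecapturePosterior",
    "cjs_history_loglik",
]

_LOG2PI = math.log(2.0 * math.pi)

# sampler vector: PARAM_NAMES with sigma2_egg replaced by its log
_IDX = {n: i for i, n in enumerate(PARAM_NAMES)}
_ILOGS2 = _IDX["sigma2_egg"]

_GROWTH_BLOCK = [_IDX[n] for n in
                 ("K", "L", "site2_K", "site3_K", "site2_L", "site3_L",
                  "a", "b", "site2_a", "site3_a", "site2_b", "site3_b")]
_EGG_BLOCK = [_IDX[n] for n in
              ("c", "d", "season2_c", "season2_d", "site2_c", "site3_c",
               "sigma2_egg")]
_HAZ_BLOCK = [_IDX[n] for n in
              ("e", "f", "season2_e", "season2_f", "site2_e", "site3_e")]
_RECAP_BLOCK = [_IDX[n] for n in
                ("g", "h", "season2_g", "season2_h", "site2_g", "site3_g")]

# initial random-walk scales, one per parameter (roughly posterior-SD sized)
_INIT_SCALE = {
    "K": 0.03, "L": 0.25, "site2_K": 0.06, "site3_K": 0.05,
    "site2_L": 0.3, "site3_L": 0.3,
    "a": 0.15, "b": 0.004, "site2_a": 0.3, "site3_a": 0.25,
    "site2_b": 0.008, "site3_b": 0.006,
    "c": 0.8, "d": 0.02, "season2_c": 1.0, "season2_d": 0.025,
    "site2_c": 0.12, "site3_c": 0.11,
    "e": 0.12, "f": 0.003, "season2_e": 0.25, "season2_f": 0.007,
    "site2_e": 0.06, "site3_e": 0.05,
    "g": 0.13, "h": 0.003, "season2_g": 0.2, "season2_h": 0.005,
    "site2_g": 0.05, "site3_g": 0.04,
    "sigma2_egg": 0.1,   # on the log scale
}


@dataclass
class MCMCConfig:
    """Sampler settings.

    Defaults are desk-scale (3 chains of 10,000 with 5,000 burn-in, thinning
    5). ``publication_settings`` returns the long run used for final
    inference (3 x 100,000, 50,000 burn-in, thin 50).
    """

    chains: int = 3
    iterations: int = 10_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0
    adapt_start: int = 200

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if (self.iterations - self.burn_in) % self.thin:
            raise ValueError("(iterations - burn_in) must be divisible by thin")

    @classmethod
    def publication_settings(cls, seed: int = 0) -> "MCMCConfig":
        return cls(chains=3, iterations=100_000, burn_in=50_000, thin=50, seed=seed)


@_numba.njit(cache=False, fastmath=False)
def _cjs_ll_jit(x1, x2, is_s1, idx_int, idx_occ, dt, valid, Ynext, M, last,
                e_t, f_t, g_t, h_t):  # pragma: no cover - exercised via wrapper
    N, Jm1 = idx_int.shape
    ll = 0.0
    for i in range(N):
        chi = 1.0
        chil = 1.0 if last[i] == Jm1 else 0.0
        for j in range(Jm1 - 1, -1, -1):
            xj = x1[i] if is_s1[i, j] else x2[i]
            xn = x1[i] if is_s1[i, j + 1] else x2[i]
            if valid[i, j]:
                # log-log link: cumulative hazard over the interval is
                # exp(e + f x) * dt, so log phi is available in closed form
                cumhaz = math.exp(e_t[idx_int[i, j]] + f_t[idx_int[i, j]] * xj) * dt[i, j]
                phi = math.exp(-cumhaz)
            else:
                cumhaz = np.inf
                phi = 0.0
            eta = g_t[idx_occ[i, j]] + h_t[idx_occ[i, j]] * xn
            if eta >= 0.0:
                q = math.exp(-eta)          # = (1-p)/p
                p = 1.0 / (1.0 + q)
            else:
                ee = math.exp(eta)
                p = ee / (1.0 + ee)
            chi = (1.0 - phi) + phi * (1.0 - p) * chi
            if j == last[i]:
                chil = chi
            if M[i, j]:
                ll -= cumhaz
                if Ynext[i, j]:
                    ll += math.log(max(p, 1e-300))
                else:
                    ll += math.log(max(1.0 - p, 1e-300))
        ll += math.log(max(chil, 1e-300))
    return ll


def cjs_history_loglik(y: np.ndarray, phi: np.ndarray, p: np.ndarray) -> float:
    """Marginal CJS log-likelihood of one detection history.

    ``y`` is the 0/1 history over J occasions (first 1 = first capture),
    ``phi[j]`` the survival probability over interval j -> j+1 and ``p[j]``
    the detection probability at occasion j+1. Alive states are marginalized
    by the chi-recursion.
    """
    y = np.asarray(y, dtype=int)
    J = len(y)
    first = int(np.argmax(y))
    last = J - 1 - int(np.argmax(y[::-1]))
    chi = np.ones(J)
    for j in range(J - 2, -1, -1):
        chi[j] = (1.0 - phi[j]) + phi[j] * (1.0 - p[j]) * chi[j + 1]
    ll = 0.0
    for j in range(first, last):
        ll += math.log(phi[j])
        ll += math.log(p[j]) if y[j + 1] else math.log(1.0 - p[j])
    return ll + math.log(chi[last])


class _StackedData:
    """All individuals stacked across sites, padded to a common occasion grid.

    Sites have different numbers of occasions; histories are padded on the
    right. Padded intervals get survival 0, which closes the chi-recursion at
    the site's true final occasion without branching.
    """

    def __init__(self, site_tables: list[tuple[str, pd.DataFrame, np.ndarray, int]]):
        Jmax = max(len(t) for _, _, t, _ in site_tables)
        self.Jmax = Jmax
        self.sites = [s for s, _, _, _ in site_tables]
        S = len(site_tables)

        occ_season = np.ones((S, Jmax), dtype=int)      # 1 or 2; padded = 2
        valid_int = np.zeros((S, Jmax - 1), dtype=bool)
        dts = np.ones((S, Jmax - 1))
        for si, (_, _, times, brk) in enumerate(site_tables):
            J = len(times)
            occ_season[si, :J] = np.where(np.arange(J) < brk, 1, 2)
            occ_season[si, J:] = 2
            valid_int[si, :J - 1] = True
            dts[si, :J - 1] = np.diff(times)

        Ys, firsts, lasts, site_idx = [], [], [], []
        x1l, x2l, has1l, has2l = [], [], [], []
        gx1, gx2, gsite = [], [], []
        for si, (site, g, times, _) in enumerate(site_tables):
            J = len(times)
            ids = g["id"].unique()
            idx = {v: i for i, v in enumerate(ids)}
            n = len(ids)
            Y = np.zeros((n, Jmax), dtype=bool)
            Y[g["id"].map(idx).to_numpy(), g["occasion"].to_numpy()] = True
            occ = np.arange(Jmax)
            firsts.append(np.where(Y, occ, Jmax).min(axis=1))
            lasts.append(np.where(Y, occ, -1).max(axis=1))
            Ys.append(Y)
            site_idx.append(np.full(n, si))

            x1 = np.full(n, np.nan)
            x2 = np.full(n, np.nan)
            sz = g.groupby(["id", "season"], sort=False)["size_mm"].mean()
            for (iid, season), v in sz.items():
                (x1 if season == 1 else x2)[idx[iid]] = v
            has1, has2 = np.isfinite(x1), np.isfinite(x2)
            grow = has1 & has2
            gx1.append(x1[grow])
            gx2.append(x2[grow])
            gsite.append(np.full(int(grow.sum()), si))
            fill = np.nanmean(np.concatenate([x1[has1], x2[has2]]))
            x1l.append(np.where(has1, x1, fill))
            x2l.append(np.where(has2, x2, fill))
            has1l.append(has1)
            has2l.append(has2)

        self.Y = np.concatenate(Ys)
        self.first = np.concatenate(firsts)
        self.last = np.concatenate(lasts)
        self.site_idx = np.concatenate(site_idx)
        self.x1 = np.concatenate(x1l)
        self.x2_obs = np.concatenate(x2l)
        self.has2 = np.concatenate(has2l)
        self.gx1 = np.concatenate(gx1)
        self.gx2 = np.concatenate(gx2)
        self.gsite = np.concatenate(gsite)
        self.n = len(self.x1)

        jj = np.arange(Jmax - 1)
        self.M = (self.first[:, None] <= jj) & (jj < self.last[:, None])
        self.dt_ind = dts[self.site_idx]                       # (N, Jmax-1)
        self.valid_ind = valid_int[self.site_idx]
        self.is_s1_occ = occ_season[self.site_idx] == 1        # (N, Jmax)
        # gather indices into flattened (site, season) coefficient tables,
        # laid out as flat[2 * si + (season - 1)]
        int_season = occ_season[:, :-1]                        # season charged to interval
        self.idx_int = (2 * self.site_idx[:, None]
                        + (int_season[self.site_idx] - 1))     # (N, Jmax-1)
        occ_next = occ_season[:, 1:]
        self.idx_occ = (2 * self.site_idx[:, None]
                        + (occ_next[self.site_idx] - 1))
        self.Ynext = self.Y[:, 1:]


class CaptureRecaptureModel:
    """Joint CJS + growth + egg-count model built from a capture table."""

    def __init__(self, data: CaptureData, design: SurveyDesign | None = None):
        self.data = data
        df = data.records
        if len(df) == 0:
            raise ValueError("empty capture data")
        site_tables = []
        for site, g in df.groupby("site", sort=True):
            if design is not None:
                times = design.occasion_times[site]
                brk = design.season_break[site]
            else:
                tbl = (g.drop_duplicates("occasion")
                        .sort_values("occasion")[["occasion", "month_offset"]])
                occ = tbl["occasion"].to_numpy()
                if not np.array_equal(occ, np.arange(occ.max() + 1)):
                    raise ValueError(
                        f"{site}: occasions {sorted(set(range(occ.max() + 1)) - set(occ))} "
                        "have no detections; pass a SurveyDesign to define the grid")
                times = tbl["month_offset"].to_numpy()
                brk = data.season_break[site]
            site_tables.append((site, g, np.asarray(times, float), brk))
        self._site_names = [s for s, _, _, _ in site_tables]
        self._stk = _StackedData(site_tables)

        if int(((self._stk.last - self._stk.first) > 0).sum()) == 0:
            raise ValueError("no recaptured individuals: survival/recapture "
                             "parameters are not estimable")
        eg = data.egg_records()
        self._n_growth = len(self._stk.gx1)
        # egg arrays with flat (site, season) index, matching _StackedData layout
        site_pos = {s: i for i, s in enumerate(self._site_names)}
        self._egg = eg
        self._egg_x = eg["size"].to_numpy()
        self._egg_y = eg["eggs"].to_numpy()
        self._egg_idx = (2 * eg["site"].map(site_pos).to_numpy()
                         + (eg["season"].to_numpy() - 1))

    def _coeff_tables(self, params: VitalRateParams):
        """Flattened per-(site, season) effective coefficients, flat[2 si + s - 1].

        Equivalent to ``params.resolve(site, season)`` for every pair, inlined
        on the hot path of the sampler.
        """
        p = params
        out = {k: np.empty(2 * len(self._site_names)) for k in
               ("K", "L", "a", "b", "c", "d", "e", "f", "g", "h")}
        for si, site in enumerate(self._site_names):
            sfx = None if site == "site1" else site

            def o(base):
                return getattr(p, f"{sfx}_{base}") if sfx else 0.0

            i1, i2 = 2 * si, 2 * si + 1
            for k in ("K", "L", "a", "b"):        # season-independent
                out[k][i1] = out[k][i2] = getattr(p, k) + o(k)
            out["c"][i1] = p.c + o("c")
            out["c"][i2] = p.c + o("c") + p.season2_c
            out["d"][i1] = p.d
            out["d"][i2] = p.d + p.season2_d
            out["e"][i1] = p.e + o("e")
            out["e"][i2] = p.e + o("e") + p.season2_e
            out["f"][i1] = p.f
            out["f"][i2] = p.f + p.season2_f
            out["g"][i1] = p.g + o("g")
            out["g"][i2] = p.g + o("g") + p.season2_g
            out["h"][i1] = p.h
            out["h"][i2] = p.h + p.season2_h
        return out

    # ------------------------------------------------------------------
    # likelihood components (theta = sampler vector, log-variance slot)
    # ------------------------------------------------------------------
    @staticmethod
    def _params_from_theta(theta: np.ndarray) -> VitalRateParams:
        vec = np.array(theta, dtype=float)
        vec[_ILOGS2] = np.exp(vec[_ILOGS2])
        return VitalRateParams.from_vector(vec)

    @staticmethod
    def theta_from_params(params: VitalRateParams) -> np.ndarray:
        vec = params.to_vector()
        vec[_ILOGS2] = np.log(vec[_ILOGS2])
        return vec

    def loglik_growth(self, params: VitalRateParams) -> float:
        stk = self._stk
        tb = self._coeff_tables(params)
        K = tb["K"][2 * stk.gsite]
        L = tb["L"][2 * stk.gsite]
        if np.any(K <= 0) or np.any(L <= 0):
            return -np.inf
        r = np.exp(-K)
        mu = r * stk.gx1 + L * (1.0 - r)
        var = np.maximum(tb["a"][2 * stk.gsite] + tb["b"][2 * stk.gsite] * stk.gx1,
                         EPS_VAR)
        return float(-0.5 * np.sum(_LOG2PI + np.log(var) + (stk.gx2 - mu) ** 2 / var))

    def loglik_eggs(self, params: VitalRateParams) -> float:
        if len(self._egg_y) == 0:
            return 0.0
        s2 = params.sigma2_egg
        if not np.isfinite(s2) or s2 <= 0:
            return -np.inf
        tb = self._coeff_tables(params)
        mu = tb["c"][self._egg_idx] + tb["d"][self._egg_idx] * self._egg_x
        r = self._egg_y - mu
        return float(-0.5 * np.sum(_LOG2PI + math.log(s2) + r * r / s2))

    def loglik_cjs(self, params: VitalRateParams) -> float:
        """CJS marginal log-likelihood (jitted path, numpy reference below)."""
        stk = self._stk
        tb = self._coeff_tables(params)
        Ksite = tb["K"][2 * stk.site_idx]
        Lsite = tb["L"][2 * stk.site_idx]
        if np.any(Ksite <= 0) or np.any(Lsite <= 0):
            return -np.inf
        r = np.exp(-Ksite)
        x2 = np.where(stk.has2, stk.x2_obs, r * stk.x1 + Lsite * (1.0 - r))
        return float(_cjs_ll_jit(
            stk.x1, x2, stk.is_s1_occ, stk.idx_int, stk.idx_occ,
            stk.dt_ind, stk.valid_ind, stk.Ynext, stk.M, stk.last,
            tb["e"], tb["f"], tb["g"], tb["h"]))

    def loglik_cjs_numpy(self, params: VitalRateParams) -> float:
        stk = self._stk
        tb = self._coeff_tables(params)
        Ksite = tb["K"][2 * stk.site_idx]
        Lsite = tb["L"][2 * stk.site_idx]
        if np.any(Ksite <= 0) or np.any(Lsite <= 0):
            return -np.inf
        # season-2 covariate: observed mean, or growth-model imputation
        r = np.exp(-Ksite)
        x2 = np.where(stk.has2, stk.x2_obs, r * stk.x1 + Lsite * (1.0 - r))
        X = np.where(stk.is_s1_occ, stk.x1[:, None], x2[:, None])

        Sm = np.exp(-np.exp(tb["e"][stk.idx_int] + tb["f"][stk.idx_int] * X[:, :-1]))
        phi = np.where(stk.valid_ind, Sm ** stk.dt_ind, 0.0)
        eta = tb["g"][stk.idx_occ] + tb["h"][stk.idx_occ] * X[:, 1:]
        p = 1.0 / (1.0 + np.exp(-eta))

        Jm = stk.Jmax
        chi = np.ones((stk.n, Jm))
        for j in range(Jm - 2, -1, -1):
            chi[:, j] = (1.0 - phi[:, j]) + phi[:, j] * (1.0 - p[:, j]) * chi[:, j + 1]

        det = np.where(stk.Ynext, np.log(np.clip(p, 1e-300, 1.0)),
                       np.log(np.clip(1.0 - p, 1e-300, 1.0)))
        terms = np.log(np.clip(phi, 1e-300, 1.0)) + det
        ll = float(np.sum(terms, where=stk.M))
        ll += float(np.sum(np.log(np.clip(
            np.take_along_axis(chi, stk.last[:, None], axis=1)[:, 0], 1e-300, 1.0))))
        return ll

    def loglik(self, params: VitalRateParams) -> float:
        """Joint log-likelihood (CJS + growth + egg terms)."""
        return (self.loglik_cjs(params) + self.loglik_growth(params)
                + self.loglik_eggs(params))

    @staticmethod
    def log_prior(theta: np.ndarray) -> float:
        # N(0, 10^2) on every coefficient and on log sigma2_egg
        return float(-0.5 * np.sum(theta * theta) / 100.0)

    # ------------------------------------------------------------------
    # starting values
    # ------------------------------------------------------------------
    def _start_theta(self) -> np.ndarray:
        params = VitalRateParams()
        gx1, gx2 = self._stk.gx1, self._stk.gx2
        theta = self.theta_from_params(params)
        if len(gx1) >= 10:
            A = np.c_[gx1, np.ones_like(gx1)]
            slope, intercept = np.linalg.lstsq(A, gx2, rcond=None)[0]
            slope = float(np.clip(slope, 0.25, 0.95))
            theta[_IDX["K"]] = -math.log(slope)
            theta[_IDX["L"]] = float(np.clip(intercept / (1.0 - slope), 25.0, 70.0))
        eg = self._egg
        if len(eg) >= 10:
            A = np.c_[eg["size"].to_numpy(), np.ones(len(eg))]
            d0, c0 = np.linalg.lstsq(A, eg["eggs"].to_numpy(), rcond=None)[0]
            theta[_IDX["c"]] = c0
            theta[_IDX["d"]] = d0
            resid = eg["eggs"].to_numpy() - (c0 + d0 * eg["size"].to_numpy())
            theta[_ILOGS2] = math.log(max(float(np.var(resid)), 0.25))
        return theta

    # ------------------------------------------------------------------
    # sampler
    # ------------------------------------------------------------------
    def fit(self, config: MCMCConfig | None = None,
            progress: bool = False) -> "CaptureRecapturePosterior":
        """Run the adaptive block-Metropolis sampler; return the posterior."""
        config = config or MCMCConfig()
        ss = np.random.SeedSequence(config.seed)
        chain_seeds = ss.spawn(config.chains)
        n_keep = (config.iterations - config.burn_in) // config.thin
        npar = len(PARAM_NAMES)
        draws = np.empty((config.chains, n_keep, npar))
        accept = np.zeros((config.chains, 4))

        blocks = [np.array(b) for b in
                  (_GROWTH_BLOCK, _EGG_BLOCK, _HAZ_BLOCK, _RECAP_BLOCK)]
        # which cached components each block touches: (growth, eggs, cjs)
        touches = [(True, False, True), (False, True, False),
                   (False, False, True), (False, False, True)]
        init_sd = np.array([_INIT_SCALE[n] for n in PARAM_NAMES])
        theta0 = self._start_theta()

        for ci in range(config.chains):
            rng = np.random.default_rng(chain_seeds[ci])
            theta = theta0 + 2.0 * init_sd * rng.standard_normal(npar)
            params = self._params_from_theta(theta)
            ll = {"growth": self.loglik_growth(params),
                  "eggs": self.loglik_eggs(params),
                  "cjs": self.loglik_cjs(params)}
            tries = 0
            while not np.isfinite(sum(ll.values())):
                theta = theta0 + init_sd * rng.standard_normal(npar)
                params = self._params_from_theta(theta)
                ll = {"growth": self.loglik_growth(params),
                      "eggs": self.loglik_eggs(params),
                      "cjs": self.loglik_cjs(params)}
                tries += 1
                if tries > 100:
                    raise RuntimeError("could not find a finite starting point")
            lp = self.log_prior(theta)

            # per-block adaptation state
            scales = [np.log(2.38 / math.sqrt(len(b))) for b in blocks]
            mean_acc = [0.0] * 4
            hist = np.empty((config.iterations, npar))
            chol = [None] * 4
            kept = 0
            for it in range(config.iterations):
                for bi, b in enumerate(blocks):
                    prop = theta.copy()
                    z = rng.standard_normal(len(b))
                    if chol[bi] is not None:
                        step = chol[bi] @ z
                    else:
                        step = init_sd[b] * z
                    prop[b] = theta[b] + math.exp(scales[bi]) * step
                    pprop = self._params_from_theta(prop)
                    tg, te, tc = touches[bi]
                    new = dict(ll)
                    if tg:
                        new["growth"] = self.loglik_growth(pprop)
                    if te:
                        new["eggs"] = self.loglik_eggs(pprop)
                    if tc:
                        new["cjs"] = self.loglik_cjs(pprop)
                    lp_prop = self.log_prior(prop)
                    loga = (sum(new.values()) + lp_prop) - (sum(ll.values()) + lp)
                    acc = math.log(rng.random()) < loga if np.isfinite(loga) else False
                    if acc:
                        theta, ll, lp = prop, new, lp_prop
                        if it >= config.burn_in:
                            accept[ci, bi] += 1
                    # Robbins–Monro scale adaptation toward 0.28 acceptance
                    g_rm = 10.0 / max(it + 1, 100)
                    scales[bi] += g_rm * ((1.0 if acc else 0.0) - 0.28)
                    mean_acc[bi] += 1.0 if acc else 0.0
                hist[it] = theta
                # refresh block proposal covariance periodically during burn-in
                if (config.adapt_start <= it < config.burn_in
                        and it % 200 == 0 and it > config.adapt_start):
                    for bi, b in enumerate(blocks):
                        sub = hist[it // 2:it + 1, b]
                        cov = np.cov(sub.T) + 1e-8 * np.eye(len(b))
                        try:
                            chol[bi] = np.linalg.cholesky(cov)
                        except np.linalg.LinAlgError:
                            pass
                if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                    draws[ci, kept] = theta
                    kept += 1
                if progress and it % 1000 == 0:
                    print(f"chain {ci + 1}: iter {it}", flush=True)
        accept /= (config.iterations - config.burn_in)

        draws_nat = draws.copy()
        draws_nat[:, :, _ILOGS2] = np.exp(draws_nat[:, :, _ILOGS2])
        return CaptureRecapturePosterior(
            draws=draws_nat, config=config, accept_rates=accept, model=self)


@dataclass
class CaptureRecapturePosterior:
    """Posterior draws of the joint model with chain metadata and diagnostics."""

    draws: np.ndarray                  # (chains, n_kept, n_params), natural scale
    config: MCMCConfig
    accept_rates: np.ndarray
    model: CaptureRecaptureModel | None = None
    param_names: tuple[str, ...] = PARAM_NAMES
    _rhat: pd.Series | None = field(default=None, repr=False)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        c, k, p = self.draws.shape
        df = pd.DataFrame(self.draws.reshape(c * k, p), columns=list(self.param_names))
        df.insert(0, "chain", np.repeat(np.arange(c), k))
        df.insert(1, "draw", np.tile(np.arange(k), c))
        return df

    @property
    def rhat(self) -> pd.Series:
        if self._rhat is None:
            import arviz as az
            ds = az.convert_to_dataset(
                {n: self.draws[:, :, i] for i, n in enumerate(self.param_names)})
            r = az.rhat(ds)
            self._rhat = pd.Series({n: float(r[n].values) for n in self.param_names})
        return self._rhat

    @property
    def converged(self) -> bool:
        """Gelman–Rubin rule: every parameter's R-hat below 1.01."""
        return bool((self.rhat < 1.01).all())

    def summary(self) -> pd.DataFrame:
        """Posterior mean, SD, and central 95% interval per parameter."""
        flat = self.draws.reshape(-1, self.draws.shape[-1])
        out = pd.DataFrame({
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1),
            "2.5%": np.quantile(flat, 0.025, axis=0),
            "97.5%": np.quantile(flat, 0.975, axis=0),
            "rhat": self.rhat.to_numpy(),
        }, index=list(self.param_names))
        return out

    def params_at_mean(self) -> VitalRateParams:
        flat = self.draws.reshape(-1, self.draws.shape[-1])
        return VitalRateParams.from_vector(flat.mean(axis=0))

    def sample_params(self, n: int | None = None,
                      rng: np.random.Generator | None = None) -> list[VitalRateParams]:
        """Evenly thinned (or randomly subsampled) draws as parameter objects."""
        flat = self.draws.reshape(-1, self.draws.shape[-1])
        if n is None or n >= len(flat):
            sel = np.arange(len(flat))
        elif rng is None:
            sel = np.linspace(0, len(flat) - 1, n).astype(int)
        else:
            sel = rng.choice(len(flat), size=n, replace=False)
        return [VitalRateParams.from_vector(flat[i]) for i in sel]

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        i = self.param_names.index(name)
        flat = self.draws.reshape(-1, self.draws.shape[-1])[:, i]
        alpha = (1.0 - level) / 2.0
        return float(np.quantile(flat, alpha)), float(np.quantile(flat, 1.0 - alpha))
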