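"""Manual perturbation elasticity of the asymptotic growth rate.

The elasticity of lambda to a parameter is measured by rebuilding the kernel
after multiplying the season-resolved parameter by (1 ± 1%) and reporting

    E_lambda = 100 * (lambda_perturbed - lambda_0) / lambda_0   [percent]

for the growth rate ``K``, the asymptotic size ``L``, and the size slope of
the mortality hazard ``f``. Perturbations act on the *effective* (site- and
season-resolved) coefficient, so a 1% change in the season-2 survival slope
scales ``f + season2_f`` as a whole. For the (negative) hazard slope a
"decrease" shrinks the magnitude of the size effect (f -> 0.99 f), weakening
the survival advantage of large individuals; the opposite sign convention is
available via ``perturb_magnitude=False``. Analogous proportional changes of
the stable size distribution's mean and variance are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ipm import (
    FixedDemography,
    IPMKernel,
    MeshConfig,
    build_kernel,
    lambda_and_stable,
    stable_summaries,
)
from .params import KernelCoeffs, VitalRateParams

__all__ = [
    "PERTURBABLE",
    "ElasticityResult",
    "perturb_and_rebuild",
    "elasticity",
    "season_average_elasticity",
    "posterior_elasticity",
]

PERTURBABLE = ("K", "L", "f")


def _resolve(params, site: str, season: int) -> KernelCoeffs:
    if isinstance(params, VitalRateParams):
        return params.resolve(site, season)
    return params


def perturbed_coeffs(co: KernelCoeffs, which: str, direction: float,
                     perturb_magnitude: bool = True) -> KernelCoeffs:
    """Scale one resolved coefficient by ``1 + direction`` (e.g. -0.01)."""
    if which not in PERTURBABLE:
        raise ValueError(f"unknown perturbation target {which!r}; "
                         f"expected one of {PERTURBABLE}")
    factor = 1.0 + direction
    if which == "f" and not perturb_magnitude:
        # alternative convention: move the slope itself down/up additively in
        # the direction of the perturbation sign
        factor = 1.0 - direction
    return co.replace(**{which: getattr(co, which) * factor})


def perturb_and_rebuild(params, which: str, direction: float,
                        fixed: FixedDemography | None = None,
                        mesh: MeshConfig | None = None,
                        season: int = 1, site: str = "site1",
                        perturb_magnitude: bool = True,
                        **kernel_kwargs) -> IPMKernel:
    """Kernel with a single resolved parameter multiplied by ``1 + direction``."""
    co = _resolve(params, site, season)
    co_p = perturbed_coeffs(co, which, direction, perturb_magnitude)
    return build_kernel(co_p, fixed, mesh, season=season, site=site,
                        **kernel_kwargs)


@dataclass
class ElasticityResult:
    """Per-draw elasticities for one parameter/direction/season."""

    parameter: str
    direction: float
    season: int
    table: pd.DataFrame   # draw, E_lambda, d_mean_pct, d_var_pct
    n_failed: int = 0

    def summary(self) -> dict[str, float]:
        e = self.table["E_lambda"].to_numpy()
        return {
            "E_lambda_mean": float(e.mean()),
            "E_lambda_2.5%": float(np.quantile(e, 0.025)),
            "E_lambda_97.5%": float(np.quantile(e, 0.975)),
            "n_draws": int(len(e)),
            "n_failed": self.n_failed,
        }


def elasticity(params, which: str, direction: float = -0.01,
               fixed: FixedDemography | None = None,
               mesh: MeshConfig | None = None,
               season: int = 1, site: str = "site1",
               perturb_magnitude: bool = True,
               **kernel_kwargs) -> dict[str, float]:
    """Percent change in lambda (and stable mean/variance) for one kernel.

    Returns ``E_lambda`` (Eq-style 100 (lambda_p - lambda_0)/lambda_0) plus
    the analogous proportional changes of the stable distribution's mean and
    variance of size, in percent.
    """
    fixed = fixed or FixedDemography()
    mesh = mesh or MeshConfig()
    k0 = build_kernel(_resolve(params, site, season), fixed, mesh,
                      season=season, site=site, **kernel_kwargs)
    lam0, v0 = lambda_and_stable(k0)
    if lam0 <= 0:
        raise ValueError("unperturbed lambda must be positive")
    kp = perturb_and_rebuild(params, which, direction, fixed, mesh,
                             season=season, site=site,
                             perturb_magnitude=perturb_magnitude,
                             **kernel_kwargs)
    lamp, vp = lambda_and_stable(kp)
    s0 = stable_summaries(v0, mesh, fixed.maturity_threshold)
    sp = stable_summaries(vp, mesh, fixed.maturity_threshold)
    return {
        "E_lambda": 100.0 * (lamp - lam0) / lam0,
        "d_mean_pct": 100.0 * (sp["mean_size"] - s0["mean_size"]) / s0["mean_size"],
        "d_var_pct": 100.0 * (sp["var_size"] - s0["var_size"]) / s0["var_size"],
        "lambda_0": lam0,
        "lambda_p": lamp,
    }


def season_average_elasticity(params, which: str, direction: float = -0.01,
                              fixed: FixedDemography | None = None,
                              mesh: MeshConfig | None = None,
                              site: str = "site1",
                              **kwargs) -> dict[str, float]:
    """Arithmetic mean of the two seasonal elasticities (with per-season values)."""
    out = {}
    es = []
    for season in (1, 2):
        r = elasticity(params, which, direction, fixed, mesh,
                       season=season, site=site, **kwargs)
        out[f"season{season}"] = r["E_lambda"]
        es.append(r["E_lambda"])
    out["average"] = float(np.mean(es))
    return out


def posterior_elasticity(draws, which: str, direction: float = -0.01,
                         fixed: FixedDemography | None = None,
                         mesh: MeshConfig | None = None,
                         season: int = 1, site: str = "site1",
                         max_draws: int | None = None,
                         **kwargs) -> ElasticityResult:
    """Per-draw elasticities over a posterior sample (violin-style output)."""
    from .ipm import _as_params_list
    params_list = _as_params_list(draws, max_draws)
    rows, n_failed = [], 0
    for i, p in enumerate(params_list):
        try:
            r = elasticity(p, which, direction, fixed, mesh,
                           season=season, site=site, **kwargs)
        except (ValueError, RuntimeError):
            n_failed += 1
            continue
        rows.append({"draw": i, "E_lambda": r["E_lambda"],
                     "d_mean_pct": r["d_mean_pct"], "d_var_pct": r["d_var_pct"]})
    return ElasticityResult(parameter=which, direction=direction, season=season,
                            table=pd.DataFrame(rows), n_failed=n_failed)
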