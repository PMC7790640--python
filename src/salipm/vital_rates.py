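"""Size-dependent vital-rate functions.

Pure, vectorized functions mapping snout-to-vent length (mm) to demographic
rates. They are shared verbatim by the individual-based simulator, the joint
likelihood of the capture–recapture model, and the projection-kernel builder,
so the generative model, the estimation model, and the population model are
one and the same set of equations:

* growth — von Bertalanffy in increment (Fabens) form,
  ``x' = exp(-K) x + L (1 - exp(-K))``, with residual variance linear in size;
* survival — log-log link, monthly survival ``exp(-exp(e + f x))``, raised to
  the interval length in months (on a half-month grid);
* recapture — logistic in size;
* fecundity — expected egg count linear in size, gated by a maturity
  threshold.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "EPS_VAR",
    "growth_mean",
    "growth_variance",
    "monthly_survival",
    "interval_survival",
    "recapture_prob",
    "expected_eggs",
    "reproduction_indicator",
]

#: Floor on the growth residual variance (mm^2). The fitted linear variance
#: model turns negative above ~56 mm; the floor keeps the growth density
#: proper without materially affecting mass below the asymptote.
EPS_VAR = 0.1

_HALF_MONTH_TOL = 1e-9


def _check_size(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("size must be finite")
    if np.any(x < 0):
        raise ValueError("size must be non-negative (snout-to-vent length, mm)")
    return x


def growth_mean(x, K: float, L: float):
    """Expected size next year from size ``x`` now (Fabens increment form).

    The map contracts toward the asymptote: ``|x' - L| = exp(-K) |x - L|``.
    """
    x = _check_size(x)
    if not np.isfinite(K) or K <= 0:
        raise ValueError("growth rate K must be finite and > 0")
    if not np.isfinite(L) or L <= 0:
        raise ValueError("asymptotic size L must be finite and > 0")
    r = np.exp(-K)
    return r * x + L * (1.0 - r)


def growth_variance(x, a: float, b: float, eps_var: float = EPS_VAR):
    """Residual variance of next year's size, ``max(a + b x, eps_var)``."""
    x = _check_size(x)
    return np.maximum(a + b * x, eps_var)


def monthly_survival(x, e: float, f: float):
    """Monthly apparent survival ``exp(-exp(e + f x))`` (log-log hazard link)."""
    x = _check_size(x)
    return np.exp(-np.exp(e + f * x))


def interval_survival(x, e: float, f: float, dt):
    """Survival over ``dt`` months, ``monthly_survival ** dt``.

    ``dt`` must be positive and lie on the half-month grid at which occasion
    timings are recorded.
    """
    dt = np.asarray(dt, dtype=float)
    if np.any(dt <= 0):
        raise ValueError("interval length dt must be > 0")
    if np.any(np.abs(dt / 0.5 - np.round(dt / 0.5)) > _HALF_MONTH_TOL):
        raise ValueError("interval length dt must be a multiple of 0.5 months")
    return monthly_survival(x, e, f) ** dt


def recapture_prob(x, g: float, h: float):
    """Per-occasion recapture probability, inverse-logit of ``g + h x``."""
    x = _check_size(x)
    eta = g + h * x
    # numerically stable inverse logit
    out = np.where(eta >= 0, 1.0 / (1.0 + np.exp(-eta)),
                   np.exp(eta) / (1.0 + np.exp(eta)))
    return out if out.ndim else float(out)


def expected_eggs(x, c: float, d: float, clamp: bool = True):
    """Expected egg count of a female of size ``x``, ``c + d x``.

    With ``clamp=True`` (kernel use) the prediction is floored at zero; the
    linear model can go negative at sizes far below maturity.
    """
    x = _check_size(x)
    out = c + d * x
    return np.maximum(out, 0.0) if clamp else out


def reproduction_indicator(x, maturity_threshold: float = 36.0):
    """1 if ``x`` is at or above the maturity threshold, else 0.

    Maturity is inclusive at the threshold (an individual measuring exactly
    the threshold is treated as mature).
    """
    x = _check_size(x)
    return (x >= maturity_threshold).astype(float)
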