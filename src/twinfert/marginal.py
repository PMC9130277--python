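"""Population-averaged (marginal) predictions from fitted GLMMs.

A conditional prediction plugs a specific random-effect value (often zero)
into the inverse link; with a non-identity link this is biased for the
population mean because averaging and back-transforming do not commute.  The
marginal prediction integrates the response-scale prediction over the fitted
random-effect distribution,

    E[h(x'beta + u)],   u ~ N(0, sigma2_total),

where ``h`` maps the linear predictor to the expected response (inverse link,
including the zero-truncation correction for truncated families) and
``sigma2_total`` sums the independent intercept variances (a sum of
independent Gaussians is Gaussian, so the nested 1-D quadratures collapse to
one).  Integration uses Gauss–Hermite quadrature by default, or Monte Carlo.

Confidence intervals come from a parametric bootstrap: simulate a response
from the fit (drawing fresh random effects), refit, recompute the statistic,
and take percentile intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .glmm import FittedModel, ModelSuite, fit_glmm, simulate_response, \
    _with_response

__all__ = [
    "marginal_predict",
    "predict_fig1_fig2_quantities",
    "bootstrap_ci",
]


def marginal_predict(fit: FittedModel, newdata: pd.DataFrame,
                     mode="marginal", integration="quadrature",
                     n_nodes=41, n_mc=100_000, rng=None,
                     conditional_re=0.0):
    """Expected response per row of ``newdata``.

    ``mode="marginal"`` integrates over u ~ N(0, sum of fitted variances);
    ``mode="conditional"`` evaluates at ``conditional_re`` (scalar or array).
    """
    eta = fit.linpred(newdata, random=())
    fam = fit.family()
    if mode == "conditional":
        return fam.mean(eta + np.asarray(conditional_re), fit.shape)
    if mode != "marginal":
        raise ValueError(f"unknown mode {mode!r}")

    s2 = float(sum(fit.sigma2.values()))
    if s2 <= 0:
        return fam.mean(eta, fit.shape)
    sd = np.sqrt(s2)
    if integration == "quadrature":
        if n_nodes < 3:
            raise ValueError("need at least 3 quadrature nodes")
        x, w = np.polynomial.hermite.hermgauss(n_nodes)
        w = w / np.sqrt(np.pi)
        u = np.sqrt(2.0) * sd * x
        vals = fam.mean(eta[:, None] + u[None, :], fit.shape)
        return vals @ w
    if integration == "monte_carlo":
        rng = rng or np.random.default_rng(0)
        u = rng.normal(0.0, sd, size=n_mc)
        return fam.mean(eta[:, None] + u[None, :], fit.shape).mean(axis=1)
    raise ValueError(f"unknown integration {integration!r}")


def predict_fig1_fig2_quantities(suite: ModelSuite,
                                 births_total_grid=None) -> dict:
    """Headline marginal estimates from the mother-level models.

    * model 1 — marginal mean total births for twinners and non-twinners and
      the twinners' excess;
    * model 2 — marginal probability of being a twinner across total births;
    * model 3 — marginal per-birth twinning probability across total births
      (the exposure-corrected relationship).
    """
    grid = np.asarray(births_total_grid if births_total_grid is not None
                      else np.arange(1, 19))
    out = {}
    if 1 in suite:
        nd = pd.DataFrame({"twinner": [0.0, 1.0]})
        mb = marginal_predict(suite[1], nd)
        out["mean_births_nontwinners"] = float(mb[0])
        out["mean_births_twinners"] = float(mb[1])
        out["extra_births_twinners"] = float(mb[1] - mb[0])
    if 2 in suite:
        nd = pd.DataFrame({"births_total": grid.astype(float)})
        out["p_twinner_by_births"] = pd.Series(
            marginal_predict(suite[2], nd), index=grid)
        out["model2_slope"] = float(suite[2].beta["births_total"])
        out["model2_odds_factor"] = float(np.exp(out["model2_slope"]))
    if 3 in suite:
        nd = pd.DataFrame({"births_total": grid.astype(float)})
        p = marginal_predict(suite[3], nd)
        out["p_twin_by_births"] = pd.Series(p, index=grid)
        out["p_twin_at_min_births"] = float(p[0])
        out["p_twin_at_max_births"] = float(p[-1])
        out["model3_slope"] = float(suite[3].beta["births_total"])
    return out


def bootstrap_ci(fit: FittedModel, statistic, df: pd.DataFrame,
                 n_boot=1000, seed=0, level=0.95, **fit_kwargs):
    """Percentile parametric-bootstrap interval for ``statistic(fit)``.

    Each replicate simulates a response from ``fit`` (new random effects
    drawn from the fitted variances), refits the same specification, and
    evaluates ``statistic`` on the refit.  Refit failures are dropped; more
    than 10% failures raises.  Returns ``(lower, upper, draws)``.
    """
    draws, failures = [], 0
    for b in range(n_boot):
        rng = np.random.default_rng([seed, b])
        y, _ = simulate_response(fit, df, rng)
        sim = _with_response(df, fit.spec, y)
        try:
            refit = fit_glmm(fit.spec, sim, **fit_kwargs)
            draws.append(statistic(refit))
        except Exception:
            failures += 1
    if failures > 0.1 * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap refits failed")
    draws = np.asarray(draws, dtype=float)
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(draws, alpha)),
            float(np.quantile(draws, 1.0 - alpha)), draws)
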