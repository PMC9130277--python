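"""Generalised linear mixed models with crossed Gaussian random intercepts.

Fits the twelve life-history models of the analysis: binomial (logit),
negative-binomial (log) and zero-truncated negative-binomial (log) responses,
with random intercepts for maternal identity and/or population.  The marginal
likelihood is approximated by a Laplace approximation at the joint mode of
(beta, u) — feasible for thousands of maternal levels because every random
intercept factor contributes a diagonal block to the Hessian — or, for
single-factor instances, by adaptive Gauss–Hermite quadrature
(``method="agq"``), which is accurate enough to serve as a near-exact
reference on small problems.

The twelve models
-----------------
Mother-level data:

1. ``births_total ~ 1 + twinner + (1|pop)``, zero-truncated negbin, log link
2. ``twinner ~ 1 + births_total + (1|pop)``, binomial, logit link
3. ``cbind(twin_total, singleton_total) ~ 1 + births_total + (1|pop)``,
   binomial, logit link — the exposure-corrected per-birth twinning model
7. ``AFB ~ 1 + twinner * births_total_fac + (1|pop)``, negbin, log link

Birth-level data (poly = bivariate polynomial in maternal age and parity,
order selected by marginal AIC):

4.  ``PP  ~ 1 + twin + poly + (1|mat) + (1|pop)``, binomial
5.  ``IBI ~ 1 + twin + poly + (1|mat) + (1|pop)``, negbin (rows with a next
    birth only)
6.  ``T   ~ 1 + poly + (1|mat) + (1|pop)``, binomial
8.  model 4 without ``twin`` (mechanism P off)
9.  model 5 without ``twin`` (mechanism I off)
10. model 6 without ``poly`` (mechanism S off)
11. model 6 without ``poly`` and without ``(1|mat)`` (S and H off)
12. model 6 without ``(1|mat)`` (mechanism H off)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.special import expit, gammaln, logsumexp

__all__ = [
    "ModelSpec",
    "FittedModel",
    "ModelSuite",
    "TruncatedNegBinom",
    "build_poly_basis",
    "fit_glmm",
    "select_poly_order",
    "fit_model_suite",
    "lrt_parametric_bootstrap",
    "MODEL_SPECS",
]

_SIGMA2_FLOOR = 1e-8
_MAX_POLY_ORDER = 6


# ---------------------------------------------------------------------------
# response families
# ---------------------------------------------------------------------------

class _Binomial:
    """Binomial with logit link; ``trials`` may exceed 1 (successes/trials)."""

    name = "binomial"
    link = "logit"
    has_shape = False

    def loglik(self, y, eta, trials, shape=None):
        n = trials
        const = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
        return const + y * eta - n * np.logaddexp(0.0, eta)

    def score(self, y, eta, trials, shape=None):
        return y - trials * expit(eta)

    def weight(self, y, eta, trials, shape=None):
        p = expit(eta)
        return np.clip(trials * p * (1.0 - p), 1e-10, None)

    def mean(self, eta, shape=None):
        return expit(eta)

    def sample(self, rng, eta, trials, shape=None):
        return rng.binomial(np.asarray(trials, dtype=int), expit(eta))


def _nb_logpmf(y, mu, shape):
    t = shape
    return (
        gammaln(y + t) - gammaln(t) - gammaln(y + 1)
        + t * (np.log(t) - np.log(t + mu))
        + y * (np.log(mu) - np.log(t + mu))
    )


def _nb_logp0(mu, shape):
    return shape * (np.log(shape) - np.log(shape + mu))


class _NegBin:
    """NB2 (variance mu + mu^2/shape), log link."""

    name = "negbin"
    link = "log"
    has_shape = True

    def loglik(self, y, eta, trials, shape):
        return _nb_logpmf(y, np.exp(eta), shape)

    def score(self, y, eta, trials, shape):
        mu = np.exp(eta)
        return shape * (y - mu) / (mu + shape)

    def weight(self, y, eta, trials, shape):
        mu = np.exp(eta)
        return np.clip(shape * mu / (mu + shape), 1e-10, None)

    def mean(self, eta, shape=None):
        return np.exp(eta)

    def sample(self, rng, eta, trials, shape):
        mu = np.exp(eta)
        p = shape / (shape + mu)
        return rng.negative_binomial(shape, p)


class _TruncNegBin:
    """Zero-truncated NB2, log link: support k >= 1."""

    name = "truncnegbin"
    link = "log"
    has_shape = True

    def loglik(self, y, eta, trials, shape):
        mu = np.exp(eta)
        logp0 = _nb_logp0(mu, shape)
        return _nb_logpmf(y, mu, shape) - np.log1p(-np.exp(logp0))

    def score(self, y, eta, trials, shape):
        mu = np.exp(eta)
        t = shape
        p0 = np.exp(_nb_logp0(mu, t))
        # d/deta of -log(1 - p0) = -p0 * t * mu / ((1 - p0) * (t + mu))
        return t * (y - mu) / (mu + t) - p0 * t * mu / ((1.0 - p0) * (t + mu))

    def weight(self, y, eta, trials, shape):
        # Fisher weight of the untruncated NB; kept positive so Newton with
        # step-halving on the exact objective still converges.
        mu = np.exp(eta)
        return np.clip(shape * mu / (mu + shape), 1e-10, None)

    def mean(self, eta, shape=None):
        mu = np.exp(eta)
        p0 = np.exp(_nb_logp0(mu, shape))
        return mu / (1.0 - p0)

    def sample(self, rng, eta, trials, shape):
        return TruncatedNegBinom(np.exp(eta), shape).rvs(rng)


_FAMILIES = {"binomial": _Binomial(), "negbin": _NegBin(), "truncnegbin": _TruncNegBin()}


class TruncatedNegBinom:
    """Zero-truncated NB2 distribution: pmf(k) = NB(k)/(1-NB(0)) for k >= 1.

    Parameters
    ----------
    mu : float or array
        Mean of the *untruncated* NB2 distribution (> 0).
    shape : float
        NB2 dispersion parameter (> 0); variance of the untruncated
        distribution is ``mu + mu**2/shape``.
    """

    def __init__(self, mu, shape):
        mu = np.asarray(mu, dtype=float)
        if np.any(mu <= 0) or shape <= 0:
            raise ValueError("mu and shape must be positive")
        self.mu = mu
        self.shape = float(shape)

    def logpmf(self, k):
        k = np.asarray(k)
        out = np.where(
            k >= 1,
            _nb_logpmf(np.maximum(k, 1), self.mu, self.shape)
            - np.log1p(-np.exp(_nb_logp0(self.mu, self.shape))),
            -np.inf,
        )
        return out

    def pmf(self, k):
        return np.exp(self.logpmf(k))

    def mean(self):
        p0 = np.exp(_nb_logp0(self.mu, self.shape))
        return self.mu / (1.0 - p0)

    def rvs(self, rng, size=None):
        """Rejection sampler: redraw untruncated NB2 draws equal to zero."""
        mu = np.broadcast_to(self.mu, size if size is not None else np.shape(self.mu))
        p = self.shape / (self.shape + mu)
        out = rng.negative_binomial(self.shape, p)
        out = np.atleast_1d(np.asarray(out))
        pflat = np.broadcast_to(p, out.shape)
        zero = out == 0
        while zero.any():
            out[zero] = rng.negative_binomial(self.shape, pflat[zero])
            zero = out == 0
        if size is None and np.ndim(self.mu) == 0:
            return int(out[0])
        return out


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_poly_basis(age, parity, order, transform=None, orthogonalize=False):
    """Bivariate polynomial basis in maternal age and parity.

    Returns all monomials ``age**i * parity**j`` with ``1 <= i+j <= order``
    (order 0 gives an empty basis).  Variables are centred and scaled using
    statistics stored in ``transform`` (computed from the data when None), so
    that the basis is well conditioned and predictions on new data reuse the
    training transform.  With ``orthogonalize=True`` the columns are further
    mapped through a QR-derived linear map; fitted values are invariant to
    this choice.

    Returns ``(matrix, names, transform)``.
    """
    if not (0 <= order <= _MAX_POLY_ORDER):
        raise ValueError(f"poly order must be in 0..{_MAX_POLY_ORDER}, got {order}")
    age = np.asarray(age, dtype=float)
    parity = np.asarray(parity, dtype=float)
    if age.shape != parity.shape:
        raise ValueError("age and parity must have equal length")
    if order == 0:
        return np.empty((age.size, 0)), [], transform or {}

    if transform is None:
        transform = {
            "age_center": float(age.mean()),
            "age_scale": float(age.std() or 1.0),
            "parity_center": float(parity.mean()),
            "parity_scale": float(parity.std() or 1.0),
        }
    a = (age - transform["age_center"]) / transform["age_scale"]
    p = (parity - transform["parity_center"]) / transform["parity_scale"]

    cols, names = [], []
    for total in range(1, order + 1):
        for i in range(total, -1, -1):
            j = total - i
            cols.append(a**i * p**j)
            names.append(f"age^{i}.parity^{j}")
    M = np.column_stack(cols)

    if orthogonalize or "ortho_map" in transform:
        if "ortho_map" not in transform:
            Q, R = np.linalg.qr(M - M.mean(axis=0))
            transform = dict(transform)
            transform["ortho_map"] = np.linalg.inv(R / np.sqrt(len(M)))
            transform["ortho_center"] = M.mean(axis=0)
        M = (M - transform["ortho_center"]) @ transform["ortho_map"]
        names = [f"poly{k+1}" for k in range(M.shape[1])]
    return M, names, transform


_FAC_LEVELS = [str(i) for i in range(1, 10)] + ["10+"]


def _births_total_fac(births_total):
    bt = np.minimum(np.asarray(births_total, dtype=int), 10)
    return np.array([str(b) if b < 10 else "10+" for b in bt])


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one mixed model: response, family and terms.

    ``terms`` may contain ``"twinner"``, ``"births_total"``, ``"twin"``,
    ``"poly"`` (with ``poly_order``) and ``"twinner*births_total_fac"``.
    ``successes``/``failures`` give a two-column binomial response (model 3).
    """

    name: str
    response: str
    family: str
    terms: tuple = ()
    poly_order: int | None = None
    random_effects: tuple = ("population_id",)
    successes: str | None = None
    failures: str | None = None

    def drop(self, *, term=None, random_effect=None, new_name=None):
        terms = tuple(t for t in self.terms if t != term) if term else self.terms
        res = tuple(r for r in self.random_effects if r != random_effect)
        poly = self.poly_order if "poly" in terms else None
        return replace(
            self,
            name=new_name or self.name,
            terms=terms,
            poly_order=poly,
            random_effects=res if random_effect else self.random_effects,
        )


def _build_design(spec: ModelSpec, df: pd.DataFrame, design_info=None,
                  orthogonalize=False):
    """Return (y, trials, X, colnames, design_info)."""
    n = len(df)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    info = dict(design_info or {})

    for term in spec.terms:
        if term in ("twinner", "births_total", "twin"):
            cols.append(np.asarray(df[term], dtype=float))
            names.append(term)
        elif term == "poly":
            M, pn, tr = build_poly_basis(
                df["age_months"], df["parity"], spec.poly_order,
                transform=info.get("poly_transform"), orthogonalize=orthogonalize)
            info["poly_transform"] = tr
            cols.extend(M.T)
            names.extend(pn)
        elif term == "twinner*births_total_fac":
            fac = _births_total_fac(df["births_total"])
            tw = np.asarray(df["twinner"], dtype=float)
            cols.append(tw)
            names.append("twinner")
            for lev in _FAC_LEVELS[1:]:
                d = (fac == lev).astype(float)
                cols.append(d)
                names.append(f"births_total_fac[{lev}]")
                cols.append(tw * d)
                names.append(f"twinner:births_total_fac[{lev}]")
        else:
            raise ValueError(f"unknown term {term!r}")

    X = np.column_stack(cols)
    # response columns may be absent in prediction-only newdata
    if spec.successes is not None and spec.successes in df.columns:
        y = np.asarray(df[spec.successes], dtype=float)
        trials = y + np.asarray(df[spec.failures], dtype=float)
    elif spec.successes is None and spec.response in df.columns:
        y = np.asarray(df[spec.response], dtype=float)
        trials = np.ones(n)
    else:
        y, trials = np.zeros(n), np.ones(n)
    return y, trials, X, names, info


# ---------------------------------------------------------------------------
# fitted-model container
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """Result of a GLMM fit.

    Attributes
    ----------
    beta : pandas.Series
        Fixed-effect coefficients, indexed by term name.
    sigma2 : dict
        Random-intercept variance per grouping factor.
    shape : float or None
        NB2 dispersion (negbin / truncated-negbin families).
    loglik : float
        Approximate marginal log-likelihood.
    aic : float
        Marginal AIC ``-2*loglik + 2*(len(beta) + len(sigma2) + has_shape)``.
    re_modes : dict of pandas.Series
        Conditional modes of the random effects, indexed by level label.
    se_beta : pandas.Series
        Wald standard errors (conditional on the variance estimates).
    """

    spec: ModelSpec
    beta: pd.Series
    sigma2: dict
    shape: float | None
    loglik: float
    aic: float
    re_modes: dict
    se_beta: pd.Series
    design_info: dict
    converged: bool
    n_obs: int
    method: str = "laplace"

    @property
    def n_params(self):
        return len(self.beta) + len(self.sigma2) + (1 if self.shape is not None else 0)

    def family(self):
        return _FAMILIES[self.spec.family]

    def linpred(self, df, random=("population_id", "maternal_id")):
        """Linear predictor for new rows; adds conditional modes for any
        grouping factor listed in ``random`` (unknown levels get 0)."""
        _, _, X, names, _ = _build_design(self.spec, df, self.design_info)
        eta = X @ self.beta.reindex(names).to_numpy()
        for fac in self.spec.random_effects:
            if fac in random and fac in df.columns:
                modes = self.re_modes.get(fac)
                if modes is not None:
                    eta = eta + modes.reindex(df[fac]).fillna(0.0).to_numpy()
        return eta

    def shifted(self, delta):
        """Copy of the fit with ``delta`` added to the intercept."""
        beta = self.beta.copy()
        beta["(Intercept)"] += delta
        return replace(self, beta=beta)


class ModelSuite(dict):
    """Mapping model number (1..12) -> FittedModel, plus selected poly orders."""

    def __init__(self, fits=None, poly_orders=None):
        super().__init__(fits or {})
        self.poly_orders = dict(poly_orders or {})

    def to_json_dict(self):
        out = {}
        for k, f in self.items():
            out[str(k)] = {
                "beta": f.beta.to_dict(),
                "se_beta": f.se_beta.to_dict(),
                "sigma2": f.sigma2,
                "shape": f.shape,
                "loglik": f.loglik,
                "aic": f.aic,
                "converged": f.converged,
                "n_obs": f.n_obs,
            }
        out["poly_orders"] = self.poly_orders
        return out


# ---------------------------------------------------------------------------
# Laplace machinery
# ---------------------------------------------------------------------------

class _LaplaceState:
    """Inner problem: joint mode of (beta, u) for fixed variance parameters.

    Random intercepts make every within-factor Hessian block diagonal.  The
    factor with the most levels ("big", typically maternal identity) is
    eliminated analytically; the fixed effects together with any remaining
    factor ("small", typically population) form a dense block solved directly.
    """

    def __init__(self, y, trials, X, family, factors):
        # factors: list of (name, codes, nlev) sorted big first
        self.y, self.trials, self.X, self.family = y, trials, X, family
        self.factors = factors
        self.p = X.shape[1]
        if factors:
            self.big_name, self.big_idx, self.qb = factors[0]
        else:
            self.big_name, self.big_idx, self.qb = None, None, 0
        if len(factors) > 1:
            self.small_name, small_idx, qs = factors[1]
            self.qs = qs
            S = np.zeros((len(y), qs))
            S[np.arange(len(y)), small_idx] = 1.0
            self.Xd = np.hstack([X, S])
            self.small_idx = small_idx
        else:
            self.small_name, self.qs, self.small_idx = None, 0, None
            self.Xd = X
        self.d = self.Xd.shape[1]
        self.v = np.zeros(self.d)   # (beta, u_small)
        self.ub = np.zeros(self.qb)

    def reset(self):
        self.v[:] = 0.0
        self.ub[:] = 0.0
        # sensible intercept start
        fam = self.family
        ybar = np.clip(self.y.mean() / max(self.trials.mean(), 1e-12), 1e-4, None)
        if fam.link == "logit":
            self.v[0] = special.logit(np.clip(ybar, 1e-4, 1 - 1e-4))
        else:
            self.v[0] = np.log(ybar)

    def eta(self):
        eta = self.Xd @ self.v
        if self.qb:
            eta = eta + self.ub[self.big_idx]
        return eta

    def _pen(self, s2b, pen_d):
        pen = 0.0
        if self.qb:
            pen += 0.5 * np.sum(self.ub**2) / s2b
        pen += 0.5 * np.sum(pen_d * self.v**2)
        return pen

    def solve_mode(self, sigma2, shape, max_iter=100, tol=1e-10):
        """Penalised Fisher scoring with step halving; returns penalised ll."""
        fam, y, tr = self.family, self.y, self.trials
        s2b = sigma2.get(self.big_name, np.inf) if self.qb else np.inf
        pen_d = np.zeros(self.d)
        if self.qs:
            pen_d[self.p:] = 1.0 / sigma2[self.small_name]

        eta = self.eta()
        pll = np.sum(fam.loglik(y, eta, tr, shape)) - self._pen(s2b, pen_d)
        if not np.isfinite(pll):
            self.reset()
            eta = self.eta()
            pll = np.sum(fam.loglik(y, eta, tr, shape)) - self._pen(s2b, pen_d)
        for _ in range(max_iter):
            s = fam.score(y, eta, tr, shape)
            W = fam.weight(y, eta, tr, shape)
            g_d = self.Xd.T @ s - pen_d * self.v
            C = (self.Xd.T * W) @ self.Xd + np.diag(pen_d)
            if self.qb:
                A = np.bincount(self.big_idx, weights=W, minlength=self.qb) + 1.0 / s2b
                g_b = np.bincount(self.big_idx, weights=s, minlength=self.qb) \
                    - self.ub / s2b
                B = np.empty((self.d, self.qb))
                for j in range(self.d):
                    B[j] = np.bincount(self.big_idx, weights=W * self.Xd[:, j],
                                       minlength=self.qb)
                S = C - (B / A) @ B.T
                rhs = g_d - B @ (g_b / A)
                try:
                    dv = np.linalg.solve(S, rhs)
                except np.linalg.LinAlgError:
                    dv = np.linalg.lstsq(S, rhs, rcond=None)[0]
                dub = (g_b - B.T @ dv) / A
            else:
                try:
                    dv = np.linalg.solve(C, g_d)
                except np.linalg.LinAlgError:
                    dv = np.linalg.lstsq(C, g_d, rcond=None)[0]
                dub = None

            step = 1.0
            v0, ub0 = self.v.copy(), self.ub.copy()
            for _half in range(30):
                self.v = v0 + step * dv
                if dub is not None:
                    self.ub = ub0 + step * dub
                eta = self.eta()
                new = np.sum(fam.loglik(y, eta, tr, shape)) - self._pen(s2b, pen_d)
                if np.isfinite(new) and new >= pll - 1e-12:
                    break
                step *= 0.5
            if not np.isfinite(new):
                self.v, self.ub = v0, ub0
                eta = self.eta()
                return pll, False
            gain = new - pll
            pll = new
            if gain < tol * (abs(pll) + 1.0):
                return pll, True
        return pll, False

    def logdet_uu(self, sigma2, shape):
        """log det of the Hessian of the negative joint log-density wrt u."""
        if not self.qb and not self.qs:
            return 0.0
        fam = self.family
        W = fam.weight(self.y, self.eta(), self.trials, shape)
        parts = 0.0
        if self.qb:
            s2b = sigma2[self.big_name]
            A = np.bincount(self.big_idx, weights=W, minlength=self.qb) + 1.0 / s2b
            parts += np.sum(np.log(A))
            if self.qs:
                Cs = np.bincount(self.small_idx, weights=W, minlength=self.qs) \
                    + 1.0 / sigma2[self.small_name]
                Bsb = np.zeros((self.qs, self.qb))
                np.add.at(Bsb, (self.small_idx, self.big_idx), W)
                Ss = np.diag(Cs) - (Bsb / A) @ Bsb.T
                sign, ld = np.linalg.slogdet(Ss)
                parts += ld
        elif self.qs:
            Cs = np.bincount(self.small_idx, weights=W, minlength=self.qs) \
                + 1.0 / sigma2[self.small_name]
            parts += np.sum(np.log(Cs))
        return parts

    def laplace_loglik(self, sigma2, shape):
        pll, ok = self.solve_mode(sigma2, shape)
        if not np.isfinite(pll):
            return -np.inf, False
        ll = pll
        for name, _, q in self.factors:
            ll -= 0.5 * q * np.log(sigma2[name])
        ll -= 0.5 * self.logdet_uu(sigma2, shape)
        return ll, ok

    def cov_dense(self, sigma2, shape):
        fam = self.family
        W = fam.weight(self.y, self.eta(), self.trials, shape)
        pen_d = np.zeros(self.d)
        if self.qs:
            pen_d[self.p:] = 1.0 / sigma2[self.small_name]
        C = (self.Xd.T * W) @ self.Xd + np.diag(pen_d)
        if self.qb:
            A = np.bincount(self.big_idx, weights=W, minlength=self.qb) \
                + 1.0 / sigma2[self.big_name]
            B = np.empty((self.d, self.qb))
            for j in range(self.d):
                B[j] = np.bincount(self.big_idx, weights=W * self.Xd[:, j],
                                   minlength=self.qb)
            C = C - (B / A) @ B.T
        return np.linalg.pinv(C)


# ---------------------------------------------------------------------------
# adaptive Gauss–Hermite (single grouping factor)
# ---------------------------------------------------------------------------

def _agq_loglik(y, trials, X, codes, q, family, beta, sigma2, shape, n_nodes=25):
    """Adaptive GH marginal log-likelihood, one random-intercept factor."""
    nodes, wts = np.polynomial.hermite.hermgauss(n_nodes)
    eta0 = X @ beta
    total = 0.0
    for g in range(q):
        m = codes == g
        yg, tg, eg = y[m], trials[m], eta0[m]

        def negjoint(u):
            return -(np.sum(family.loglik(yg, eg + u, tg, shape))
                     - 0.5 * u * u / sigma2 - 0.5 * np.log(2 * np.pi * sigma2))

        u = 0.0
        for _ in range(50):
            s = np.sum(family.score(yg, eg + u, tg, shape)) - u / sigma2
            h = np.sum(family.weight(yg, eg + u, tg, shape)) + 1.0 / sigma2
            du = s / h
            # step-halve on the joint density
            step, f0 = 1.0, negjoint(u)
            while negjoint(u + step * du) > f0 and step > 1e-8:
                step *= 0.5
            u += step * du
            if abs(step * du) < 1e-10:
                break
        h = np.sum(family.weight(yg, eg + u, tg, shape)) + 1.0 / sigma2
        sd = 1.0 / np.sqrt(h)
        uk = u + np.sqrt(2.0) * sd * nodes
        logint = np.array([-negjoint(v) for v in uk])
        total += (np.log(np.sqrt(2.0) * sd)
                  + logsumexp(np.log(wts) + nodes**2 + logint))
    return total


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------

def _encode_factors(spec, df, fix_sigma2):
    factors = []
    for fac in spec.random_effects:
        if fix_sigma2 and fix_sigma2.get(fac, None) == 0:
            continue
        codes, levels = pd.factorize(df[fac].to_numpy())
        if len(levels) < 2:
            raise ValueError(f"random factor {fac!r} needs >= 2 levels")
        factors.append((fac, codes, len(levels), levels))
    factors.sort(key=lambda t: -t[2])
    return factors


def fit_glmm(spec: ModelSpec, df: pd.DataFrame, method="laplace",
             fix_sigma2=None, orthogonalize=False, n_nodes=25,
             outer_maxiter=400) -> FittedModel:
    """Fit a GLMM by approximate maximum marginal likelihood.

    ``method="laplace"`` (default) uses a Laplace approximation at the joint
    mode of fixed and random effects, with the variance parameters (and NB2
    shape) optimised in an outer Nelder–Mead loop.  ``method="agq"`` uses
    adaptive Gauss–Hermite quadrature with all parameters in the outer
    optimiser; it requires a single random-intercept factor and is intended
    for small instances and reference computations.

    ``fix_sigma2={factor: 0}`` removes a random factor (degenerate variance),
    which reduces the model to an ordinary GLM when no factor remains.
    """
    family = _FAMILIES[spec.family]
    resp = spec.successes if spec.successes is not None else spec.response
    if resp not in df.columns:
        raise ValueError(f"response column {resp!r} not in data")
    y, trials, X, names, info = _build_design(
        spec, df, orthogonalize=orthogonalize)
    factors = _encode_factors(spec, df, fix_sigma2)

    if method == "agq":
        return _fit_agq(spec, family, y, trials, X, names, info, factors,
                        df, n_nodes, fix_sigma2)
    if method != "laplace":
        raise ValueError(f"unknown method {method!r}")

    state = _LaplaceState(y, trials, X, family,
                          [(f[0], f[1], f[2]) for f in factors])
    state.reset()

    n_var = len(factors)
    psi0 = np.full(n_var, np.log(0.05))
    if family.has_shape:
        m, v = y.mean(), y.var()
        shape0 = m * m / max(v - m, 0.1 * m)
        psi0 = np.append(psi0, np.log(np.clip(shape0, 0.05, 100.0)))

    def unpack(psi):
        sigma2 = {factors[i][0]: float(np.exp(np.clip(psi[i], -20, 10)))
                  for i in range(n_var)}
        for f in sigma2:
            sigma2[f] = max(sigma2[f], _SIGMA2_FLOOR)
        shape = float(np.exp(np.clip(psi[n_var], -6, 8))) if family.has_shape else None
        return sigma2, shape

    def neg(psi):
        sigma2, shape = unpack(psi)
        ll, _ = state.laplace_loglik(sigma2, shape)
        if not np.isfinite(ll):
            return 1e10
        return -ll

    if len(psi0):
        res = optimize.minimize(neg, psi0, method="Nelder-Mead",
                                options={"maxiter": outer_maxiter,
                                         "xatol": 1e-4, "fatol": 1e-7})
        psi = res.x
        outer_ok = res.success or res.fun < neg(psi0)
    else:
        psi = psi0
        outer_ok = True
    sigma2, shape = unpack(psi)
    ll, inner_ok = state.laplace_loglik(sigma2, shape)

    beta = pd.Series(state.v[:X.shape[1]], index=names)
    cov = state.cov_dense(sigma2, shape)
    se = pd.Series(np.sqrt(np.clip(np.diag(cov)[:X.shape[1]], 0, None)),
                   index=names)

    re_modes = {}
    for i, (fac, codes, q, levels) in enumerate(factors):
        if fac == state.big_name:
            re_modes[fac] = pd.Series(state.ub.copy(), index=levels)
        else:
            re_modes[fac] = pd.Series(state.v[X.shape[1]:].copy(), index=levels)
    # factors dropped via fix_sigma2=0 are reported with zero variance
    full_sigma2 = dict(sigma2)
    if fix_sigma2:
        for fac, v in fix_sigma2.items():
            if v == 0 and fac in spec.random_effects:
                full_sigma2[fac] = 0.0

    k = len(beta) + len(sigma2) + (1 if family.has_shape else 0)
    return FittedModel(
        spec=spec, beta=beta, sigma2=full_sigma2, shape=shape,
        loglik=float(ll), aic=float(-2 * ll + 2 * k), re_modes=re_modes,
        se_beta=se, design_info=info, converged=bool(inner_ok and outer_ok),
        n_obs=len(y), method="laplace")


def _fit_agq(spec, family, y, trials, X, names, info, factors, df, n_nodes,
             fix_sigma2):
    if len(factors) != 1:
        raise ValueError("method='agq' supports exactly one random factor")
    fac, codes, q, levels = factors[0]
    p = X.shape[1]

    # Laplace fit for starting values
    lap = fit_glmm(spec, df, method="laplace", fix_sigma2=fix_sigma2)
    phi0 = np.concatenate([
        lap.beta.to_numpy(),
        [np.log(max(lap.sigma2[fac], 1e-4))],
        [np.log(lap.shape)] if family.has_shape else [],
    ])

    def unpack(phi):
        beta = phi[:p]
        s2 = float(np.exp(np.clip(phi[p], -20, 10)))
        shape = float(np.exp(np.clip(phi[p + 1], -6, 8))) if family.has_shape else None
        return beta, s2, shape

    def neg(phi):
        beta, s2, shape = unpack(phi)
        ll = _agq_loglik(y, trials, X, codes, q, family, beta, s2, shape,
                         n_nodes=n_nodes)
        return -ll if np.isfinite(ll) else 1e10

    res = optimize.minimize(neg, phi0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-7,
                                     "fatol": 1e-10})
    beta_v, s2, shape = unpack(res.x)
    ll = -res.fun

    # conditional modes at the optimum
    modes = np.zeros(q)
    eta0 = X @ beta_v
    for g in range(q):
        m = codes == g
        u = 0.0
        for _ in range(100):
            s = np.sum(family.score(y[m], eta0[m] + u, trials[m], shape)) - u / s2
            h = np.sum(family.weight(y[m], eta0[m] + u, trials[m], shape)) + 1 / s2
            du = s / h
            u += du
            if abs(du) < 1e-12:
                break
        modes[g] = u

    # numerical Wald SEs for beta
    se = np.full(p, np.nan)
    try:
        eps = 1e-4
        H = np.zeros((p, p))
        f0 = neg(res.x)
        for i in range(p):
            for j in range(i, p):
                xpp = res.x.copy(); xpp[i] += eps; xpp[j] += eps
                xpm = res.x.copy(); xpm[i] += eps; xpm[j] -= eps
                xmp = res.x.copy(); xmp[i] -= eps; xmp[j] += eps
                xmm = res.x.copy(); xmm[i] -= eps; xmm[j] -= eps
                H[i, j] = H[j, i] = (neg(xpp) - neg(xpm) - neg(xmp) + neg(xmm)) / (4 * eps * eps)
        se = np.sqrt(np.clip(np.diag(np.linalg.pinv(H)), 0, None))
    except Exception:  # pragma: no cover - diagnostics only
        pass

    k = p + 1 + (1 if family.has_shape else 0)
    return FittedModel(
        spec=spec, beta=pd.Series(beta_v, index=names),
        sigma2={fac: s2}, shape=shape, loglik=float(ll),
        aic=float(-2 * ll + 2 * k),
        re_modes={fac: pd.Series(modes, index=levels)},
        se_beta=pd.Series(se, index=names), design_info=info,
        converged=bool(res.success or np.isfinite(ll)), n_obs=len(y),
        method="agq")


# ---------------------------------------------------------------------------
# polynomial order selection and the model suite
# ---------------------------------------------------------------------------

def select_poly_order(spec_template: ModelSpec, df: pd.DataFrame,
                      orders=range(_MAX_POLY_ORDER + 1), **fit_kwargs):
    """Fit every polynomial order and pick the smallest marginal AIC.

    Returns ``(best_order, aic_trace)`` where ``aic_trace`` maps order to
    marginal AIC (NaN for non-convergent orders, which are excluded from the
    argmin with a warning).
    """
    if "poly" not in spec_template.terms:
        raise ValueError("spec_template must contain a 'poly' term")
    trace = {}
    for order in orders:
        spec = replace(spec_template, poly_order=order)
        if order == 0:
            spec = spec.drop(term="poly")
        try:
            fit = fit_glmm(spec, df, **fit_kwargs)
            trace[order] = fit.aic if fit.converged else np.nan
            if not fit.converged:
                warnings.warn(f"order {order}: fit did not converge; excluded")
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"order {order}: {exc}; excluded")
            trace[order] = np.nan
    finite = {k: v for k, v in trace.items() if np.isfinite(v)}
    if not finite:
        raise RuntimeError("no polynomial order converged")
    best = min(finite, key=finite.get)
    return best, trace


MODEL_SPECS = {
    1: ModelSpec("model1", "births_total", "truncnegbin", ("twinner",)),
    2: ModelSpec("model2", "twinner", "binomial", ("births_total",)),
    3: ModelSpec("model3", "twin_total", "binomial", ("births_total",),
                 successes="twin_total", failures="singleton_total"),
    4: ModelSpec("model4", "PP", "binomial", ("twin", "poly"), 2,
                 ("maternal_id", "population_id")),
    5: ModelSpec("model5", "IBI_months", "negbin", ("twin", "poly"), 2,
                 ("maternal_id", "population_id")),
    6: ModelSpec("model6", "twin", "binomial", ("poly",), 2,
                 ("maternal_id", "population_id")),
    7: ModelSpec("model7", "AFB_months", "negbin",
                 ("twinner*births_total_fac",)),
}
MODEL_SPECS[8] = MODEL_SPECS[4].drop(term="twin", new_name="model8")
MODEL_SPECS[9] = MODEL_SPECS[5].drop(term="twin", new_name="model9")
MODEL_SPECS[10] = MODEL_SPECS[6].drop(term="poly", new_name="model10")
MODEL_SPECS[11] = MODEL_SPECS[6].drop(term="poly").drop(
    random_effect="maternal_id", new_name="model11")
MODEL_SPECS[12] = MODEL_SPECS[6].drop(random_effect="maternal_id",
                                      new_name="model12")


def fit_model_suite(birth_df: pd.DataFrame, mother_df: pd.DataFrame,
                    poly_orders=None, select_orders=False,
                    models=None, **fit_kwargs) -> ModelSuite:
    """Fit the twelve-model suite (or a subset via ``models``).

    Models 1–3 and 7 use mother-level data; 4–6 and 8–12 use birth-level
    data, with models 5 and 9 restricted to births followed by another birth
    (IBI present).  ``poly_orders`` maps model number (4, 5, 6) to the
    polynomial order; with ``select_orders=True`` the order minimising the
    marginal AIC (0..6) is chosen per base model, as in the original
    analysis.  Derived models 8/9/12 reuse the base model's order.
    """
    orders = {4: 2, 5: 2, 6: 2}
    if poly_orders:
        orders.update(poly_orders)
    suite = ModelSuite()
    ibi_df = birth_df[birth_df["PP"] == 1]

    if select_orders:
        for num in (4, 5, 6):
            best, _ = select_poly_order(MODEL_SPECS[num],
                                        ibi_df if num == 5 else birth_df,
                                        **fit_kwargs)
            orders[num] = best
    suite.poly_orders = dict(orders)

    wanted = set(models) if models is not None else set(range(1, 13))
    base_order = {4: 4, 5: 5, 6: 6, 8: 4, 9: 5, 12: 6}
    for num in sorted(wanted):
        spec = MODEL_SPECS[num]
        if "poly" in spec.terms:
            spec = replace(spec, poly_order=orders[base_order[num]])
            if orders[base_order[num]] == 0:
                spec = spec.drop(term="poly")
        if num in (1, 2, 3, 7):
            data = mother_df
        elif num in (5, 9):
            data = ibi_df
        else:
            data = birth_df
        suite[num] = fit_glmm(spec, data, **fit_kwargs)
    return suite


# ---------------------------------------------------------------------------
# simulation from a fit and bootstrap LRT
# ---------------------------------------------------------------------------

def simulate_response(fit: FittedModel, df: pd.DataFrame, rng):
    """Draw a new response vector from the fitted model, with fresh random
    effects drawn from N(0, sigma2) for every grouping factor."""
    _, trials, X, names, _ = _build_design(fit.spec, df, fit.design_info)
    eta = X @ fit.beta.reindex(names).to_numpy()
    for fac, s2 in fit.sigma2.items():
        if s2 <= 0:
            continue
        codes, levels = pd.factorize(df[fac].to_numpy())
        u = rng.normal(0.0, np.sqrt(s2), size=len(levels))
        eta = eta + u[codes]
    return fit.family().sample(rng, eta, trials, fit.shape), trials


def _with_response(df, spec, y):
    out = df.copy()
    if spec.successes is not None:
        trials = (df[spec.successes] + df[spec.failures]).to_numpy()
        out[spec.successes] = y
        out[spec.failures] = trials - y
    else:
        out[spec.response] = y
    return out


def lrt_parametric_bootstrap(null_fit: FittedModel, alt_fit: FittedModel,
                             df: pd.DataFrame, n_boot=1000, seed=0,
                             **fit_kwargs):
    """Parametric-bootstrap likelihood-ratio test of nested GLMMs.

    Simulates ``n_boot`` responses from the null fit, refits both models on
    each, and returns ``(p_value, lr_obs, lr_boot)`` with
    ``p = (1 + #{LR* >= LR_obs}) / (n_kept + 1)``.  Refit failures are
    dropped; more than 10% failures raises.
    """
    lr_obs = 2.0 * (alt_fit.loglik - null_fit.loglik)
    lrs = []
    failures = 0
    for b in range(n_boot):
        rng = np.random.default_rng([seed, b])
        y, _ = simulate_response(null_fit, df, rng)
        sim = _with_response(df, null_fit.spec, y)
        try:
            f0 = fit_glmm(null_fit.spec, sim, **fit_kwargs)
            f1 = fit_glmm(alt_fit.spec, sim, **fit_kwargs)
            lrs.append(2.0 * (f1.loglik - f0.loglik))
        except Exception:
            failures += 1
    if failures > 0.1 * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap refits failed")
    lrs = np.asarray(lrs)
    p = (1.0 + np.sum(lrs >= lr_obs)) / (len(lrs) + 1.0)
    return p, lr_obs, lrs
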