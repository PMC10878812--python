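"""Posterior inference engine for the hierarchical models in this package.

The regression models fitted here (lognormal reaction-time, Poisson
commission-error, Gaussian second-level fNIRS models) are all either linear
mixed models on a transformed scale or low-dimensional generalized linear
(mixed) models.  Inference uses an exact-conditional scheme:

* For linear mixed models, random effects and fixed effects are integrated
  out analytically, leaving a low-dimensional marginal posterior over the
  variance parameters.  That marginal is approximated by a Laplace
  (Gaussian) approximation at its mode; variance-parameter draws are taken
  from it, and for each draw the fixed effects are sampled from their exact
  Gaussian conditional posterior.
* For Poisson models with a participant-level random intercept, the random
  effect is integrated by Gauss-Hermite quadrature and the joint posterior
  over coefficients and the random-effect scale is approximated by a
  Laplace approximation.

With the data sizes this package targets (hundreds to thousands of
observations per fit) the posteriors are close to Gaussian and these
approximations are accurate; they are also deterministic up to the draw
seed, which keeps the full pipeline reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize

__all__ = [
    "PosteriorSummary",
    "PosteriorFit",
    "hpd_interval",
    "fit_lmm",
    "fit_poisson",
    "LooResult",
    "compare_loo",
]


# --------------------------------------------------------------------------
# HPD intervals and posterior containers
# --------------------------------------------------------------------------

def hpd_interval(draws, mass: float = 0.95):
    """Highest-posterior-density interval from posterior draws.

    Returns the shortest contiguous interval containing ``ceil(mass * n)``
    of the sorted draws (assumes a unimodal posterior).  Width ties are
    broken toward the smallest lower bound.

    Parameters
    ----------
    draws : array-like
        One-dimensional collection of posterior draws.
    mass : float
        Probability mass the interval must contain, in (0, 1].

    Returns
    -------
    (lo, hi) : tuple of float
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("empty draws")
    if not 0.0 < mass <= 1.0:
        raise ValueError("mass must be in (0, 1]")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: smallest lo
    return float(x[i]), float(x[i + k - 1])


@dataclass
class PosteriorSummary:
    """A named effect with posterior mean and 95% HPD interval."""

    name: str
    mean: float
    hpd_lo: float
    hpd_hi: float
    n_draws: int
    scale: str = "model"

    @classmethod
    def from_draws(cls, name, draws, mass=0.95, scale="model"):
        draws = np.asarray(draws, dtype=float).ravel()
        lo, hi = hpd_interval(draws, mass)
        return cls(name, float(np.mean(draws)), lo, hi, draws.size, scale)

    def as_dict(self):
        return {
            "effect": self.name,
            "scale": self.scale,
            "mean": self.mean,
            "hpd_lo": self.hpd_lo,
            "hpd_hi": self.hpd_hi,
            "n_draws": self.n_draws,
        }


@dataclass
class PosteriorFit:
    """Posterior draws plus diagnostics for one fitted model.

    ``draws`` maps parameter names to arrays whose first axis indexes
    draws.  ``log_likelihood`` (draws x observations), when present, holds
    pointwise log-likelihood values for LOO model comparison.
    """

    draws: dict
    diagnostics: dict = field(default_factory=dict)
    log_likelihood: np.ndarray | None = None

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", True))

    def to_inference_data(self):
        """Export draws (and pointwise log-likelihood, if stored) as an
        ArviZ InferenceData container."""
        import arviz as az

        posterior = {k: np.asarray(v)[None, ...] for k, v in
                     self.draws.items() if np.asarray(v).ndim <= 2}
        ll = None
        if self.log_likelihood is not None:
            ll = {"y": self.log_likelihood[None, :, :]}
        return az.from_dict(posterior=posterior, log_likelihood=ll)

    def summary(self, name, index=None, mass=0.95, scale="model"):
        d = self.draws[name]
        if index is not None:
            d = d[:, index]
        label = name if index is None else f"{name}[{index}]"
        return PosteriorSummary.from_draws(label, d, mass=mass, scale=scale)


# --------------------------------------------------------------------------
# Laplace machinery
# --------------------------------------------------------------------------

def _numeric_hessian(f, x, step=1e-4):
    """Central-difference Hessian of scalar ``f`` at ``x``."""
    x = np.asarray(x, dtype=float)
    d = x.size
    h = step * np.maximum(1.0, np.abs(x))
    H = np.empty((d, d))
    f0 = f(x)
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        e = np.zeros(d)
        e[i] = h[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j] + fmm
            ) / (2.0 * h[i] * h[j])
    return H


def _safe_cov_from_neg_hessian(H):
    """Invert a negative log-posterior Hessian into a PD covariance.

    Residual negative or near-zero curvature directions (saddles left by
    the optimizer, finite-difference noise) are handled by taking the
    curvature magnitude with a relative floor, which bounds the sampled
    spread in those directions instead of letting it diverge.
    """
    H = 0.5 * (H + H.T)
    w, V = np.linalg.eigh(H)
    w = np.abs(w)
    w = np.maximum(w, max(1e-6 * w.max(), 1e-8))
    return (V / w) @ V.T


def _laplace(negpost, x0, bounds=None):
    """Minimize a negative log posterior and return (mode, covariance, ok).

    Quasi-Newton descent followed by a simplex polish; the polish mops up
    the noisy/cliff regions where finite-difference gradients mislead.
    """
    res = optimize.minimize(negpost, x0, method="L-BFGS-B", bounds=bounds)
    polish = optimize.minimize(negpost, res.x, method="Nelder-Mead",
                               options={"maxiter": 4000, "xatol": 1e-6,
                                        "fatol": 1e-8})
    best = polish if polish.fun <= res.fun else res
    H = _numeric_hessian(negpost, best.x)
    cov = _safe_cov_from_neg_hessian(H)
    ok = bool(res.success or polish.success)
    return best.x, cov, ok


# --------------------------------------------------------------------------
# Linear mixed models
# --------------------------------------------------------------------------

def _chol_from_theta(theta, q):
    """Unconstrained vector -> lower Cholesky factor of a q x q covariance."""
    L = np.zeros((q, q))
    idx = 0
    for j in range(q):
        L[j, j] = np.exp(theta[idx])
        idx += 1
    for j in range(q):
        for i in range(j + 1, q):
            L[i, j] = theta[idx]
            idx += 1
    return L


def _n_chol_params(q):
    return q + q * (q - 1) // 2


class _LmmCore:
    """Marginal-likelihood computations for y = X b + Z u + e.

    Rows are grouped by ``groups`` (participants); u is a q-dimensional
    random effect per group with covariance S.  The residual is either
    iid N(0, sigma^2) (univariate) or, when ``pairs``/``outcome`` are
    given, correlated within row pairs through a 2 x 2 covariance R
    (the multivariate HbO/HbR case).  Missing halves of a pair are
    handled by marginalization.
    """

    def __init__(self, y, X, groups, Z, outcome=None, pairs=None,
                 beta_prior_sd=10.0, resid_scale=1.0, re_scale=1.0):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.Z = np.asarray(Z, dtype=float)
        self.groups = np.asarray(groups)
        self.n, self.p = self.X.shape
        self.q = self.Z.shape[1]
        self.multivariate = outcome is not None
        self.outcome = None if outcome is None else np.asarray(outcome, dtype=int)
        self.pairs = None if pairs is None else np.asarray(pairs)
        self.beta_prior_sd = float(beta_prior_sd)
        self.resid_scale = float(resid_scale)
        self.re_scale = float(re_scale)
        self.group_ids = np.unique(self.groups)
        self.group_rows = [np.nonzero(self.groups == g)[0] for g in self.group_ids]
        if self.multivariate:
            self.n_resid = 3  # cholesky of 2x2 R
            # precompute complete-pair rows (ordered hbo, hbr) and partials
            pair_ids, inverse = np.unique(self.pairs, return_inverse=True)
            full, partial_rows, partial_out = [], [], []
            for k in range(pair_ids.size):
                rows = np.nonzero(inverse == k)[0]
                if rows.size == 2:
                    o = self.outcome[rows]
                    full.append(rows[np.argsort(o)])
                else:
                    partial_rows.append(rows[0])
                    partial_out.append(self.outcome[rows[0]])
            self._full_pairs = (np.array(full, dtype=int).reshape(-1, 2)
                                if full else np.empty((0, 2), dtype=int))
            self._partial_rows = np.array(partial_rows, dtype=int)
            self._partial_out = np.array(partial_out, dtype=int)
        else:
            self.n_resid = 1  # log sigma
        self.n_theta = self.n_resid + _n_chol_params(self.q)

    # -- parameter handling -------------------------------------------------
    def unpack(self, theta):
        theta = np.asarray(theta, dtype=float)
        resid = theta[: self.n_resid]
        Ls = _chol_from_theta(theta[self.n_resid:], self.q)
        S = Ls @ Ls.T
        return resid, S

    def theta0(self):
        t = np.zeros(self.n_theta)
        if self.multivariate:
            t[0] = np.log(self.resid_scale)
            t[1] = np.log(self.resid_scale)
            t[2] = 0.0
        else:
            t[0] = np.log(self.resid_scale)
        for j in range(self.q):
            t[self.n_resid + j] = np.log(self.re_scale)
        return t

    def log_prior(self, theta):
        """Weak priors keeping scales proper: lognormal-ish on sds."""
        lp = 0.0
        sd = 1.5
        if self.multivariate:
            lp += -0.5 * ((theta[0] - np.log(self.resid_scale)) / sd) ** 2
            lp += -0.5 * ((theta[1] - np.log(self.resid_scale)) / sd) ** 2
            lp += -0.5 * (theta[2] / (1.5 * self.resid_scale)) ** 2
        else:
            lp += -0.5 * ((theta[0] - np.log(self.resid_scale)) / sd) ** 2
        k = self.n_resid
        for j in range(self.q):
            lp += -0.5 * ((theta[k] - np.log(self.re_scale)) / sd) ** 2
            k += 1
        for j in range(self.n_theta - k):
            lp += -0.5 * (theta[k + j] / (1.5 * self.re_scale)) ** 2
        return lp

    # -- whitening for the multivariate residual ----------------------------
    def _whitened(self, resid):
        """Return (y, X, Z) with unit residual variance given resid params."""
        if not self.multivariate:
            sigma = np.exp(resid[0])
            return self.y / sigma, self.X / sigma, self.Z / sigma, \
                self.n * np.log(sigma ** 2)
        Lr = np.array([[np.exp(resid[0]), 0.0], [resid[2], np.exp(resid[1])]])
        R = Lr @ Lr.T
        y = self.y.copy()
        X = self.X.copy()
        Z = self.Z.copy()
        logdet = 0.0
        Li = np.linalg.inv(Lr)
        fp = self._full_pairs
        if fp.size:
            y[fp.ravel()] = np.einsum("ij,kj->ki", Li, y[fp]).ravel()
            X[fp.ravel()] = np.einsum("ij,kjp->kip", Li, X[fp]).reshape(
                -1, self.p)
            Z[fp.ravel()] = np.einsum("ij,kjq->kiq", Li, Z[fp]).reshape(
                -1, self.q)
            # log det R = 2 (log l11 + log l22) from the Cholesky factor
            logdet += fp.shape[0] * 2.0 * (resid[0] + resid[1])
        if self._partial_rows.size:
            var = R[self._partial_out, self._partial_out]
            s = np.sqrt(var)
            y[self._partial_rows] /= s
            X[self._partial_rows] /= s[:, None]
            Z[self._partial_rows] /= s[:, None]
            logdet += np.log(var).sum()
        return y, X, Z, logdet

    # -- marginal posterior over theta --------------------------------------
    def beta_given_theta(self, theta):
        """Return (m, Lam, log_marg) for beta | theta with beta integrated."""
        resid, S = self.unpack(theta)
        yw, Xw, Zw, logdetR = self._whitened(resid)
        q = self.q
        Iq = np.eye(q)
        try:
            Sinv = np.linalg.inv(S + 1e-12 * Iq)
        except np.linalg.LinAlgError:
            return None
        XtVX = np.zeros((self.p, self.p))
        XtVy = np.zeros(self.p)
        ytVy = 0.0
        logdetV = logdetR
        for rows in self.group_rows:
            Xi = Xw[rows]
            Zi = Zw[rows]
            yi = yw[rows]
            ZtZ = Zi.T @ Zi
            M = Sinv + ZtZ
            try:
                Minv = np.linalg.inv(M)
            except np.linalg.LinAlgError:
                return None
            sign, ld = np.linalg.slogdet(Iq + ZtZ @ S)
            if sign <= 0:
                return None
            logdetV += ld
            ZtX = Zi.T @ Xi
            Zty = Zi.T @ yi
            XtVX += Xi.T @ Xi - ZtX.T @ Minv @ ZtX
            XtVy += Xi.T @ yi - ZtX.T @ Minv @ Zty
            ytVy += yi @ yi - Zty @ Minv @ Zty
        Lam = XtVX + np.eye(self.p) / self.beta_prior_sd ** 2
        try:
            cf = np.linalg.cholesky(Lam)
        except np.linalg.LinAlgError:
            return None
        m = np.linalg.solve(Lam, XtVy)
        logdetLam = 2.0 * np.sum(np.log(np.diag(cf)))
        log_marg = -0.5 * (
            logdetV
            + ytVy
            - m @ Lam @ m
            + logdetLam
            + 2 * self.p * np.log(self.beta_prior_sd)
        )
        if not (np.isfinite(log_marg) and np.isfinite(m).all()):
            return None
        return m, Lam, log_marg

    def neg_log_post(self, theta):
        out = self.beta_given_theta(theta)
        if out is None:
            return 1e10
        _, _, log_marg = out
        val = -(log_marg + self.log_prior(theta))
        return val if np.isfinite(val) else 1e10

    # -- random-effect conditionals -----------------------------------------
    def sample_u(self, theta, beta, rng):
        """Draw u_g | beta, theta, y for every group; returns (G, q)."""
        resid, S = self.unpack(theta)
        yw, Xw, Zw, _ = self._whitened(resid)
        Sinv = np.linalg.inv(S + 1e-12 * np.eye(self.q))
        U = np.empty((len(self.group_rows), self.q))
        for gi, rows in enumerate(self.group_rows):
            Zi = Zw[rows]
            ri = yw[rows] - Xw[rows] @ beta
            P = Sinv + Zi.T @ Zi
            cov = np.linalg.inv(P)
            mu = cov @ (Zi.T @ ri)
            U[gi] = rng.multivariate_normal(mu, cov)
        return U


def fit_lmm(y, X, groups, Z, *, outcome=None, pairs=None,
            beta_prior_sd=10.0, resid_scale=1.0, re_scale=1.0,
            n_draws=2000, seed=0, pointwise=False, coef_names=None):
    """Fit a Bayesian linear mixed model and return posterior draws.

    Parameters
    ----------
    y, X, groups, Z
        Response (n,), fixed-effect design (n, p), group labels (n,) and
        random-effect design (n, q); one q-dimensional random effect per
        group with an unstructured covariance.
    outcome, pairs
        For the bivariate (HbO, HbR) case: outcome index in {0, 1} per row
        and a pair identifier linking the two rows that share a residual
        2 x 2 covariance.  Leave ``None`` for univariate models.
    beta_prior_sd, resid_scale, re_scale
        Prior scales: N(0, beta_prior_sd^2) on fixed effects; weakly
        informative lognormal-type priors centred at ``resid_scale`` and
        ``re_scale`` on the residual and random-effect sds.
    pointwise
        If True (univariate only), store pointwise log-likelihood values
        per draw for LOO comparison.

    Returns
    -------
    PosteriorFit
        Draws: ``beta`` (n_draws, p), ``theta`` (variance parameters),
        ``sigma`` (univariate) and ``sd_u`` (random-effect sds).
    """
    core = _LmmCore(y, X, groups, Z, outcome=outcome, pairs=pairs,
                    beta_prior_sd=beta_prior_sd, resid_scale=resid_scale,
                    re_scale=re_scale)
    mode, cov, ok = _laplace(core.neg_log_post, core.theta0())
    rng = np.random.default_rng(seed)
    theta_draws = rng.multivariate_normal(mode, cov, size=n_draws)
    beta_draws = np.empty((n_draws, core.p))
    sigma_draws = np.empty(n_draws)
    sd_u_draws = np.empty((n_draws, core.q))
    re_cov_draws = np.empty((n_draws, core.q, core.q))
    loglik = np.empty((n_draws, core.n)) if pointwise else None
    # cache conditional posteriors: recomputing per draw is the honest route
    for d in range(n_draws):
        th = theta_draws[d]
        out = core.beta_given_theta(th)
        if out is None:  # fall back to the mode on numerically bad draws
            th = mode
            theta_draws[d] = th
            out = core.beta_given_theta(th)
        m, Lam, _ = out
        cf = np.linalg.cholesky(Lam)
        beta = m + np.linalg.solve(cf.T, rng.standard_normal(core.p))
        beta_draws[d] = beta
        resid, S = core.unpack(th)
        sd_u_draws[d] = np.sqrt(np.diag(S))
        re_cov_draws[d] = S
        sigma_draws[d] = np.exp(resid[0])
        if pointwise:
            U = core.sample_u(th, beta, rng)
            sigma = np.exp(resid[0])
            mu = core.X @ beta
            for gi, rows in enumerate(core.group_rows):
                mu[rows] += core.Z[rows] @ U[gi]
            loglik[d] = (
                -0.5 * np.log(2 * np.pi * sigma ** 2)
                - 0.5 * ((core.y - mu) / sigma) ** 2
            )
    diagnostics = {
        "converged": ok,
        "method": "marginal Laplace + exact Gaussian conditional",
        "theta_mode": mode,
        "n_obs": core.n,
        "seed": seed,
    }
    draws = {
        "beta": beta_draws,
        "theta": theta_draws,
        "sigma": sigma_draws,
        "sd_u": sd_u_draws,
        "re_cov": re_cov_draws,
    }
    if coef_names is not None:
        draws.update({nm: beta_draws[:, j] for j, nm in enumerate(coef_names)})
    return PosteriorFit(draws=draws, diagnostics=diagnostics,
                        log_likelihood=loglik)


# --------------------------------------------------------------------------
# Poisson models (Gauss-Hermite marginalized random intercept)
# --------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = hermegauss(31)  # probabilists' nodes: N(0,1) weights
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2 * np.pi)


def _poisson_marginal_loglik(y, eta, log_tau):
    """Sum of per-observation marginal log-likelihoods with a N(0, tau^2)
    random intercept integrated by Gauss-Hermite quadrature."""
    tau = np.exp(log_tau)
    lam = eta[:, None] + tau * _GH_NODES[None, :]
    # log Poisson pmf without the y! constant
    logp = y[:, None] * lam - np.exp(lam)
    mx = logp.max(axis=1, keepdims=True)
    lik = np.log((np.exp(logp - mx) * _GH_WEIGHTS[None, :]).sum(axis=1)) + mx[:, 0]
    return lik


def fit_poisson(y, X, *, offset=None, random_intercept=True,
                beta_prior_sd=10.0, tau_scale=0.3,
                n_draws=2000, seed=0, pointwise=False, coef_names=None):
    """Bayesian Poisson regression, optionally with an observation-level
    N(0, tau^2) random intercept (lognormal overdispersion).

    ``offset`` is added to the linear predictor (use log-exposure so that
    rate-scale quantities are exposure-invariant).  Inference is a Laplace
    approximation of the joint posterior over coefficients and log tau.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    d = p + (1 if random_intercept else 0)

    def negpost(par):
        beta = par[:p]
        eta = X @ beta + off
        if random_intercept:
            ll = _poisson_marginal_loglik(y, eta, par[p]).sum()
            lp = -0.5 * ((par[p] - np.log(tau_scale)) / 1.5) ** 2
        else:
            ll = np.sum(y * eta - np.exp(eta))
            lp = 0.0
        lp += -0.5 * np.sum((beta / beta_prior_sd) ** 2)
        val = -(ll + lp)
        return val if np.isfinite(val) else 1e10

    x0 = np.zeros(d)
    with np.errstate(over="ignore"):
        x0[0] = np.log(max(y.mean(), 0.5)) - off.mean()
        if random_intercept:
            x0[p] = np.log(tau_scale)
        mode, cov, ok = _laplace(negpost, x0)
    rng = np.random.default_rng(seed)
    par_draws = rng.multivariate_normal(mode, cov, size=n_draws)
    beta_draws = par_draws[:, :p]
    draws = {"beta": beta_draws}
    if random_intercept:
        draws["tau"] = np.exp(par_draws[:, p])
    if coef_names is not None:
        draws.update({nm: beta_draws[:, j] for j, nm in enumerate(coef_names)})
    loglik = None
    if pointwise:
        from scipy.special import gammaln
        loglik = np.empty((n_draws, n))
        for i in range(n_draws):
            eta = X @ beta_draws[i] + off
            if random_intercept:
                loglik[i] = _poisson_marginal_loglik(
                    y, eta, np.log(draws["tau"][i])) - gammaln(y + 1)
            else:
                loglik[i] = y * eta - np.exp(eta) - gammaln(y + 1)
    diagnostics = {"converged": ok, "mode": mode, "seed": seed,
                   "method": "joint Laplace (Gauss-Hermite marginal)"}
    return PosteriorFit(draws=draws, diagnostics=diagnostics,
                        log_likelihood=loglik)


# --------------------------------------------------------------------------
# LOO comparison
# --------------------------------------------------------------------------

@dataclass
class LooResult:
    """PSIS-LOO comparison of two models fitted to the same observations."""

    elpd_diff: float
    se_diff: float
    elpd_a: float
    elpd_b: float
    pareto_k_max_a: float
    pareto_k_max_b: float


def _loo(fit: PosteriorFit):
    import arviz as az

    if fit.log_likelihood is None:
        raise ValueError("fit has no stored pointwise log-likelihood; "
                         "refit with pointwise=True")
    ll = fit.log_likelihood[None, :, :]  # (chain, draw, obs)
    idata = az.from_dict(
        posterior={"dummy": fit.draws["beta"][None, :, 0]},
        log_likelihood={"y": ll},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True)
    return res


def compare_loo(fit_a: PosteriorFit, fit_b: PosteriorFit) -> LooResult:
    """PSIS-smoothed LOO elpd difference (A minus B) with standard error.

    Both fits must carry pointwise log-likelihoods over the identical
    observation set (same length, same order).
    """
    la = _loo(fit_a)
    lb = _loo(fit_b)
    pa = np.asarray(la.loo_i)
    pb = np.asarray(lb.loo_i)
    if pa.shape != pb.shape:
        raise ValueError("models were fitted to different observation sets")
    diff = pa - pb
    se = float(np.sqrt(diff.size * np.var(diff, ddof=1)))
    return LooResult(
        elpd_diff=float(diff.sum()),
        se_diff=se,
        elpd_a=float(la.elpd_loo),
        elpd_b=float(lb.elpd_loo),
        pareto_k_max_a=float(np.max(np.asarray(la.pareto_k))),
        pareto_k_max_b=float(np.max(np.asarray(lb.pareto_k))),
    )
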