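"""Beta-binomial additive occurrence models for hourly call presence.

Hydrophone data arrive as station-month records: ``k_hours`` hours with at
least one song call detected out of ``n_hours`` analyzed. Consecutive hours
are not independent — a whale singing in one hour tends to be heard the
next — so the counts are over-dispersed relative to a binomial. The model
here is a beta-binomial whose mean ``mu`` (probability of hearing at least
one call in an hour) and over-dispersion ``sigma`` both carry additive
predictors in longitude, latitude and month, in the spirit of distributional
regression (GAMLSS): logit link on ``mu``, log link on ``sigma``.

The beta-binomial is parameterized so that the mixing probability is
``Beta(mu/sigma, (1-mu)/sigma)``; its variance is
``n*mu*(1-mu)*(1 + sigma*(n-1)/(1+sigma))``, which collapses to the binomial
variance as ``sigma -> 0``.

Fitting is by direct maximum likelihood over the joint coefficient vector
with analytic gradients, multi-started quasi-Newton (L-BFGS-B). Candidate
structures are ranked by small-sample corrected AIC (AICc).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, expit, gammaln, logit
from scipy.special import psi as digamma

from .splines import cr_design, quantile_knots

__all__ = [
    "BBParams",
    "ModelStructure",
    "FitControl",
    "DesignInfo",
    "bb_logpmf",
    "bb_mean_var",
    "build_design",
    "aicc",
    "BetaBinomialGAM",
    "BetaBinomialGAMResults",
    "fit_occurrence_model",
    "select_model",
    "bootstrap_refit",
    "TABLE_CANDIDATES",
]

ACOUSTIC_COLUMNS = ["station_id", "lon_east", "lat", "month",
                    "n_hours", "k_hours", "call_type"]

_ETA_MU_MAX = 30.0
_ETA_SIGMA_MAX = 25.0


# ---------------------------------------------------------------------------
# distribution


@dataclass(frozen=True)
class BBParams:
    """Beta-binomial parameters: mean ``mu`` and over-dispersion ``sigma``."""

    mu: float
    sigma: float

    def __post_init__(self):
        if not 0.0 < self.mu < 1.0:
            raise ValueError(f"mu must be in (0, 1), got {self.mu}")
        if self.sigma < 0.0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


def bb_logpmf(k, n, params: BBParams | None = None, *, mu=None, sigma=None):
    """Log-pmf of the beta-binomial count ``k`` out of ``n`` trials.

    Computed through log-gamma differences:
    ``log C(n,k) + B(k+a, n-k+b) - B(a, b)`` with ``a = mu/sigma`` and
    ``b = (1-mu)/sigma``. ``sigma = 0`` returns the binomial log-pmf
    (the limit distribution). Broadcasts over array arguments.
    """
    if params is not None:
        mu, sigma = params.mu, params.sigma
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("require 0 <= k <= n")
    if np.any(sigma < 0):
        raise ValueError("sigma must be >= 0")

    choose = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = mu / np.where(sigma > 0, sigma, 1.0)
        b = (1.0 - mu) / np.where(sigma > 0, sigma, 1.0)
        bb = choose + betaln(k + a, n - k + b) - betaln(a, b)
        # binomial limit, evaluated safely at k = 0 and k = n
        binom = choose + np.where(k > 0, k * np.log(mu), 0.0) \
            + np.where(n - k > 0, (n - k) * np.log1p(-mu), 0.0)
    out = np.where(sigma > 0, bb, binom)
    return out if out.ndim else float(out)


def bb_mean_var(n, params: BBParams):
    """Closed-form mean and variance of the beta-binomial."""
    n = float(n)
    mu, s = params.mu, params.sigma
    mean = n * mu
    var = n * mu * (1 - mu) * (1 + s * (n - 1) / (1 + s))
    return mean, var


# ---------------------------------------------------------------------------
# model structure and design matrices


@dataclass(frozen=True)
class ModelStructure:
    """Candidate structure: likelihood family and predictor complexity.

    ``mu_terms`` / ``sigma_terms`` take values ``constant`` (intercept only),
    ``linear`` (lon + lat + month factor) or ``additive`` (cubic regression
    splines in lon and lat + month factor). A plain binomial family has no
    over-dispersion parameter (``sigma_terms='none'``).
    """

    family: str = "beta_binomial"
    mu_terms: str = "additive"
    sigma_terms: str = "additive"
    spline_df: int = 4
    month_as_factor: bool = True

    def __post_init__(self):
        if self.family not in ("binomial", "beta_binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.mu_terms not in ("constant", "linear", "additive"):
            raise ValueError(f"unknown mu_terms {self.mu_terms!r}")
        if self.sigma_terms not in ("none", "constant", "linear", "additive"):
            raise ValueError(f"unknown sigma_terms {self.sigma_terms!r}")
        if self.family == "binomial" and self.sigma_terms != "none":
            raise ValueError("binomial family requires sigma_terms='none'")
        if self.family == "beta_binomial" and self.sigma_terms == "none":
            raise ValueError("beta_binomial family requires sigma terms")
        if self.spline_df < 3:
            raise ValueError("spline_df must be >= 3")

    @property
    def label(self) -> str:
        fam = {"binomial": "Binomial", "beta_binomial": "Beta-Binomial"}[self.family]
        cap = {"none": "N/A", "constant": "Constant",
               "linear": "Linear", "additive": "Additive"}
        return f"{fam} / {cap[self.mu_terms]} / {cap[self.sigma_terms]}"


#: The six candidate structures ranked in the occurrence model selection:
#: every combination of binomial vs beta-binomial family with linear or
#: additive mean terms, and constant/linear/additive dispersion terms.
TABLE_CANDIDATES = [
    ModelStructure("beta_binomial", "additive", "additive"),
    ModelStructure("beta_binomial", "additive", "linear"),
    ModelStructure("beta_binomial", "additive", "constant"),
    ModelStructure("beta_binomial", "linear", "linear"),
    ModelStructure("binomial", "additive", "none"),
    ModelStructure("binomial", "linear", "none"),
]


@dataclass
class DesignInfo:
    """Everything needed to rebuild design rows for new (lon, lat, month)."""

    structure: ModelStructure
    knots_lon: np.ndarray | None
    knots_lat: np.ndarray | None
    lon_center: float
    lon_scale: float
    lat_center: float
    lat_scale: float
    month_levels: list[int] = field(default_factory=list)  # reference first
    n_cols_mu: int = 0
    n_cols_sigma: int = 0

    def param_design(self, lon, lat, month, which: str) -> np.ndarray:
        terms = (self.structure.mu_terms if which == "mu"
                 else self.structure.sigma_terms)
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        month = np.atleast_1d(np.asarray(month, dtype=int))
        if np.any((month < 1) | (month > 12)):
            raise ValueError("month must be in 1..12")
        cols = [np.ones_like(lon)]
        if terms == "linear":
            cols.append((lon - self.lon_center) / self.lon_scale)
            cols.append((lat - self.lat_center) / self.lat_scale)
        elif terms == "additive":
            cols.append(cr_design(lon, self.knots_lon))
            cols.append(cr_design(lat, self.knots_lat))
        if terms in ("linear", "additive") and self.structure.month_as_factor:
            missing = set(np.unique(month)) - set(self.month_levels)
            if missing:
                warnings.warn(
                    f"months {sorted(missing)} not in training data; "
                    "predicting at the reference-month level",
                    stacklevel=2,
                )
            for lev in self.month_levels[1:]:
                cols.append((month == lev).astype(float))
        return np.column_stack([np.column_stack([c]) if c.ndim == 1 else c
                                for c in cols])

    def is_extrapolation(self, lon, lat) -> np.ndarray:
        """True where a point lies outside the spline knot ranges."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        out = np.zeros(lon.shape, dtype=bool)
        if self.knots_lon is not None:
            out |= (lon < self.knots_lon[0]) | (lon > self.knots_lon[-1])
            out |= (lat < self.knots_lat[0]) | (lat > self.knots_lat[-1])
        return out


def _make_info(data: pd.DataFrame, structure: ModelStructure) -> DesignInfo:
    lon = data["lon_east"].to_numpy(dtype=float)
    lat = data["lat"].to_numpy(dtype=float)
    month = data["month"].to_numpy(dtype=int)
    if np.any((month < 1) | (month > 12)):
        raise ValueError("month must be in 1..12")

    needs_spline = "additive" in (structure.mu_terms, structure.sigma_terms)
    knots_lon = knots_lat = None
    if needs_spline:
        try:
            knots_lon = quantile_knots(lon, structure.spline_df)
        except ValueError as err:
            raise ValueError(f"lon_east: {err}") from err
        try:
            knots_lat = quantile_knots(lat, structure.spline_df)
        except ValueError as err:
            raise ValueError(f"lat: {err}") from err

    levels = sorted(set(int(m) for m in month))
    ref = 1 if 1 in levels else levels[0]
    levels = [ref] + [m for m in levels if m != ref]

    def _scale(x):
        s = float(np.std(x))
        return float(np.mean(x)), (s if s > 0 else 1.0)

    lon_c, lon_s = _scale(lon)
    lat_c, lat_s = _scale(lat)
    info = DesignInfo(structure, knots_lon, knots_lat,
                      lon_c, lon_s, lat_c, lat_s, levels)
    info.n_cols_mu = info.param_design(lon[:1], lat[:1], month[:1], "mu").shape[1]
    if structure.sigma_terms != "none":
        info.n_cols_sigma = info.param_design(
            lon[:1], lat[:1], month[:1], "sigma").shape[1]
    return info


def build_design(data: pd.DataFrame, structure: ModelStructure):
    """Design matrices for the mean and dispersion linear predictors.

    Returns ``(X_mu, X_sigma, info)``; ``X_sigma`` is ``None`` for the
    binomial family. Column counts: additive terms give
    ``1 + spline_df + spline_df + (levels - 1)`` columns, linear terms
    ``1 + 2 + (levels - 1)``, constant a lone intercept.
    """
    info = _make_info(data, structure)
    lon = data["lon_east"].to_numpy(dtype=float)
    lat = data["lat"].to_numpy(dtype=float)
    month = data["month"].to_numpy(dtype=int)
    X_mu = info.param_design(lon, lat, month, "mu")
    X_sigma = None
    if structure.sigma_terms != "none":
        X_sigma = info.param_design(lon, lat, month, "sigma")
    return X_mu, X_sigma, info


# ---------------------------------------------------------------------------
# information criterion


def aicc(loglik: float, df: int, n_obs: int) -> float:
    """Small-sample corrected AIC: ``-2*loglik + 2*df + 2*df*(df+1)/(n-df-1)``."""
    if n_obs <= df + 1:
        raise ValueError(
            f"AICc undefined for n_obs={n_obs} <= df+1={df + 1}")
    return -2.0 * loglik + 2.0 * df + 2.0 * df * (df + 1) / (n_obs - df - 1)


# ---------------------------------------------------------------------------
# likelihood internals


def _nll_grad_betabin(theta, X_mu, X_sigma, k, n):
    p1 = X_mu.shape[1]
    eta1 = np.clip(X_mu @ theta[:p1], -_ETA_MU_MAX, _ETA_MU_MAX)
    eta2 = np.clip(X_sigma @ theta[p1:], -_ETA_SIGMA_MAX, _ETA_SIGMA_MAX)
    mu = expit(eta1)
    sig = np.exp(eta2)
    a = mu / sig
    b = (1.0 - mu) / sig

    ll = np.sum(betaln(k + a, n - k + b) - betaln(a, b))

    psi_ab = digamma(a + b)
    psi_nab = digamma(n + a + b)
    dla = digamma(k + a) - psi_nab - digamma(a) + psi_ab
    dlb = digamma(n - k + b) - psi_nab - digamma(b) + psi_ab
    d_eta1 = (dla - dlb) * mu * (1.0 - mu) / sig
    d_eta2 = -(a * dla + b * dlb)
    grad = np.concatenate([-(X_mu.T @ d_eta1), -(X_sigma.T @ d_eta2)])
    return -ll, grad


def _hess_betabin(theta, X_mu, X_sigma, k, n):
    """Analytic Hessian of the negative log-likelihood (trigamma terms)."""
    from scipy.special import polygamma
    p1 = X_mu.shape[1]
    eta1 = np.clip(X_mu @ theta[:p1], -_ETA_MU_MAX, _ETA_MU_MAX)
    eta2 = np.clip(X_sigma @ theta[p1:], -_ETA_SIGMA_MAX, _ETA_SIGMA_MAX)
    mu = expit(eta1)
    sig = np.exp(eta2)
    a = mu / sig
    b = (1.0 - mu) / sig

    psi_ab = digamma(a + b)
    psi_nab = digamma(n + a + b)
    A = digamma(k + a) - psi_nab - digamma(a) + psi_ab
    B = digamma(n - k + b) - psi_nab - digamma(b) + psi_ab
    t_ab = polygamma(1, a + b)
    t_nab = polygamma(1, n + a + b)
    Aa = polygamma(1, k + a) - t_nab - polygamma(1, a) + t_ab
    Ab = t_ab - t_nab
    Bb = polygamma(1, n - k + b) - t_nab - polygamma(1, b) + t_ab

    m1 = mu * (1.0 - mu) / sig
    d11 = (Aa - 2.0 * Ab + Bb) * m1 ** 2 + (A - B) * m1 * (1.0 - 2.0 * mu)
    d12 = -m1 * (a * Aa + b * Ab - a * Ab - b * Bb + (A - B))
    d22 = a * A + b * B + a ** 2 * Aa + 2.0 * a * b * Ab + b ** 2 * Bb

    H11 = X_mu.T @ (X_mu * (-d11)[:, None])
    H12 = X_mu.T @ (X_sigma * (-d12)[:, None])
    H22 = X_sigma.T @ (X_sigma * (-d22)[:, None])
    return np.block([[H11, H12], [H12.T, H22]])


def _hess_binom(theta, X_mu, k, n):
    eta = np.clip(X_mu @ theta, -_ETA_MU_MAX, _ETA_MU_MAX)
    mu = expit(eta)
    w = n * mu * (1.0 - mu)
    return X_mu.T @ (X_mu * w[:, None])


def _nll_grad_binom(theta, X_mu, k, n):
    eta = np.clip(X_mu @ theta, -_ETA_MU_MAX, _ETA_MU_MAX)
    mu = expit(eta)
    ll = np.sum(k * eta - n * np.logaddexp(0.0, eta))
    grad = X_mu.T @ (n * mu - k)
    return -ll, grad


@dataclass(frozen=True)
class FitControl:
    """Optimizer settings for the maximum-likelihood fit."""

    maxiter: int = 500
    #: fast-path convergence: infinity norm of the per-observation mean
    #: gradient below this
    gtol_mean: float = 1e-5
    #: main convergence criterion: a full damped-Newton step improves the
    #: negative log-likelihood by less than this (nats)
    decrement_tol: float = 1e-6
    n_starts: int = 3
    jitter: float = 0.4
    polish_iter: int = 30
    seed: int = 0


def _fd_hessian(fun, x, g, h=1e-6):
    """Forward-difference Hessian of the analytic gradient."""
    p = x.size
    H = np.empty((p, p))
    for j in range(p):
        xp = x.copy()
        xp[j] += h
        _, gp = fun(xp)
        H[:, j] = (gp - g) / h
    return (H + H.T) / 2.0


def _polish(fun, hess, x, control: FitControl, n_obs: int):
    """Damped Newton refinement of an L-BFGS-B solution.

    Quasi-Newton alone stalls once objective decrements reach machine
    precision, leaving the gradient above any fixed small tolerance on
    large-count data. A few Newton steps (finite-difference Hessian of the
    analytic gradient) close the gap; convergence is declared when the
    Newton decrement — the second-order estimate of the remaining
    log-likelihood improvement — is negligible, or the mean gradient is
    already tiny. Returns ``(x, converged, hessian)``.
    """
    H = None
    converged = False
    p = x.size
    lam = None
    for _ in range(control.polish_iter):
        f, g = fun(x)
        if not np.isfinite(f):
            return x, False, None
        H = hess(x)
        if not np.all(np.isfinite(H)):
            return x, False, None
        if np.max(np.abs(g)) / n_obs < control.gtol_mean:
            converged = True
            break
        scale = max(1.0, abs(np.trace(H)) / p)
        if lam is None:
            lam = 1e-8 * scale
        # Levenberg damping: grow the ridge until the step is a descent
        # direction (the Hessian can be indefinite in flat regions)
        step = None
        for _ in range(12):
            try:
                cand = np.linalg.solve(H + lam * np.eye(p), -g)
            except np.linalg.LinAlgError:
                lam = max(lam * 10.0, 1e-6 * scale)
                continue
            if g @ cand < 0:
                step = cand
                break
            lam = max(lam * 10.0, 1e-6 * scale)
        if step is None:
            return x, False, H
        t = 1.0
        fn = np.inf
        for _ in range(30):
            fn, _ = fun(x + t * step)
            if np.isfinite(fn) and fn <= f:
                break
            t /= 2.0
        else:
            lam *= 10.0
            continue
        x = x + t * step
        lam = lam / 3.0 if t == 1.0 else lam * 3.0
        if f - fn < control.decrement_tol:
            converged = True
            break
    return x, converged, H


# ---------------------------------------------------------------------------
# model / results


class BetaBinomialGAM:
    """Occurrence model for one call type, statsmodels-style.

    Parameters
    ----------
    data : DataFrame
        Station-month records with columns ``station_id, lon_east, lat,
        month, n_hours, k_hours`` (and optionally ``call_type``, which must
        then be a single value — the two populations are fitted separately).
    structure : ModelStructure
        Likelihood family and predictor complexity.
    """

    def __init__(self, data: pd.DataFrame, structure: ModelStructure | None = None):
        if structure is None:
            structure = ModelStructure()
        if len(data) == 0:
            raise ValueError("empty acoustic data")
        if "call_type" in data.columns and data["call_type"].nunique() > 1:
            raise ValueError(
                "mixed call types; fit each population's model separately")
        k = data["k_hours"].to_numpy(dtype=float)
        n = data["n_hours"].to_numpy(dtype=float)
        if np.any(k < 0) or np.any(k > n):
            raise ValueError("require 0 <= k_hours <= n_hours")
        if n.sum() <= 0:
            raise ValueError("no analyzed hours in data")
        self.data = data.reset_index(drop=True)
        self.structure = structure
        self.k = k
        self.n = n
        self.X_mu, self.X_sigma, self.info = build_design(self.data, structure)

    @classmethod
    def from_dataframe(cls, data, structure=None):
        return cls(data, structure)

    @property
    def df_model(self) -> int:
        return self.X_mu.shape[1] + (
            0 if self.X_sigma is None else self.X_sigma.shape[1])

    def _start(self) -> np.ndarray:
        pbar = float(np.clip(self.k.sum() / self.n.sum(), 1e-4, 1 - 1e-4))
        beta_mu = np.zeros(self.X_mu.shape[1])
        beta_mu[0] = logit(pbar)
        if self.X_sigma is None:
            return beta_mu
        beta_sigma = np.zeros(self.X_sigma.shape[1])
        beta_sigma[0] = np.log(0.1)
        return np.concatenate([beta_mu, beta_sigma])

    def loglik(self, theta: np.ndarray) -> float:
        if self.X_sigma is None:
            nll, _ = _nll_grad_binom(theta, self.X_mu, self.k, self.n)
        else:
            nll, _ = _nll_grad_betabin(theta, self.X_mu, self.X_sigma,
                                       self.k, self.n)
        return -nll - self._const()

    def _const(self) -> float:
        # binomial coefficient terms, free of parameters
        return -float(np.sum(gammaln(self.n + 1) - gammaln(self.k + 1)
                             - gammaln(self.n - self.k + 1)))

    def fit(self, control: FitControl | None = None,
            start_params: np.ndarray | None = None) -> "BetaBinomialGAMResults":
        """Maximize the likelihood; never raises on optimizer failure.

        Multi-start quasi-Newton from the empirical-logit start (or
        ``start_params``, e.g. a previous fit's coefficients when refitting
        to resampled data) plus jittered copies, followed by damped-Newton
        polishing. The best solution wins; failure to meet the convergence
        criteria sets ``converged=False`` rather than raising.
        """
        control = control or FitControl()
        if self.X_sigma is None:
            fun = lambda th: _nll_grad_binom(th, self.X_mu, self.k, self.n)
            hess = lambda th: _hess_binom(th, self.X_mu, self.k, self.n)
        else:
            fun = lambda th: _nll_grad_betabin(
                th, self.X_mu, self.X_sigma, self.k, self.n)
            hess = lambda th: _hess_betabin(
                th, self.X_mu, self.X_sigma, self.k, self.n)

        n_obs = len(self.data)
        rng = np.random.default_rng(control.seed)
        base = self._start()
        if start_params is not None and start_params.size == base.size:
            base = np.asarray(start_params, dtype=float)
        starts = [base]
        for _ in range(control.n_starts - 1):
            starts.append(base + rng.normal(0.0, control.jitter, base.size))

        best_x, best_f = None, np.inf
        for x0 in starts:
            res = minimize(
                fun, x0, jac=True, method="L-BFGS-B",
                options={"maxiter": control.maxiter,
                         "maxfun": 10 * control.maxiter,
                         "ftol": 1e-13, "gtol": 1e-9},
            )
            if np.isfinite(res.fun) and res.fun < best_f:
                best_x, best_f = res.x, res.fun
        if best_x is None:
            theta, converged, H = self._start(), False, None
        else:
            theta, converged, H = _polish(fun, hess, best_x, control, n_obs)
        p1 = self.X_mu.shape[1]
        beta_mu = theta[:p1]
        beta_sigma = theta[p1:] if self.X_sigma is not None else np.empty(0)
        fitted_mu = expit(np.clip(self.X_mu @ beta_mu, -_ETA_MU_MAX, _ETA_MU_MAX))
        if fitted_mu.max() < 1e-4 or fitted_mu.min() > 1 - 1e-4:
            # all-presence / all-absence data push mu to the boundary where
            # the MLE is degenerate; flag rather than trust the fit
            warnings.warn("fitted occurrence probability at the boundary; "
                          "flagging fit as non-converged", stacklevel=2)
            converged = False

        nll, _ = fun(theta)
        loglik = -nll + self._const()
        df = self.df_model
        try:
            crit = aicc(loglik, df, n_obs)
        except ValueError:
            crit = np.nan
            converged = False
        bse = None
        if H is not None:
            with np.errstate(all="ignore"):
                try:
                    cov = np.linalg.inv(H)
                    diag = np.diag(cov)
                    bse = np.sqrt(np.where(diag > 0, diag, np.nan))
                except np.linalg.LinAlgError:
                    bse = None
        return BetaBinomialGAMResults(
            model=self, structure=self.structure, info=self.info,
            beta_mu=beta_mu, beta_sigma=beta_sigma, loglik=float(loglik),
            df_model=df, n_obs=n_obs, aicc=float(crit),
            converged=bool(converged), bse=bse, seed=control.seed)


@dataclass
class BetaBinomialGAMResults:
    """Fitted occurrence model: coefficients on the link scales plus fit
    diagnostics. Prediction rebuilds the stored spline bases, so results
    round-trip through JSON without the original data."""

    structure: ModelStructure
    info: DesignInfo
    beta_mu: np.ndarray
    beta_sigma: np.ndarray
    loglik: float
    df_model: int
    n_obs: int
    aicc: float
    converged: bool
    #: standard errors of the stacked (beta_mu, beta_sigma) coefficients
    #: from the inverse observed information, when available
    bse: np.ndarray | None = None
    seed: int = 0
    model: BetaBinomialGAM | None = None

    def predict_mu(self, lon_east, lat, month, return_extrapolation=False):
        """Probability of at least one call in an hour at (lon, lat, month).

        Spline bases extend linearly beyond their boundary knots; set
        ``return_extrapolation=True`` to also get a boolean mask marking
        points outside the knot ranges.
        """
        X = self.info.param_design(lon_east, lat, month, "mu")
        mu = expit(np.clip(X @ self.beta_mu, -_ETA_MU_MAX, _ETA_MU_MAX))
        mu = mu if np.asarray(lon_east).ndim else float(mu[0])
        if return_extrapolation:
            extra = self.info.is_extrapolation(lon_east, lat)
            return mu, (extra if np.asarray(lon_east).ndim else bool(extra[0]))
        return mu

    def predict_sigma(self, lon_east, lat, month):
        if self.structure.sigma_terms == "none":
            z = np.zeros(np.atleast_1d(np.asarray(lon_east)).shape)
            return z if np.asarray(lon_east).ndim else 0.0
        X = self.info.param_design(lon_east, lat, month, "sigma")
        sig = np.exp(np.clip(X @ self.beta_sigma,
                             -_ETA_SIGMA_MAX, _ETA_SIGMA_MAX))
        return sig if np.asarray(lon_east).ndim else float(sig[0])

    @property
    def fittedvalues(self) -> np.ndarray:
        if self.model is None:
            raise ValueError("fitted values unavailable on a deserialized result")
        return expit(np.clip(self.model.X_mu @ self.beta_mu,
                             -_ETA_MU_MAX, _ETA_MU_MAX))

    def summary(self) -> str:
        lines = [
            "Beta-binomial additive occurrence model"
            if self.structure.family == "beta_binomial"
            else "Binomial additive occurrence model",
            "=" * 55,
            f"Structure:   {self.structure.label}",
            f"N obs:       {self.n_obs}",
            f"df:          {self.df_model}",
            f"Log-lik:     {self.loglik:.3f}",
            f"AICc:        {self.aicc:.3f}",
            f"Converged:   {self.converged}",
            "-" * 55,
            "mu coefficients (logit scale):",
            "  " + np.array2string(self.beta_mu, precision=4),
        ]
        if self.beta_sigma.size:
            lines += ["sigma coefficients (log scale):",
                      "  " + np.array2string(self.beta_sigma, precision=4)]
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        s = self.structure
        i = self.info
        return {
            "structure": {"family": s.family, "mu_terms": s.mu_terms,
                          "sigma_terms": s.sigma_terms,
                          "spline_df": s.spline_df,
                          "month_as_factor": s.month_as_factor},
            "knots_lon": None if i.knots_lon is None else list(i.knots_lon),
            "knots_lat": None if i.knots_lat is None else list(i.knots_lat),
            "lon_center": i.lon_center, "lon_scale": i.lon_scale,
            "lat_center": i.lat_center, "lat_scale": i.lat_scale,
            "month_levels": list(i.month_levels),
            "beta_mu": list(self.beta_mu),
            "beta_sigma": list(self.beta_sigma),
            "loglik": self.loglik, "df": self.df_model, "n_obs": self.n_obs,
            "aicc": self.aicc, "converged": self.converged, "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "BetaBinomialGAMResults":
        structure = ModelStructure(**d["structure"])
        info = DesignInfo(
            structure,
            None if d["knots_lon"] is None else np.asarray(d["knots_lon"]),
            None if d["knots_lat"] is None else np.asarray(d["knots_lat"]),
            d["lon_center"], d["lon_scale"], d["lat_center"], d["lat_scale"],
            [int(m) for m in d["month_levels"]])
        return cls(structure=structure, info=info,
                   beta_mu=np.asarray(d["beta_mu"]),
                   beta_sigma=np.asarray(d["beta_sigma"]),
                   loglik=d["loglik"], df_model=d["df"], n_obs=d["n_obs"],
                   aicc=d["aicc"], converged=d["converged"],
                   seed=d.get("seed", 0))

    @classmethod
    def from_json(cls, path) -> "BetaBinomialGAMResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _failed_result(structure: ModelStructure, n_obs: int,
                   seed: int) -> BetaBinomialGAMResults:
    info = DesignInfo(structure, None, None, 0.0, 1.0, 0.0, 1.0, [1])
    return BetaBinomialGAMResults(
        structure=structure, info=info, beta_mu=np.empty(0),
        beta_sigma=np.empty(0), loglik=np.nan, df_model=0, n_obs=n_obs,
        aicc=np.nan, converged=False, seed=seed)


def fit_occurrence_model(data: pd.DataFrame,
                         structure: ModelStructure | None = None,
                         control: FitControl | None = None):
    """Convenience wrapper: construct the model and fit it."""
    return BetaBinomialGAM(data, structure).fit(control)


def select_model(data: pd.DataFrame,
                 candidates: list[ModelStructure] | None = None,
                 control: FitControl | None = None,
                 return_fits: bool = False):
    """Fit candidate structures and rank them by AICc.

    Returns a table sorted by AICc with a ``delta_aicc`` column relative to
    the best converged candidate; non-converged candidates sort last.
    """
    if candidates is None:
        candidates = TABLE_CANDIDATES
    if len(candidates) == 0:
        raise ValueError("no candidate structures")
    rows = []
    fits = []
    for cand in candidates:
        try:
            fit = BetaBinomialGAM(data, cand).fit(control)
        except ValueError:
            fit = _failed_result(cand, len(data), 0)
        fits.append(fit)
        rows.append({"structure": cand.label, "family": cand.family,
                     "mu_terms": cand.mu_terms, "sigma_terms": cand.sigma_terms,
                     "df": fit.df_model if fit.df_model else np.nan,
                     "loglik": fit.loglik, "aicc": fit.aicc,
                     "converged": fit.converged})
    table = pd.DataFrame(rows)
    conv = table[table["converged"]]
    if len(conv) == 0:
        raise RuntimeError("no candidate structure converged")
    best = conv["aicc"].min()
    table["delta_aicc"] = table["aicc"] - best
    table = table.sort_values(
        ["converged", "aicc"], ascending=[False, True]).reset_index(drop=True)
    if return_fits:
        return table, fits
    return table


def bootstrap_refit(data: pd.DataFrame, structure: ModelStructure,
                    rng_seed: int,
                    control: FitControl | None = None,
                    start_params: np.ndarray | None = None,
                    ) -> BetaBinomialGAMResults:
    """Refit after resampling station-month rows with replacement.

    Resamples to the original row count; degenerate resamples (too few
    distinct covariate values for the spline basis, boundary fits) come
    back with ``converged=False`` rather than raising.
    """
    if len(data) == 0:
        raise ValueError("empty acoustic data")
    rng = np.random.default_rng(rng_seed)
    idx = rng.integers(0, len(data), len(data))
    resampled = data.iloc[idx].reset_index(drop=True)
    control = control or FitControl()
    control = replace(control, seed=int(rng.integers(0, 2**31 - 1)))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return BetaBinomialGAM(resampled, structure).fit(
                control, start_params=start_params)
    except ValueError:
        return _failed_result(structure, len(resampled), control.seed)
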