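"""Whole-genome regression models.

``fit_rrblup`` maximizes the restricted likelihood of
``y = 1 mu + M alpha + e`` with ``alpha ~ N(0, sigma2_a I)`` through a
spectral decomposition of the genomic kernel ``K = M M'`` (efficient when
markers far outnumber lines) and returns BLUP marker effects.  This marker
formulation is algebraically identical to GBLUP with kernel ``K`` and the
same variance components.

``fit_bayesian`` dispatches to one single-site Gibbs sampler covering the
Bayesian alphabet (Bayes RR, A, B, Cpi, Lasso).  Prior hyperparameters
default to the usual rule of thumb: scales chosen so the implied marker
variance mass corresponds to half the phenotypic variance, nu = 5 for the
scaled-t slabs, Beta(5, 5) for the mixture probability, Gamma(1.1, rate
matched to the data) for the Lasso rate; everything is overridable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _gibbs
from .dosage import DosageMatrix

MODELS = ("RRBLUP", "BayesA", "BayesB", "BayesCpi", "BayesLasso", "BayesRR")
_MODEL_CODE = {"BayesRR": _gibbs.MODEL_RR, "BayesA": _gibbs.MODEL_A,
               "BayesB": _gibbs.MODEL_B, "BayesCpi": _gibbs.MODEL_CPI,
               "BayesLasso": _gibbs.MODEL_LASSO}


@dataclass
class GsModelSpec:
    """Model choice plus chain settings and prior hyperparameters."""

    model: str = "RRBLUP"
    n_iter: int = 40_000
    burn_in: int = 20_000
    thin: int = 1
    seed: int = 0
    nu: float = 5.0            # df of the scaled-inv-chi2 marker-variance prior
    nu_e: float = 5.0          # df of the residual-variance prior
    r2_prior: float = 0.5      # fraction of var(y) assigned to markers a priori
    scale: Optional[float] = None       # marker-variance prior scale S (auto)
    scale_e: Optional[float] = None     # residual prior scale (auto)
    pi0: float = 0.5           # prior mean of the spike probability
    pi_prior_count: float = 10.0
    fix_pi: Optional[float] = None      # fix the spike probability (B / Cpi)
    lasso_shape: float = 1.1
    lasso_rate: Optional[float] = None  # auto-tuned to the data when None
    fix_sigma2_e: Optional[float] = None
    fix_sigma2_a: Optional[float] = None

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.nu <= 0 or self.nu_e <= 0 or self.lasso_shape <= 0:
            raise ValueError("hyperparameters must be positive")


@dataclass
class MarkerEffectSet:
    """Intercept + per-marker effects from one fitted GS model."""

    model: str
    mu: float
    effects: np.ndarray
    marker_ids: Optional[list] = None
    sigma2_e: float = np.nan
    sigma2_alpha: float = np.nan
    pip: Optional[np.ndarray] = None   # posterior inclusion probability
    pi: Optional[float] = None         # posterior mean spike probability
    boundary: bool = False             # variance ratio hit the search boundary
    spec: Optional[GsModelSpec] = None

    def __post_init__(self):
        self.effects = np.asarray(self.effects, dtype=float)
        if self.pip is not None and (np.any(self.pip < 0) or np.any(self.pip > 1)):
            raise ValueError("inclusion probabilities must be in [0, 1]")


def _as_matrix(M):
    if isinstance(M, DosageMatrix):
        M.require_state("final")
        return M.values.astype(float), M.markers["id"].tolist()
    M = np.asarray(M, dtype=float)
    return M, None


# ---------------------------------------------------------------------------
# RRBLUP
# ---------------------------------------------------------------------------

def fit_rrblup(M, y, bounds=(-12.0, 12.0)) -> MarkerEffectSet:
    """REML ridge regression of phenotypes on markers.

    The variance ratio ``lambda = sigma2_e / sigma2_a`` is profiled on the
    eigenbasis of ``K = M M'``; marker effects are the BLUPs
    ``alpha = M'(K + lambda I)^(-1) (y - 1 mu)``.  A constant response is a
    boundary case: effects are all zero and the result is flagged.
    """
    from scipy.optimize import minimize_scalar

    X, marker_ids = _as_matrix(M)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y length does not match rows of M")
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(y)):
        raise ValueError("missing or non-finite entries")

    if np.var(y) < 1e-14:
        return MarkerEffectSet(model="RRBLUP", mu=float(y.mean()),
                               effects=np.zeros(p), marker_ids=marker_ids,
                               sigma2_e=0.0, sigma2_alpha=0.0, boundary=True)

    K = X @ X.T
    S, U = np.linalg.eigh(K)
    S = np.maximum(S, 0.0)
    ones = np.ones((n, 1))
    ystar = U.T @ y
    Xstar = U.T @ ones

    def negll(log_lam):
        lam = np.exp(log_lam)
        d = S + lam
        Xd = Xstar / d[:, None]
        XtViX = Xstar.T @ Xd
        beta = np.linalg.solve(XtViX, Xd.T @ ystar)
        r = ystar - Xstar @ beta
        quad = float(np.sum(r * r / d))
        s2u = quad / (n - 1)
        ll = -0.5 * ((n - 1) * (np.log(2 * np.pi * s2u) + 1)
                     + np.sum(np.log(d)) + np.linalg.slogdet(XtViX)[1])
        return -ll

    res = minimize_scalar(negll, bounds=bounds, method="bounded",
                          options={"xatol": 1e-10})
    log_lam = float(res.x)
    lam = np.exp(log_lam)
    boundary = min(log_lam - bounds[0], bounds[1] - log_lam) < 1e-6

    d = S + lam
    Xd = Xstar / d[:, None]
    XtViX = Xstar.T @ Xd
    beta = np.linalg.solve(XtViX, Xd.T @ ystar)
    r = ystar - Xstar @ beta
    s2u = float(np.sum(r * r / d)) / (n - 1)
    s2e = lam * s2u
    alpha = X.T @ (U @ (r / d))
    return MarkerEffectSet(model="RRBLUP", mu=float(beta[0]), effects=alpha,
                           marker_ids=marker_ids, sigma2_e=s2e,
                           sigma2_alpha=s2u, boundary=boundary)


# ---------------------------------------------------------------------------
# Bayesian alphabet
# ---------------------------------------------------------------------------

def fit_bayesian(M, y, spec: GsModelSpec) -> MarkerEffectSet:
    """Fit one Bayesian-alphabet model by single-site Gibbs sampling.

    Posterior means over post-burn-in (thinned) samples are returned.  A
    chain reaching a non-finite state raises with the iteration index.
    """
    if spec.model == "RRBLUP":
        raise ValueError("use fit_rrblup for the RRBLUP model")
    X, marker_ids = _as_matrix(M)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y length does not match rows of M")

    var_y = max(float(np.var(y)), 1e-12)
    sum_var = float(np.sum(np.var(X, axis=0)))
    if sum_var <= 0:
        sum_var = float(p)
    r2 = spec.r2_prior
    nu, nu_e = spec.nu, spec.nu_e

    slab_frac = 1.0
    if spec.model in ("BayesB", "BayesCpi"):
        pi_eff = spec.fix_pi if spec.fix_pi is not None else spec.pi0
        slab_frac = max(1.0 - pi_eff, 0.05)
    S_a = spec.scale
    if S_a is None:
        S_a = r2 * var_y / sum_var * (nu - 2.0) / nu / slab_frac
    S_e = spec.scale_e
    if S_e is None:
        S_e = (1.0 - r2) * var_y * (nu_e - 2.0) / nu_e
    lasso_rate = spec.lasso_rate
    if lasso_rate is None:
        lam2_0 = 2.0 * sum_var * (1.0 - r2) / r2
        lasso_rate = spec.lasso_shape / lam2_0

    pi_is_fixed = spec.fix_pi is not None
    pi_init = spec.fix_pi if pi_is_fixed else spec.pi0
    a_pi = spec.pi_prior_count * spec.pi0
    b_pi = spec.pi_prior_count * (1.0 - spec.pi0)

    out = _gibbs.run_gibbs(
        np.ascontiguousarray(X), y, _MODEL_CODE[spec.model],
        spec.n_iter, spec.burn_in, spec.thin, int(spec.seed) % (2 ** 31),
        nu_e, S_e, nu, S_a, float(pi_init), pi_is_fixed, a_pi, b_pi,
        spec.lasso_shape, lasso_rate,
        spec.fix_sigma2_e is not None, float(spec.fix_sigma2_e or 0.0),
        spec.fix_sigma2_a is not None, float(spec.fix_sigma2_a or 0.0),
    )
    mu_sum, alpha_sum, incl_sum, se_sum, sa_sum, pi_sum, n_keep, bad_it = out
    if bad_it:
        raise RuntimeError(f"Gibbs chain diverged at iteration {bad_it}")
    if n_keep == 0:
        raise RuntimeError("no post-burn-in samples kept")

    pip = incl_sum / n_keep if spec.model in ("BayesB", "BayesCpi") else None
    pi_hat = pi_sum / n_keep if spec.model in ("BayesB", "BayesCpi") else None
    return MarkerEffectSet(
        model=spec.model, mu=mu_sum / n_keep, effects=alpha_sum / n_keep,
        marker_ids=marker_ids, sigma2_e=se_sum / n_keep,
        sigma2_alpha=sa_sum / n_keep, pip=pip, pi=pi_hat, spec=spec)


def fit_gs_model(M, y, spec: GsModelSpec) -> MarkerEffectSet:
    """Dispatch on ``spec.model`` (RRBLUP -> REML, otherwise Gibbs)."""
    if spec.model == "RRBLUP":
        return fit_rrblup(M, y)
    return fit_bayesian(M, y, spec)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_gebv(effects: MarkerEffectSet, M_new) -> np.ndarray:
    """GEBV_i = mu + sum_j m_ij alpha_j for each line of ``M_new``.

    When both the effect set and ``M_new`` carry marker ids, columns are
    aligned by id; ids present in the training set but absent from ``M_new``
    raise an error listing them.
    """
    if isinstance(M_new, DosageMatrix) and effects.marker_ids is not None:
        ids_new = M_new.markers["id"].tolist()
        lookup = {m: i for i, m in enumerate(ids_new)}
        missing = [m for m in effects.marker_ids if m not in lookup]
        if missing:
            raise ValueError(
                f"{len(missing)} training markers absent from prediction set: "
                f"{missing[:5]}{'...' if len(missing) > 5 else ''}")
        order = [lookup[m] for m in effects.marker_ids]
        X = M_new.values[:, order].astype(float)
    else:
        X, _ = _as_matrix(M_new)
        if X.shape[1] != len(effects.effects):
            raise ValueError("marker count mismatch and no ids to align by")
    return effects.mu + X @ effects.effects


def gblup_gebv(M_train, y_train, M_new, sigma2_a: float, sigma2_e: float):
    """GEBVs from the kernel (GBLUP) formulation with given variance
    components: ``g_new = K_new,train (K + lambda I)^(-1) (y - mu)`` with
    ``K = M M'``.  Used as the independent cross-check of the marker
    formulation."""
    X, _ = _as_matrix(M_train)
    Xn, _ = _as_matrix(M_new)
    y = np.asarray(y_train, dtype=float)
    n = X.shape[0]
    lam = sigma2_e / sigma2_a
    K = X @ X.T
    Vinv = np.linalg.inv(K + lam * np.eye(n))
    ones = np.ones(n)
    mu = float(ones @ Vinv @ y / (ones @ Vinv @ ones))
    r = y - mu
    Knew = Xn @ X.T
    return mu + Knew @ (Vinv @ r)
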