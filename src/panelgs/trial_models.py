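"""REML mixed models for lattice field trials.

The model per plot is

    y = mu + beta*stand + gamma*flowering + year + rep(year) + block(rep, year)
        + genotype(+year) + residual

with the year terms dropping out for single-year data.  Random terms
(replicate, block, genotype, residual) accept a variance structure over the
year grouping factor:

* ``ID``   one effect per (level, year), common variance, independent;
* ``DIAG`` as ID but with a separate variance per year;
* ``CS``   compound symmetry, decomposed as a main effect (variance sigma^2_main,
  shared across years) plus an independent (level x year) interaction
  (sigma^2_int) — for the genotype term these are the genetic main-effect and
  genotype-by-year variances;
* ``US``   unstructured year x year covariance (Cholesky-parameterized).

Restricted likelihood is maximized over transformed parameters (log standard
deviations, Cholesky factors) with a quasi-Newton search plus an optional
Nelder-Mead polish; fixed effects come from GLS at the optimum and BLUPs from
the mixed-model equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

STRUCTURES = ("ID", "DIAG", "CS", "US", "OMIT")


@dataclass
class VcovSpec:
    """Variance structure per random term, over the year grouping factor.

    ``OMIT`` drops the replicate or block term entirely (used e.g. for a
    plain one-way genotype/residual model)."""

    genotype: str = "CS"
    rep: str = "ID"
    block: str = "ID"
    residual: str = "ID"

    def __post_init__(self):
        for name in ("genotype", "rep", "block", "residual"):
            s = getattr(self, name)
            if s not in STRUCTURES:
                raise ValueError(f"unknown structure {s!r} for term {name}")
        if self.residual not in ("ID", "DIAG"):
            raise ValueError("residual structure must be ID or DIAG")
        if self.genotype == "OMIT":
            raise ValueError("the genotype term cannot be omitted")

    def label(self) -> str:
        return f"g:{self.genotype}/r:{self.rep}/b:{self.block}/e:{self.residual}"


@dataclass
class FittedTrialModel:
    spec: VcovSpec
    fixed_effects: pd.Series
    varcomps: dict
    random_effects: dict           # term name -> Series indexed by level key
    loglik: float                  # restricted log-likelihood at the optimum
    bic: float
    n_obs: int
    n_varparams: int
    converged: bool
    message: str = ""
    response: str = "trait"
    n_years: int = 1
    n_reps: int = 1
    blup_combination: str = "main"  # how per-genotype BLUPs were combined


# ---------------------------------------------------------------------------
# random-term machinery
# ---------------------------------------------------------------------------

class _Term:
    """One random term: incidence matrix Z plus a parameterized covariance."""

    def __init__(self, name, structure, base_keys, years, obs_base, obs_year):
        self.name = name
        self.structure = structure
        self.base_keys = list(base_keys)     # distinct base levels
        self.years = list(years)             # distinct years (sorted)
        m = len(self.years)
        if structure in ("CS", "US") and m < 2:
            raise ValueError(
                f"structure {structure} for term {name} requires >= 2 years")
        nb, ny = len(self.base_keys), m
        base_ix = {k: i for i, k in enumerate(self.base_keys)}
        year_ix = {y: i for i, y in enumerate(self.years)}
        n = len(obs_base)
        # levels ordered year-major within base: level = base*ny + year
        self.level_of_obs = np.array(
            [base_ix[b] * ny + year_ix[y] for b, y in zip(obs_base, obs_year)])
        self.q = nb * ny
        self.Z = np.zeros((n, self.q))
        self.Z[np.arange(n), self.level_of_obs] = 1.0
        self.obs_year_ix = np.array([year_ix[y] for y in obs_year])
        # main-effect incidence for the CS decomposition
        if structure == "CS":
            self.Zmain = np.zeros((n, nb))
            self.Zmain[np.arange(n), [base_ix[b] for b in obs_base]] = 1.0

    @property
    def n_params(self) -> int:
        m = len(self.years)
        return {"ID": 1, "DIAG": m, "CS": 2, "US": m * (m + 1) // 2}[self.structure]

    def init_params(self, var0: float) -> np.ndarray:
        s = 0.5 * np.log(var0)
        if self.structure == "US":
            m = len(self.years)
            out = np.zeros(self.n_params)
            out[:m] = s  # log sds on the Cholesky diagonal
            return out
        return np.full(self.n_params, s)

    def contribution(self, theta: np.ndarray) -> np.ndarray:
        """Z G Z' for this term at parameters theta."""
        m = len(self.years)
        nb = len(self.base_keys)
        if self.structure == "ID":
            v = np.exp(2 * theta[0])
            return v * (self.Z @ self.Z.T)
        if self.structure == "DIAG":
            vy = np.exp(2 * theta)           # per-year variance
            d = vy[np.arange(self.q) % m]    # level variance by its year
            return (self.Z * d) @ self.Z.T
        if self.structure == "CS":
            v_main, v_int = np.exp(2 * theta[0]), np.exp(2 * theta[1])
            return v_main * (self.Zmain @ self.Zmain.T) + v_int * (self.Z @ self.Z.T)
        # US: K = L L' from Cholesky params, G = I_nb (x) K
        L = self._chol(theta)
        K = L @ L.T
        big = np.kron(np.eye(nb), K)
        return self.Z @ big @ self.Z.T

    def _chol(self, theta):
        m = len(self.years)
        L = np.zeros((m, m))
        L[np.diag_indices(m)] = np.exp(theta[:m])
        if m > 1:
            L[np.tril_indices(m, -1)] = theta[m:]
        return L

    def varcomps(self, theta) -> dict:
        m = len(self.years)
        if self.structure == "ID":
            return {"variance": float(np.exp(2 * theta[0]))}
        if self.structure == "DIAG":
            return {f"variance_year{y}": float(np.exp(2 * theta[i]))
                    for i, y in enumerate(self.years)}
        if self.structure == "CS":
            return {"variance_main": float(np.exp(2 * theta[0])),
                    "variance_interaction": float(np.exp(2 * theta[1]))}
        L = self._chol(theta)
        K = L @ L.T
        return {"covariance_years": K}

    def blups(self, theta, ZtVinv_r) -> pd.Series:
        """G Z' V^-1 r for this term; index = level keys."""
        m = len(self.years)
        nb = len(self.base_keys)
        if self.structure == "CS":
            v_main, v_int = np.exp(2 * theta[0]), np.exp(2 * theta[1])
            u_main = v_main * (self.Zmain.T @ ZtVinv_r)
            u_int = v_int * (self.Z.T @ ZtVinv_r)
            idx_main = pd.Index(self.base_keys, name="level")
            out = {"main": pd.Series(u_main, index=idx_main)}
            idx = pd.MultiIndex.from_tuples(
                [(b, y) for b in self.base_keys for y in self.years],
                names=["level", "year"])
            out["interaction"] = pd.Series(u_int, index=idx)
            return out
        Zt_r = self.Z.T @ ZtVinv_r
        if self.structure == "ID":
            u = np.exp(2 * theta[0]) * Zt_r
        elif self.structure == "DIAG":
            vy = np.exp(2 * theta)
            u = vy[np.arange(self.q) % m] * Zt_r
        else:
            L = self._chol(theta)
            K = L @ L.T
            u = (np.kron(np.eye(nb), K)) @ Zt_r
        idx = pd.MultiIndex.from_tuples(
            [(b, y) for b in self.base_keys for y in self.years],
            names=["level", "year"])
        return {"levels": pd.Series(u, index=idx)}


def _build_terms(df, spec, years):
    obs_year = df["year"].tolist()
    terms = []
    if spec.rep != "OMIT":
        rep_keys = sorted(df["rep"].unique())
        terms.append(_Term("rep", spec.rep, rep_keys, years,
                           df["rep"].tolist(), obs_year))
    if spec.block != "OMIT":
        blk = list(zip(df["rep"], df["block"]))
        blk_keys = sorted(set(blk))
        terms.append(_Term("block", spec.block, blk_keys, years, blk, obs_year))
    geno_keys = sorted(df["genotype"].unique())
    terms.append(_Term("genotype", spec.genotype, geno_keys, years,
                       df["genotype"].tolist(), obs_year))
    return terms


def _fixed_design(df, years, use_flowering_covariate, use_stand_covariate):
    cols = {"intercept": np.ones(len(df))}
    if use_stand_covariate:
        cols["stand"] = df["stand"].to_numpy(float)
    if use_flowering_covariate:
        cols["flowering"] = df["flowering"].to_numpy(float)
    for y in years[1:]:
        cols[f"year_{y}"] = (df["year"] == y).to_numpy(float)
    # a constant covariate (e.g. uniform crop stand) is collinear with the
    # intercept; drop it rather than let X lose rank
    for name in [n for n in cols if n != "intercept"]:
        if np.ptp(cols[name]) == 0:
            del cols[name]
    X = np.column_stack(list(cols.values()))
    return X, list(cols)


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def _restricted_loglik(theta, terms, resid_struct, obs_year_ix, n_years,
                       X, y, split):
    n, p = X.shape
    V = np.zeros((n, n))
    for t, sl in zip(terms, split):
        V += t.contribution(theta[sl])
    et = theta[split[-1].stop:]
    if resid_struct == "ID":
        ve = np.exp(2 * et[0]) * np.ones(n)
    else:
        vy = np.exp(2 * et)
        ve = vy[obs_year_ix]
    V[np.diag_indices(n)] += ve
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -1e12, None
    logdetV = 2 * np.sum(np.log(np.diag(L)))
    Vi_X = np.linalg.solve(L.T, np.linalg.solve(L, X))
    Vi_y = np.linalg.solve(L.T, np.linalg.solve(L, y))
    XtViX = X.T @ Vi_X
    sign, logdetX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -1e12, None
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    Vi_r = np.linalg.solve(L.T, np.linalg.solve(L, r))
    quad = float(r @ Vi_r)
    ll = -0.5 * ((n - p) * np.log(2 * np.pi) + logdetV + logdetX + quad)
    return ll, (beta, Vi_r, XtViX)


def fit_reml(data: pd.DataFrame, spec: VcovSpec = None, response: str = "trait",
             use_flowering_covariate: bool = True, use_stand_covariate: bool = True,
             polish: bool = True, max_iter: int = 500,
             tol: float = 1e-8) -> FittedTrialModel:
    """Fit the lattice mixed model by REML under the given variance spec.

    ``data`` is long-format with columns genotype, year, rep, block, stand,
    flowering and the response.  The flowering covariate must be switched off
    when the response *is* days to flowering.  Non-convergence is flagged on
    the result, never silent.
    """
    required = {"genotype", "year", "rep", "block", "stand", response}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if use_flowering_covariate and "flowering" not in data.columns:
        raise ValueError("flowering covariate requested but column absent")
    df = data.reset_index(drop=True)
    years = sorted(df["year"].unique())
    if spec is None:
        spec = VcovSpec(genotype="CS" if len(years) > 1 else "ID")

    y = df[response].to_numpy(float)
    X, fixed_names = _fixed_design(df, years, use_flowering_covariate,
                                   use_stand_covariate)
    terms = _build_terms(df, spec, years)

    # parameter layout
    split, start = [], 0
    for t in terms:
        split.append(slice(start, start + t.n_params))
        start += t.n_params
    n_resid = 1 if spec.residual == "ID" else len(years)
    n_par = start + n_resid
    year_ix = pd.Categorical(df["year"], categories=years).codes

    var0 = max(np.var(y), 1e-6) / (len(terms) + 1)
    theta0 = np.empty(n_par)
    for t, sl in zip(terms, split):
        theta0[sl] = t.init_params(var0)
    theta0[start:] = 0.5 * np.log(var0)

    def negll(theta):
        ll, _ = _restricted_loglik(theta, terms, spec.residual, year_ix,
                                   len(years), X, y, split)
        return -ll

    bounds = [(-8.0, 8.0)] * n_par
    for t, sl in zip(terms, split):
        if t.structure == "US":
            m = len(t.years)
            for k in range(sl.start + m, sl.stop):
                bounds[k] = (-50.0, 50.0)  # off-diagonal Cholesky entries

    res = optimize.minimize(negll, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": max_iter, "ftol": 1e-12,
                                     "gtol": 1e-10})
    theta, best = res.x, res.fun
    converged, message = bool(res.success), str(res.message)
    if polish:
        res2 = optimize.minimize(negll, theta, method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": 1e-13,
                                          "maxiter": 20000, "maxfev": 20000})
        if res2.fun <= best + tol:
            theta, best = res2.x, res2.fun
            converged = converged or bool(res2.success)

    ll, aux = _restricted_loglik(theta, terms, spec.residual, year_ix,
                                 len(years), X, y, split)
    if aux is None:
        raise RuntimeError("restricted likelihood not finite at the optimum")
    beta, Vi_r, _ = aux

    varcomps = {}
    random_effects = {}
    for t, sl in zip(terms, split):
        varcomps[t.name] = t.varcomps(theta[sl])
        random_effects[t.name] = t.blups(theta[sl], Vi_r)
    et = theta[start:]
    if spec.residual == "ID":
        varcomps["residual"] = {"variance": float(np.exp(2 * et[0]))}
    else:
        varcomps["residual"] = {f"variance_year{yv}": float(np.exp(2 * et[i]))
                                for i, yv in enumerate(years)}

    n_obs = len(df)
    bic = -2 * ll + n_par * np.log(n_obs)
    model = FittedTrialModel(
        spec=spec,
        fixed_effects=pd.Series(beta, index=fixed_names),
        varcomps=varcomps,
        random_effects=random_effects,
        loglik=float(ll),
        bic=float(bic),
        n_obs=n_obs,
        n_varparams=n_par,
        converged=converged,
        message=message,
        response=response,
        n_years=len(years),
        n_reps=df.groupby("year")["rep"].nunique().max(),
    )
    return model


def select_vcov_by_bic(data: pd.DataFrame, candidate_specs, response="trait",
                       use_flowering_covariate: bool = True,
                       stage: str = "random_terms", polish: bool = False):
    """Fit every candidate VcovSpec and pick the smallest BIC.

    All candidates share the same fixed effects by construction (the fixed
    part is set by ``use_flowering_covariate``, not by the spec), which keeps
    REML likelihoods comparable.  Ties go to the candidate with fewer
    variance parameters.  Returns ``(best model, BIC table)``.
    """
    if not candidate_specs:
        raise ValueError("no candidate specs")
    fits, rows = [], []
    for cand in candidate_specs:
        m = fit_reml(data, cand, response=response,
                     use_flowering_covariate=use_flowering_covariate,
                     polish=polish)
        fits.append(m)
        rows.append((cand.label(), stage, m.n_varparams, m.loglik, m.bic,
                     m.converged))
    table = pd.DataFrame(rows, columns=["spec", "stage", "n_varparams",
                                        "loglik", "bic", "converged"])
    order = sorted(range(len(fits)),
                   key=lambda i: (round(fits[i].bic, 10), fits[i].n_varparams))
    return fits[order[0]], table


# ---------------------------------------------------------------------------
# heritability and BLUPs
# ---------------------------------------------------------------------------

def heritability_multi_year(sigma2_g, sigma2_ga, sigma2_e, n_r, m) -> float:
    """Entry-mean heritability for multi-year trials:
    h2 = sg2 / (sg2 + sga2/m + se2/(n_r m))."""
    if min(sigma2_g, sigma2_ga, sigma2_e) < 0:
        raise ValueError("variance components must be non-negative")
    if n_r < 1 or m < 1:
        raise ValueError("n_r and m must be >= 1")
    denom = sigma2_g + sigma2_ga / m + sigma2_e / (n_r * m)
    if denom == 0:
        raise ValueError("all variance components are zero")
    return sigma2_g / denom


def heritability_single_year(sigma2_g, sigma2_e, n_r) -> float:
    """Entry-mean heritability for single-year trials:
    h2 = sg2 / (sg2 + se2/n_r)."""
    if min(sigma2_g, sigma2_e) < 0:
        raise ValueError("variance components must be non-negative")
    if n_r < 1:
        raise ValueError("n_r must be >= 1")
    denom = sigma2_g + sigma2_e / n_r
    if denom == 0:
        raise ValueError("variance components are all zero")
    return sigma2_g / denom


def genotype_blups(model: FittedTrialModel) -> pd.DataFrame:
    """One breeding value per genotype from a fitted model.

    Under a CS genotype structure this is the across-year main effect; under
    ID with one year, the per-genotype effect; under ID/DIAG/US with several
    years, the arithmetic mean of the per-year genotype BLUPs (recorded in
    ``blup_combination``)."""
    if not model.converged:
        raise ValueError("model did not converge; BLUPs unreliable")
    eff = model.random_effects["genotype"]
    if "main" in eff:
        s = eff["main"]
        model.blup_combination = "cs_main_effect"
    else:
        per_level = eff["levels"]
        s = per_level.groupby(level="level").mean()
        model.blup_combination = ("per_genotype" if model.n_years == 1
                                  else "mean_of_per_year_blups")
    out = pd.DataFrame({"genotype": s.index, "blup": s.to_numpy()})
    return out.reset_index(drop=True)
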