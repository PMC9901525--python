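"""Mixed-model battery linking migration timing to performance and weather.

Gaussian linear mixed models (REML, crossed random intercepts for bird and
year, optionally logger type) are fitted through statsmodels' variance-
components formulation; fixed effects are tested with Wald z statistics
(equivalent, for single-df terms, to the Wald chi-square convention of the R
``car`` package) and summarised with the Nakagawa-Schielzeth marginal and
conditional pseudo-R².

Route straightness lives in (0, 1] and is modelled with a beta-distribution
GLMM (logit link).  No installed Python package offers a beta GLMM, so it is
implemented here directly: random intercepts are integrated out with a
Laplace approximation (Fisher-scoring inner loop for the conditional modes,
quasi-Newton outer optimisation over fixed effects, log precision and log
random-effect SDs).  Pseudo-R² is not defined for this family and is
reported as missing.

Multicollinearity among fixed main effects is screened with variance
inflation factors, flagged at VIF >= 2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools.numdiff import approx_hess1

logger = logging.getLogger(__name__)

VIF_WARN = 2.0


# ------------------------------------------------------------------ utilities

def scale_dates(dates) -> tuple[np.ndarray, tuple[float, float]]:
    """Centre and scale Julian days to zero mean, unit (sample) SD.

    Returns the scaled covariate and the (mean, SD) used, so the transform
    can be inverted; scaling is per fitted dataset (per leg).  Raises on
    fewer than two distinct dates (zero SD).
    """
    d = np.asarray(dates, dtype=float)
    mu = d.mean()
    sd = d.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot scale dates with zero standard deviation")
    return (d - mu) / sd, (float(mu), float(sd))


def _design(data: pd.DataFrame, fixed: list[str]) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects design matrix with intercept; adult is the age reference."""
    cols = [np.ones(len(data))]
    names = ["Intercept"]
    for term in fixed:
        if term == "age":
            cols.append((data["age"].astype(str) == "juvenile").to_numpy(dtype=float))
            names.append("Age (juv.)")
        elif ":" in term:
            a, b = term.split(":")
            cols.append(_numeric(data, a) * _numeric(data, b))
            names.append(term)
        else:
            cols.append(_numeric(data, term))
            names.append(term)
    return np.column_stack(cols), names


def _numeric(data: pd.DataFrame, term: str) -> np.ndarray:
    if term == "age":
        return (data["age"].astype(str) == "juvenile").to_numpy(dtype=float)
    return data[term].to_numpy(dtype=float)


def vif(data: pd.DataFrame, fixed: list[str]) -> dict[str, float]:
    """Variance inflation factor per fixed main effect (interactions excluded).

    Computed from auxiliary regressions among the mains with an intercept.
    Perfectly collinear covariates yield ``inf``.  A warning is logged when
    any VIF >= 2, the screening threshold used for model acceptance.
    """
    mains = [t for t in fixed if ":" not in t]
    if len(mains) < 2:
        return {t: 1.0 for t in mains}
    X = np.column_stack([np.ones(len(data))] + [_numeric(data, t) for t in mains])
    out = {}
    for k, term in enumerate(mains, start=1):
        with np.errstate(divide="ignore"):
            try:
                v = float(variance_inflation_factor(X, k))
            except Exception:
                v = float("inf")
        out[term] = v if np.isfinite(v) else float("inf")
    if any(v >= VIF_WARN for v in out.values()):
        logger.warning("VIF >= %.1f detected: %s", VIF_WARN, out)
    return out


@dataclass
class ModelFit:
    """Tidy container for one fitted mixed model."""

    response: str
    family: str  # 'gaussian' | 'beta'
    terms: pd.DataFrame  # term, estimate, se, stat, p
    vcomp: dict[str, float]  # random-intercept variances
    resid_var: float | None  # residual variance (gaussian) or None
    precision: float | None  # beta precision phi or None
    r2_marginal: float | None
    r2_conditional: float | None
    var_fixed: float | None
    vif: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    singular: bool = False
    n: int = 0
    notes: list[str] = field(default_factory=list)

    def coef(self, term: str) -> float:
        row = self.terms[self.terms["term"] == term]
        if len(row) == 0:
            raise KeyError(term)
        return float(row["estimate"].iloc[0])

    def se(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "se"])

    def pvalue(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "p"])


def nakagawa_r2(fit: ModelFit) -> tuple[float | None, float | None]:
    """Nakagawa-Schielzeth marginal and conditional R² of a gaussian LMM.

    marginal = var(fixed) / (var(fixed) + sum(random variances) + residual);
    conditional adds the random variances to the numerator.  Returns
    (None, None) for non-gaussian families, where the decomposition is not
    available.
    """
    if fit.family != "gaussian":
        return (None, None)
    vf = fit.var_fixed or 0.0
    vr = sum(fit.vcomp.values())
    ve = fit.resid_var or 0.0
    tot = vf + vr + ve
    if tot <= 0:
        return (None, None)
    return (vf / tot, (vf + vr) / tot)


def _usable_random(data: pd.DataFrame, random: tuple[str, ...]) -> list[str]:
    keep = []
    for r in random:
        if data[r].nunique() >= 2:
            keep.append(r)
        else:
            logger.warning("random factor %r has < 2 levels; dropped", r)
    return keep


# --------------------------------------------------------------- gaussian LMM

def fit_lmm(data: pd.DataFrame, response: str, fixed: list[str],
            random: tuple[str, ...] = ("bird", "year"),
            reml: bool = True) -> ModelFit:
    """REML gaussian LMM with crossed random intercepts.

    ``fixed`` lists covariate columns ('age' is coded juvenile-vs-adult with
    adult as reference; 'a:b' denotes an interaction).  Random factors with a
    single level are dropped with a warning; singular (zero-variance) fits
    are flagged, not hidden.
    """
    data = data.dropna(subset=[response] + [c for t in fixed for c in t.split(":")])
    X, names = _design(data, fixed)
    y = data[response].to_numpy(dtype=float)
    rand = _usable_random(data, random)
    singular = False
    converged = True
    if rand:
        if len(rand) == 1:
            # one factor: native random-intercept formulation (fast, stable)
            model = MixedLM(y, X, groups=data[rand[0]].astype(str).to_numpy())
        else:
            # crossed factors: single supergroup with one variance component
            # per factor (the lme4-style crossed-intercepts trick)
            exog_vc = {r: pd.get_dummies(data[r].astype(str)).to_numpy(dtype=float)
                       for r in rand}
            from statsmodels.regression.mixed_linear_model import VCSpec
            vcs = VCSpec(
                list(exog_vc),
                [[[f"{r}[{i}]" for i in range(exog_vc[r].shape[1])]] for r in exog_vc],
                [[exog_vc[r]] for r in exog_vc],
            )
            model = MixedLM(y, X, groups=np.zeros(len(data)), exog_vc=vcs)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                res = model.fit(reml=reml)
            except np.linalg.LinAlgError:
                res = model.fit(reml=reml, method=["lbfgs", "powell"])
        msgs = [str(w.message) for w in caught]
        singular = any("singular" in m.lower() or "boundary" in m.lower() for m in msgs)
        converged = bool(getattr(res, "converged", True))
        est = res.fe_params
        se = res.bse_fe.to_numpy() if hasattr(res.bse_fe, "to_numpy") else np.asarray(res.bse_fe)
        if len(rand) == 1:
            vcomp = {rand[0]: float(np.asarray(res.cov_re)[0, 0])}
        else:
            vcomp = {r: float(v) for r, v in zip(rand, res.vcomp)}
        resid = float(res.scale)
    else:
        import statsmodels.api as sm
        res = sm.OLS(y, X).fit()
        est = res.params
        se = res.bse
        vcomp = {}
        resid = float(res.mse_resid)
    est = np.asarray(est, dtype=float)
    se = np.asarray(se, dtype=float)
    z = np.divide(est, se, out=np.full_like(est, np.nan), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    terms = pd.DataFrame({"term": names, "estimate": est, "se": se,
                          "stat": z, "p": p})
    var_fixed = float(np.var(X @ est))
    fit = ModelFit(response=response, family="gaussian", terms=terms,
                   vcomp=vcomp, resid_var=resid, precision=None,
                   r2_marginal=None, r2_conditional=None, var_fixed=var_fixed,
                   vif=vif(data, fixed), converged=converged, singular=singular,
                   n=len(data))
    fit.r2_marginal, fit.r2_conditional = nakagawa_r2(fit)
    if singular:
        fit.notes.append("singular fit: one or more variance components at boundary")
    if not converged:
        fit.notes.append("optimizer did not converge")
    return fit


# ------------------------------------------------------------------ beta GLMM

def _beta_eta_derivs(eta: np.ndarray, y: np.ndarray, phi: float):
    """Log-likelihood, gradient and Fisher weight of a logit-beta model in eta."""
    mu = special.expit(eta)
    mu = np.clip(mu, 1e-10, 1 - 1e-10)
    a = mu * phi
    b = (1 - mu) * phi
    ll = float(np.sum(special.gammaln(phi) - special.gammaln(a) - special.gammaln(b)
                      + (a - 1) * np.log(y) + (b - 1) * np.log1p(-y)))
    m = mu * (1 - mu)
    ystar = np.log(y) - np.log1p(-y)
    mustar = special.digamma(a) - special.digamma(b)
    grad = phi * m * (ystar - mustar)
    w = phi ** 2 * m ** 2 * (special.polygamma(1, a) + special.polygamma(1, b))
    return ll, grad, w


def _laplace_nll(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                 Z: np.ndarray, blocks: list[int]) -> float:
    """Negative Laplace-approximate marginal log-likelihood.

    ``theta`` = [beta, log phi, log sd per random factor]; ``Z`` stacks the
    indicator columns of the random factors, ``blocks`` their column counts.
    """
    p = X.shape[1]
    k = len(blocks)
    beta = theta[:p]
    phi = float(np.exp(theta[p]))
    sds = np.exp(theta[p + 1: p + 1 + k])
    dvar = np.concatenate([np.full(nb, sd ** 2) for nb, sd in zip(blocks, sds)])
    dvar = np.maximum(dvar, 1e-12)
    xb = X @ beta
    b = np.zeros(Z.shape[1])
    pen_ll = -np.inf
    for _ in range(200):  # Fisher scoring for the conditional modes
        eta = xb + Z @ b
        ll, grad, w = _beta_eta_derivs(eta, y, phi)
        g = Z.T @ grad - b / dvar
        H = (Z.T * w) @ Z + np.diag(1.0 / dvar)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return 1e10
        new_pen = ll - 0.5 * np.sum(b ** 2 / dvar)
        # step halving on the penalized objective
        t = 1.0
        for _ in range(30):
            b_try = b + t * step
            eta_try = xb + Z @ b_try
            ll_try, _, _ = _beta_eta_derivs(eta_try, y, phi)
            pen_try = ll_try - 0.5 * np.sum(b_try ** 2 / dvar)
            if pen_try >= new_pen - 1e-12:
                break
            t *= 0.5
        b = b + t * step
        if np.max(np.abs(t * step)) < 1e-10 or abs(pen_try - pen_ll) < 1e-12:
            pen_ll = pen_try
            break
        pen_ll = pen_try
    eta = xb + Z @ b
    ll, _, w = _beta_eta_derivs(eta, y, phi)
    H = (Z.T * w) @ Z + np.diag(1.0 / dvar)
    sign, logdet_h = np.linalg.slogdet(H)
    if sign <= 0:
        return 1e10
    marg = ll - 0.5 * np.sum(b ** 2 / dvar) - 0.5 * np.sum(np.log(dvar)) - 0.5 * logdet_h
    if not np.isfinite(marg):
        return 1e10
    return -marg


def fit_beta_glmm(data: pd.DataFrame, response: str, fixed: list[str],
                  random: tuple[str, ...] = ("bird", "year")) -> ModelFit:
    """Beta GLMM (logit link) with crossed random intercepts via Laplace ML.

    The response must lie strictly in (0, 1); clip boundary values upstream
    (see :func:`storkmig.metrics.straightness`).  Wald z tests on the logit
    scale; pseudo-R² is reported as missing for this family.
    """
    data = data.dropna(subset=[response] + [c for t in fixed for c in t.split(":")])
    y = data[response].to_numpy(dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("beta response must be strictly inside (0, 1); "
                         "clip boundary values before fitting")
    X, names = _design(data, fixed)
    rand = _usable_random(data, random)
    Zs = [pd.get_dummies(data[r].astype(str)).to_numpy(dtype=float) for r in rand]
    Z = np.hstack(Zs) if Zs else np.zeros((len(data), 0))
    blocks = [z.shape[1] for z in Zs]

    # starting values: logit-scale OLS and method-of-moments precision
    ylog = np.log(y) - np.log1p(-y)
    beta0, *_ = np.linalg.lstsq(X, ylog, rcond=None)
    mu0 = special.expit(X @ beta0)
    v = np.var(y - mu0)
    phi0 = max(float(np.mean(mu0 * (1 - mu0)) / max(v, 1e-6) - 1.0), 2.0)
    theta0 = np.concatenate([beta0, [np.log(phi0)], np.full(len(blocks), np.log(0.1))])
    bounds = ([(None, None)] * X.shape[1] + [(-2.0, 12.0)]
              + [(-7.0, 3.0)] * len(blocks))
    res = optimize.minimize(
        _laplace_nll, theta0, args=(X, y, Z, blocks), method="L-BFGS-B",
        bounds=bounds, options={"maxiter": 500, "ftol": 1e-11})
    p = X.shape[1]
    est = res.x[:p]
    hess = approx_hess1(res.x, _laplace_nll, args=(X, y, Z, blocks))
    se = np.full(p, np.nan)
    try:
        cov = np.linalg.inv(hess)
        d = np.diag(cov)[:p]
        se = np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        pass
    z = est / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    terms = pd.DataFrame({"term": names, "estimate": est, "se": se,
                          "stat": z, "p": pvals})
    sds = np.exp(res.x[p + 1:])
    fit = ModelFit(response=response, family="beta", terms=terms,
                   vcomp={r: float(s ** 2) for r, s in zip(rand, sds)},
                   resid_var=None, precision=float(np.exp(res.x[p])),
                   r2_marginal=None, r2_conditional=None, var_fixed=None,
                   vif=vif(data, fixed), converged=bool(res.success),
                   n=len(data))
    if not res.success:
        fit.notes.append(f"optimizer message: {res.message}")
    return fit


# ----------------------------------------------------------------- battery

#: per-leg performance metrics and whether their Date covariate is scaled /
#: which family is used (straightness: beta-logit; ODBA adds a logger-type
#: random intercept)
PERFORMANCE_METRICS = {
    "duration_days": {"scale_date": True, "family": "gaussian"},
    "migratory_days": {"scale_date": True, "family": "gaussian"},
    "stopover_days": {"scale_date": True, "family": "gaussian"},
    "beeline_km": {"scale_date": False, "family": "gaussian"},
    "straightness": {"scale_date": True, "family": "beta"},
    "mean_flight_odba": {"scale_date": True, "family": "gaussian",
                         "extra_random": ("logger_type",)},
}
WEATHER_METRICS = ("mean_blh", "mean_wind_support", "mean_zonal_wind")


def _prep(df: pd.DataFrame, scale_date: bool) -> pd.DataFrame:
    d = df.copy()
    d = d.dropna(subset=["start_date_julian"])
    if scale_date:
        d["date_cov"], _ = scale_dates(d["start_date_julian"])
    else:
        d["date_cov"] = d["start_date_julian"].astype(float)
    return d


def _tidy(fit: ModelFit, group: str, response: str, leg) -> pd.DataFrame:
    t = fit.terms.copy()
    t.insert(0, "leg", leg)
    t.insert(0, "response", response)
    t.insert(0, "model_group", group)
    t["r2_marginal"] = np.nan if fit.r2_marginal is None else fit.r2_marginal
    t["r2_conditional"] = np.nan if fit.r2_conditional is None else fit.r2_conditional
    t["family"] = fit.family
    t["n"] = fit.n
    t["converged"] = fit.converged
    t["error"] = ""
    return t


def _failure_row(group, response, leg, err) -> pd.DataFrame:
    return pd.DataFrame([{"model_group": group, "response": response, "leg": leg,
                          "term": "", "estimate": np.nan, "se": np.nan,
                          "stat": np.nan, "p": np.nan, "r2_marginal": np.nan,
                          "r2_conditional": np.nan, "family": "", "n": 0,
                          "converged": False, "error": str(err)}])


def run_model_battery(leg_summaries: pd.DataFrame,
                      daily_flight: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fit the full timing battery and return one tidy row per term.

    * 18 performance models: 6 metrics x legs 1-3 (straightness as beta GLMM,
      flight ODBA with an extra logger-type random intercept);
    * 6 destination models: latitude and longitude of the migration endpoint
      against the start date of each leg;
    * 9 weather models: mean boundary layer height, wind support and zonal
      wind per leg;
    * 1 flight-direction model (needs ``daily_flight``): daily mean
      longitudinal speed against leg-3 start date, daily mean zonal wind and
      their interaction.

    Single-model failures are recorded as rows with an ``error`` field; the
    battery always continues.
    """
    out = []
    ls = leg_summaries.copy()
    ls["bird"] = ls["bird_id"]
    ls["year"] = ls["year"].astype(str)

    for metric, spec in PERFORMANCE_METRICS.items():
        for leg in (1, 2, 3):
            sub = ls[(ls["leg"] == leg)].dropna(subset=[metric])
            try:
                d = _prep(sub, spec["scale_date"])
                extra = tuple(r for r in spec.get("extra_random", ())
                              if r in d.columns)
                rand = ("bird", "year") + extra
                if spec["family"] == "beta":
                    fit = fit_beta_glmm(d, metric, ["date_cov", "age"])
                else:
                    fit = fit_lmm(d, metric, ["date_cov", "age"], random=rand)
                out.append(_tidy(fit, "performance", metric, leg))
            except Exception as err:  # per-model failure, battery continues
                out.append(_failure_row("performance", metric, leg, err))

    dest = ls[ls["leg"] == "all"][["bird_id", "destination_lon", "destination_lat"]]
    for resp in ("destination_lat", "destination_lon"):
        for leg in (1, 2, 3):
            sub = (ls[ls["leg"] == leg]
                   .drop(columns=["destination_lon", "destination_lat"], errors="ignore")
                   .merge(dest, on="bird_id", how="inner"))
            try:
                d = _prep(sub, scale_date=False)
                fit = fit_lmm(d, resp, ["date_cov", "age"])
                out.append(_tidy(fit, "destination", resp, leg))
            except Exception as err:
                out.append(_failure_row("destination", resp, leg, err))

    for metric in WEATHER_METRICS:
        for leg in (1, 2, 3):
            sub = ls[(ls["leg"] == leg)]
            if metric not in sub.columns:
                out.append(_failure_row("weather", metric, leg, "column absent"))
                continue
            sub = sub.dropna(subset=[metric])
            try:
                d = _prep(sub, scale_date=False)
                fit = fit_lmm(d, metric, ["date_cov", "age"])
                out.append(_tidy(fit, "weather", metric, leg))
            except Exception as err:
                out.append(_failure_row("weather", metric, leg, err))

    if daily_flight is not None and len(daily_flight):
        try:
            d = daily_flight.copy()
            d["bird"] = d["bird_id"]
            d["year"] = d["year"].astype(str)
            d["date_cov"] = d["leg3_start_julian"].astype(float)
            d["wind"] = d["mean_zonal_wind"].astype(float)
            fit = fit_lmm(d, "mean_longitudinal_speed",
                          ["date_cov", "age", "wind", "date_cov:wind"])
            out.append(_tidy(fit, "flight_direction", "mean_longitudinal_speed", 3))
        except Exception as err:
            out.append(_failure_row("flight_direction", "mean_longitudinal_speed", 3, err))
    return pd.concat(out, ignore_index=True)
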