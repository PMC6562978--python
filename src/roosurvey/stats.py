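"""Inferential layer for the grouping/spacing analysis.

The models mirror a standard behavioural-ecology workflow:

* one-way ANOVA with Tukey HSD on log grazing density;
* D'Agostino skewness and Anscombe-Glynn kurtosis tests on group sizes,
  implemented from the published normal approximations;
* Gaussian linear mixed models (random session intercept, optionally a
  crossed group-size intercept) with likelihood-ratio tests for the
  disturbance factor and Tukey-adjusted least-squares-means contrasts;
* a negative-binomial regression of group size on log distance-to-cover,
  nested within disturbance type, with a Gaussian session intercept
  integrated out by Laplace approximation and Wald 95% CIs;
* a binomial GAM of vulnerable-individual positioning on a spline of
  distance to cover with disturbance as a fixed factor;
* greenness models (zone differences, and log group size on greenness
  nested in zone).

Natural logarithms are used throughout; distances are floored at 1 m
before logging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.special import gammaln

from .landscape import DISTURBANCE_LABELS

_Z95 = sps.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class MomentTestResult:
    """A moment-based normality test: sample statistic, Z, two-sided p."""

    kind: str  # "skewness" or "kurtosis"
    statistic: float  # g1 (skewness) or non-excess g2 (kurtosis)
    z: float
    p: float
    n: int

    def as_dict(self) -> dict:
        return {"kind": self.kind, "statistic": self.statistic,
                "z": self.z, "p": self.p, "n": self.n}


@dataclass
class FitResult:
    """Coefficients, intervals, variance components and contrasts of a fit.

    ``params`` rows: term, estimate, ci_low, ci_high, detected (CI excludes
    zero).  ``contrasts`` rows: pair, estimate, stat, p_adj.  ``random_sd``
    maps random-effect names to their estimated SDs.  ``stats`` holds
    fit-level scalars (F, LRT statistic and p, log-likelihoods, edf, ...).
    """

    family: str
    formula: str
    params: pd.DataFrame
    n_obs: int
    random_sd: dict = field(default_factory=dict)
    contrasts: pd.DataFrame | None = None
    stats: dict = field(default_factory=dict)
    method: tuple = ()

    def to_json_dict(self) -> dict:
        return {
            "family": self.family,
            "formula": self.formula,
            "n_obs": self.n_obs,
            "params": self.params.to_dict(orient="records"),
            "random_sd": self.random_sd,
            "contrasts": (None if self.contrasts is None
                          else self.contrasts.to_dict(orient="records")),
            "stats": {k: (float(v) if isinstance(v, (int, float, np.floating,
                                                     np.integer, bool)) else v)
                      for k, v in self.stats.items()},
            "method": list(self.method),
        }


def _params_frame(terms, est, se) -> pd.DataFrame:
    est = np.asarray(est, float)
    se = np.asarray(se, float)
    lo, hi = est - _Z95 * se, est + _Z95 * se
    return pd.DataFrame(
        {"term": terms, "estimate": est, "se": se,
         "ci_low": lo, "ci_high": hi,
         "detected": (lo > 0) | (hi < 0)}
    )


# ---------------------------------------------------------------------------
# Moment tests
# ---------------------------------------------------------------------------

def _central_moments(x):
    x = np.asarray(x, float)
    n = x.size
    m = x - x.mean()
    m2 = np.mean(m ** 2)
    return n, m2, np.mean(m ** 3), np.mean(m ** 4)


def dagostino_skewness(x) -> MomentTestResult:
    """D'Agostino's test of skewness.

    The sample skewness g1 = m3 / m2^{3/2} is mapped to an approximately
    standard normal Z through the Johnson SU transformation of D'Agostino
    (1970); the p-value is two-sided.  Requires n >= 8 and non-zero
    variance.
    """
    n, m2, m3, _ = _central_moments(x)
    if n < 8:
        raise ValueError("skewness test needs n >= 8")
    if m2 <= 0:
        raise ValueError("zero variance: skewness undefined")
    g1 = m3 / m2 ** 1.5

    y = g1 * np.sqrt((n + 1.0) * (n + 3.0) / (6.0 * (n - 2.0)))
    beta2 = (3.0 * (n ** 2 + 27.0 * n - 70.0) * (n + 1.0) * (n + 3.0)
             / ((n - 2.0) * (n + 5.0) * (n + 7.0) * (n + 9.0)))
    w2 = -1.0 + np.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / np.sqrt(0.5 * np.log(w2))
    alpha = np.sqrt(2.0 / (w2 - 1.0))
    ya = y / alpha
    z = delta * np.log(ya + np.sqrt(ya ** 2 + 1.0))
    p = 2.0 * sps.norm.sf(abs(z))
    return MomentTestResult("skewness", float(g1), float(z), float(p), n)


def anscombe_kurtosis(x) -> MomentTestResult:
    """Anscombe-Glynn test of kurtosis.

    The sample kurtosis is reported in the non-excess convention
    (g2 = m4 / m2^2; a normal sample gives about 3, leptokurtic > 3) and
    mapped to Z through the Wilson-Hilferty cube-root transformation of
    Anscombe & Glynn (1983).  Requires n >= 20.
    """
    n, m2, _, m4 = _central_moments(x)
    if n < 20:
        raise ValueError("kurtosis test needs n >= 20")
    if m2 <= 0:
        raise ValueError("zero variance: kurtosis undefined")
    b2 = m4 / m2 ** 2

    eb2 = 3.0 * (n - 1.0) / (n + 1.0)
    vb2 = (24.0 * n * (n - 2.0) * (n - 3.0)
           / ((n + 1.0) ** 2 * (n + 3.0) * (n + 5.0)))
    xx = (b2 - eb2) / np.sqrt(vb2)
    sqrtb1 = (6.0 * (n ** 2 - 5.0 * n + 2.0) / ((n + 7.0) * (n + 9.0))
              * np.sqrt(6.0 * (n + 3.0) * (n + 5.0)
                        / (n * (n - 2.0) * (n - 3.0))))
    a = 6.0 + 8.0 / sqrtb1 * (2.0 / sqrtb1
                              + np.sqrt(1.0 + 4.0 / sqrtb1 ** 2))
    term = (1.0 - 2.0 / a) / (1.0 + xx * np.sqrt(2.0 / (a - 4.0)))
    z = ((1.0 - 2.0 / (9.0 * a)) - np.cbrt(term)) / np.sqrt(2.0 / (9.0 * a))
    p = 2.0 * sps.norm.sf(abs(z))
    return MomentTestResult("kurtosis", float(b2), float(z), float(p), n)


# ---------------------------------------------------------------------------
# Density ANOVA + Tukey HSD
# ---------------------------------------------------------------------------

def density_anova(density: pd.DataFrame) -> FitResult:
    """One-way ANOVA on log density across zones, with Tukey HSD contrasts.

    ``density`` is the output of ``grazing_density`` (one row per
    zone x session).  Densities must be positive so the log is defined.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    zones = sorted(density["zone"].unique())
    if len(zones) < 2 or density["session"].nunique() < 2:
        raise ValueError("need at least two zones and two sessions")
    if (density["density_per_km2"] <= 0).any():
        raise ValueError("non-positive density: log transform undefined")
    logd = np.log(density["density_per_km2"].to_numpy(float))
    samples = [logd[(density["zone"] == z).to_numpy()] for z in zones]
    if np.ptp(logd) == 0.0:
        # all cells identical: no variance anywhere, nothing to detect
        f, p = 0.0, 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = sps.f_oneway(*samples)
    k, n = len(zones), len(logd)

    if np.ptp(logd) == 0.0:
        pairs = [(a, b) for i, a in enumerate(zones) for b in zones[i + 1:]]
        contrasts = pd.DataFrame(
            {"pair": [f"{a}-{b}" for a, b in pairs],
             "estimate": 0.0, "p_adj": 1.0}
        )
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tk = pairwise_tukeyhsd(logd, density["zone"].to_numpy(), alpha=0.05)
        contrasts = pd.DataFrame(
            {
                "pair": [f"{a}-{b}" for a, b in
                         zip(tk.groupsunique[tk._multicomp.pairindices[0]],
                             tk.groupsunique[tk._multicomp.pairindices[1]])],
                "estimate": tk.meandiffs,
                "p_adj": tk.pvalues,
            }
        )
    means = {z: float(s.mean()) for z, s in zip(zones, samples)}
    params = _params_frame(
        [f"mean log density {z}" for z in zones],
        [means[z] for z in zones],
        [float(s.std(ddof=1) / np.sqrt(len(s))) for s in samples],
    )
    return FitResult(
        family="gaussian-anova",
        formula="log(density) ~ zone",
        params=params, n_obs=n, contrasts=contrasts,
        stats={"F": float(f), "df1": k - 1, "df2": n - k, "p": float(p)},
        method=("one-way ANOVA", "TukeyHSD", "natural log"),
    )


# ---------------------------------------------------------------------------
# Gaussian linear mixed models
# ---------------------------------------------------------------------------

def _fit_mixedlm(formula, data, random, reml):
    """MixedLM fit with the requested random intercepts.

    ``random`` is a tuple of grouping-factor column names.  One factor is
    fitted as a classical random intercept; several are fitted as crossed
    variance components inside a single super-group.  Falls back to OLS
    (sigma = 0) when the mixed fit is singular or fails, mirroring
    boundary fits where the session variance collapses to zero.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if len(random) == 1:
                md = smf.mixedlm(formula, data=data, groups=data[random[0]])
            else:
                d = data.copy()
                d["_one"] = 1
                vcf = {r: f"0 + C({r})" for r in random}
                md = smf.mixedlm(formula, data=d, groups=d["_one"],
                                 re_formula="0", vc_formula=vcf)
            res = None
            for method in ("powell", "lbfgs"):
                try:
                    cand = md.fit(reml=reml, method=method, maxiter=500)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if not np.all(np.isfinite(cand.fe_params)):
                    continue
                if res is None or (np.isfinite(cand.llf)
                                   and cand.llf > res.llf):
                    res = cand
            if res is None:
                raise np.linalg.LinAlgError("mixed fit failed")
            if not reml:
                # the sigma = 0 boundary (plain OLS) is inside the parameter
                # space: never report a "maximum" below it
                ols = smf.ols(formula, data=data).fit()
                if not np.isfinite(res.llf) or ols.llf > res.llf + 1e-6:
                    return ols, True
            return res, False
        except (np.linalg.LinAlgError, ValueError):
            res = smf.ols(formula, data=data).fit()
            return res, True


def _random_sds(res, fallback: bool, random) -> dict:
    if fallback:
        return {r: 0.0 for r in random}
    out = {}
    try:
        if hasattr(res, "vcomp") and len(res.vcomp):
            for name, v in zip(res.model.exog_vc.names, res.vcomp):
                out[name] = float(np.sqrt(max(v, 0.0)))
        else:
            out[random[0]] = float(np.sqrt(max(res.cov_re.iloc[0, 0], 0.0)))
    except Exception:
        pass
    return out


def _lsmeans_contrasts(res, data, formula_rhs, factor, levels, df_resid):
    """Least-squares means per factor level and Tukey-adjusted contrasts.

    The lsmean covariance comes from the fitted fixed-effect covariance;
    the Tukey adjustment uses the studentized range on the residual df.
    """
    from patsy import build_design_matrices

    design_info = res.model.data.design_info
    grid = pd.DataFrame({factor: levels})
    for col in data.columns:
        if col == factor or col.startswith("_"):
            continue
        if col in formula_rhs:
            if data[col].dtype.kind in "OU" or f"C({col})" in formula_rhs:
                grid[col] = data[col].iloc[0]
            else:
                grid[col] = data[col].mean()
    (dm,) = build_design_matrices([design_info], grid)
    dm = np.asarray(dm)
    fe = res.fe_params if hasattr(res, "fe_params") else res.params
    cov = np.asarray(res.cov_params())[: dm.shape[1], : dm.shape[1]]
    means = dm @ np.asarray(fe)
    k = len(levels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            c = dm[i] - dm[j]
            est = float(c @ np.asarray(fe))
            se = float(np.sqrt(max(c @ cov @ c, 0.0)))
            if se == 0:
                t, p = 0.0, 1.0
            else:
                t = est / se
                p = float(sps.studentized_range.sf(abs(t) * np.sqrt(2.0),
                                                   k, max(df_resid, 2)))
            rows.append({"pair": f"{levels[i]}-{levels[j]}",
                         "estimate": est, "stat": t,
                         "p_adj": min(max(p, 0.0), 1.0)})
    lsm = pd.DataFrame({"level": levels, "lsmean": means})
    return lsm, pd.DataFrame(rows)


def _zone_lrt(formula_full, formula_null, data, random):
    """ML likelihood-ratio test of the zone factor in a mixed model."""
    res_f, fb_f = _fit_mixedlm(formula_full, data, random, reml=False)
    res_n, _ = _fit_mixedlm(formula_null, data, random, reml=False)
    ll_f, ll_n = float(res_f.llf), float(res_n.llf)
    if not (np.isfinite(ll_f) and np.isfinite(ll_n)):
        # degenerate mixed fit (residual variance at zero); use the
        # fixed-effects likelihoods for the LRT instead
        import statsmodels.formula.api as smf

        res_f = smf.ols(formula_full, data=data).fit()
        res_n = smf.ols(formula_null, data=data).fit()
        fb_f = True
        ll_f, ll_n = float(res_f.llf), float(res_n.llf)
    df = (res_f.params.size if not hasattr(res_f, "fe_params")
          else len(res_f.fe_params)) - (
         res_n.params.size if not hasattr(res_n, "fe_params")
         else len(res_n.fe_params))
    stat = max(0.0, 2.0 * (ll_f - ll_n))
    p = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0
    return res_f, fb_f, stat, df, p


def _mixed_zone_model(data, response, random, extra_rhs="",
                      family_tag="gaussian-lmm") -> FitResult:
    """Shared builder: response ~ zone (+extras) with random intercepts."""
    zones = [z for z in DISTURBANCE_LABELS if z in set(data["zone"])]
    zones += sorted(set(data["zone"]) - set(zones))
    data = data.copy()
    data["zone"] = pd.Categorical(data["zone"], categories=zones)

    rhs = "C(zone)" + extra_rhs
    full = f"{response} ~ {rhs}"
    null = f"{response} ~ 1" + extra_rhs
    if len(zones) < 2:
        res, fb = _fit_mixedlm(null, data, random, reml=False)
        fe = res.fe_params if hasattr(res, "fe_params") else res.params
        se = res.bse[: len(fe)]
        return FitResult(
            family=family_tag, formula=full,
            params=_params_frame(list(fe.index), fe, se),
            n_obs=len(data), random_sd=_random_sds(res, fb, random),
            stats={"lrt_stat": 0.0, "lrt_df": 0, "lrt_p": 1.0},
            method=("MixedLM", "single zone: LRT is identity"),
        )

    res, fb, stat, df, p = _zone_lrt(full, null, data, random)
    fe = res.fe_params if hasattr(res, "fe_params") else res.params
    nfe = len(fe)
    se = np.asarray(res.bse)[:nfe]
    df_resid = len(data) - nfe
    lsm, contrasts = _lsmeans_contrasts(res, data, rhs, "zone", zones, df_resid)
    fr = FitResult(
        family=family_tag, formula=full,
        params=_params_frame(list(fe.index), np.asarray(fe), se),
        n_obs=len(data), random_sd=_random_sds(res, fb, random),
        contrasts=contrasts,
        stats={"lrt_stat": stat, "lrt_df": df, "lrt_p": p,
               "sigma0_fallback": fb},
        method=("MixedLM", "ML LRT", "Tukey (studentized range)"),
    )
    fr.stats["lsmeans"] = lsm.to_dict(orient="records")
    return fr


def groupsize_lmm(groups: pd.DataFrame) -> FitResult:
    """Disturbance x chain-rule effects on log group size.

    ``groups`` needs columns size, zone, chain_m, session.  Fits a
    Gaussian LMM of log size on zone x chain with a random session
    intercept, and returns Tukey-adjusted pairwise contrasts of the
    zone-within-chain cell means (within and between chain rules).
    """
    df = groups.copy()
    if df["session"].nunique() < 2 or df["zone"].nunique() < 2:
        raise ValueError("need at least two zones and two sessions")
    df["log_size"] = np.log(df["size"].astype(float))
    zones = [z for z in DISTURBANCE_LABELS if z in set(df["zone"])]
    df["zone"] = pd.Categorical(df["zone"], categories=zones)
    chains = sorted(df["chain_m"].unique())
    df["cell"] = (df["zone"].astype(str) + "@"
                  + df["chain_m"].astype(int).astype(str) + "m")
    cells = [f"{z}@{int(c)}m" for c in chains for z in zones
             if f"{z}@{int(c)}m" in set(df["cell"])]
    df["cell"] = pd.Categorical(df["cell"], categories=cells)

    formula = "log_size ~ C(cell)"
    res, fb = _fit_mixedlm(formula, df, ("session",), reml=False)
    fe = res.fe_params if hasattr(res, "fe_params") else res.params
    nfe = len(fe)
    df_resid = len(df) - nfe
    lsm, contrasts = _lsmeans_contrasts(res, df, "C(cell)", "cell",
                                        cells, df_resid)
    _, _, stat, dfl, p = _zone_lrt(formula, "log_size ~ 1", df, ("session",))
    fr = FitResult(
        family="gaussian-lmm",
        formula="log(size) ~ zone x chain + (1 | session)",
        params=_params_frame(list(fe.index), np.asarray(fe),
                             np.asarray(res.bse)[:nfe]),
        n_obs=len(df), random_sd=_random_sds(res, fb, ("session",)),
        contrasts=contrasts,
        stats={"lrt_stat": stat, "lrt_df": dfl, "lrt_p": p,
               "sigma0_fallback": fb, "lsmeans": lsm.to_dict(orient="records")},
        method=("MixedLM", "lsmeans", "Tukey (studentized range)"),
    )
    return fr


def clusteredness_lmm(groups: pd.DataFrame) -> FitResult:
    """Zone effect on log mean nearest-neighbour distance.

    ``groups`` needs columns mean_nn_m (> 0; singletons excluded), zone,
    session, size.  Random intercepts: session and group-size level.
    LRT for the zone factor plus Tukey contrasts.
    """
    df = groups.dropna(subset=["mean_nn_m"]).copy()
    df = df[df["mean_nn_m"] > 0]
    df["log_nn"] = np.log(df["mean_nn_m"].astype(float))
    df["gsize"] = df["size"].astype(int)
    return _mixed_zone_model(df, "log_nn", ("session", "gsize"))


def demography_lmm(compositions: pd.DataFrame, demo_class: str) -> FitResult:
    """Zone effect on one demographic class's per-group proportion.

    ``compositions`` is the per-group composition table (needs the class
    proportion column, zone, session, n_members).  Random intercepts:
    session and group-size level.
    """
    df = compositions.copy()
    df["prop"] = df[demo_class].astype(float)
    df["gsize"] = df["n_members"].astype(int)
    fr = _mixed_zone_model(df, "prop", ("session", "gsize"))
    fr.stats["demo_class"] = demo_class
    return fr


# ---------------------------------------------------------------------------
# Negative-binomial GLMM with Laplace-approximated session intercept
# ---------------------------------------------------------------------------

def _nb_logpmf(y, mu, k):
    return (gammaln(y + k) - gammaln(k) - gammaln(y + 1.0)
            + k * np.log(k / (k + mu)) + y * np.log(mu / (k + mu)))


def _laplace_nll(theta, y, X, sess_idx, n_sess, fixed_sigma=None):
    """Negative Laplace-approximate marginal log-likelihood.

    theta = (beta, log k[, sigma]); the session intercepts are profiled
    out by a concave 1-D Newton step per session (the NB log-likelihood
    is concave in the linear predictor).
    """
    p = X.shape[1]
    beta = theta[:p]
    k = np.exp(theta[p])
    sigma = fixed_sigma if fixed_sigma is not None else theta[p + 1]
    eta = X @ beta

    if sigma <= 1e-8:
        mu = np.exp(np.clip(eta, -30, 30))
        return -float(np.sum(_nb_logpmf(y, mu, k)))

    u = np.zeros(n_sess)
    for _ in range(50):
        mu = np.exp(np.clip(eta + u[sess_idx], -30, 30))
        s = mu / (k + mu)
        grad_i = y - (y + k) * s
        hess_i = -(y + k) * k * mu / (k + mu) ** 2
        g = np.bincount(sess_idx, grad_i, minlength=n_sess) - u / sigma ** 2
        h = np.bincount(sess_idx, hess_i, minlength=n_sess) - 1.0 / sigma ** 2
        step = g / h
        # damped Newton; h < 0 so the step is ascent
        u_new = u - np.clip(step, -5.0, 5.0)
        if np.max(np.abs(u_new - u)) < 1e-10:
            u = u_new
            break
        u = u_new
    mu = np.exp(np.clip(eta + u[sess_idx], -30, 30))
    f = np.sum(_nb_logpmf(y, mu, k))
    hess_i = -(y + k) * k * mu / (k + mu) ** 2
    h = np.bincount(sess_idx, hess_i, minlength=n_sess) - 1.0 / sigma ** 2
    ll = (f - 0.5 * np.sum(u ** 2) / sigma ** 2
          - n_sess * np.log(sigma) - 0.5 * np.sum(np.log(-h)))
    return -float(ll)


def _num_gradient(fun, x, eps=1e-6):
    g = np.zeros(len(x))
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(len(x)):
        e = np.zeros(len(x)); e[i] = steps[i]
        g[i] = (fun(x + e) - fun(x - e)) / (2 * steps[i])
    return g


def _newton_polish(fun, x, bounds, max_steps=6):
    """Damped Newton refinement after L-BFGS-B, respecting lower bounds."""
    f = fun(x)
    for _ in range(max_steps):
        g = _num_gradient(fun, x)
        H = _num_hessian(fun, x)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        improved = False
        for damp in (1.0, 0.5, 0.25, 0.1):
            cand = x - damp * step
            for i, (lo, _hi) in enumerate(bounds):
                if lo is not None:
                    cand[i] = max(cand[i], lo)
            fc = fun(cand)
            if fc < f - 1e-12:
                x, f = cand, fc
                improved = True
                break
        if not improved:
            break
    return x


def _num_hessian(fun, x, eps=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    f0 = fun(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    _ = f0
    return H


def groupsize_cover_glmm(
    groups: pd.DataFrame,
    ref: str = "HB",
    sigma: float | None = None,
) -> FitResult:
    """NB regression of group size on log distance-to-cover, nested in zone.

    ``groups`` needs columns size (counts >= 1), cover_m (distance from
    group centre to forest edge, floored at 1 m before logging), zone,
    session.  The model is NB2 with log link,

        log mu = intercept(ref) + zone deviations + beta_zone * log(cover),

    one slope per zone, plus a Gaussian session random intercept whose
    marginal likelihood is integrated by Laplace approximation.  Wald 95%
    CIs come from the numerical Hessian at the optimum; a slope is flagged
    ``detected`` when its CI excludes zero.  Pass ``sigma=0`` to fix the
    random effect at zero (the fit then reduces to a plain NB GLM).
    """
    df = groups.copy()
    y = df["size"].to_numpy(float)
    if (y < 1).any():
        raise ValueError("group sizes must be >= 1")
    logd = np.log(np.maximum(df["cover_m"].to_numpy(float), 1.0))
    zones = [z for z in DISTURBANCE_LABELS if z in set(df["zone"])]
    zones += sorted(set(df["zone"]) - set(zones))
    if ref in zones:
        zones = [ref] + [z for z in zones if z != ref]
    zcodes = df["zone"].map({z: i for i, z in enumerate(zones)}).to_numpy()

    nz = len(zones)
    n = len(df)
    X = np.zeros((n, 2 * nz))
    X[:, 0] = 1.0
    for i in range(1, nz):
        X[:, i] = (zcodes == i)
    for i in range(nz):
        X[:, nz + i] = (zcodes == i) * logd
    terms = ([f"Intercept ({zones[0]})"] + list(zones[1:])
             + [f"{z}:Cover" for z in zones])

    sess_levels, sess_idx = np.unique(df["session"].to_numpy(), return_inverse=True)
    n_sess = len(sess_levels)

    # starting values from a Poisson fit and moment-matched dispersion
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta0 = sm.GLM(y, X, family=sm.families.Poisson()).fit().params
    mu0 = np.exp(np.clip(X @ beta0, -30, 30))
    excess = np.mean((y - mu0) ** 2 - mu0)
    k0 = float(np.clip(np.mean(mu0 ** 2) / max(excess, 1e-6), 0.05, 50.0))

    fixed_sigma = sigma
    if fixed_sigma is None:
        x0 = np.concatenate([beta0, [np.log(k0)], [0.1]])
        bounds = [(None, None)] * (len(beta0) + 1) + [(0.0, None)]
    else:
        x0 = np.concatenate([beta0, [np.log(k0)]])
        bounds = [(None, None)] * (len(beta0) + 1)

    def nll(theta):
        return _laplace_nll(theta, y, X, sess_idx, n_sess,
                            fixed_sigma=fixed_sigma)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        opt = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 1000, "ftol": 1e-14,
                                         "gtol": 1e-10})
    theta = _newton_polish(nll, opt.x, bounds)
    p = X.shape[1]
    k_hat = float(np.exp(theta[p]))
    sigma_hat = (float(fixed_sigma) if fixed_sigma is not None
                 else float(theta[p + 1]))

    # Wald covariance: drop sigma from the Hessian when it sits on the
    # zero boundary, where the curvature in sigma is not informative
    at_boundary = fixed_sigma is not None or sigma_hat < 1e-4
    if at_boundary:
        th_red = theta[: p + 1]

        def nll_red(t):
            return _laplace_nll(t, y, X, sess_idx, n_sess, fixed_sigma=0.0)

        H = _num_hessian(nll_red, th_red)
    else:
        H = _num_hessian(nll, theta)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)

    fr = FitResult(
        family="negative-binomial GLMM",
        formula="size ~ zone / log(cover) + (1 | session), NB2 log link",
        params=_params_frame(terms, theta[:p], se),
        n_obs=n,
        random_sd={"session": sigma_hat},
        stats={
            "dispersion_k": k_hat, "alpha": 1.0 / k_hat,
            "loglik": -float(opt.fun),
            "converged": bool(opt.success),
            "grad_norm": float(np.max(np.abs(opt.jac)))
            if opt.jac is not None else np.nan,
            "poisson_limit": k_hat > 1e4,
        },
        method=("Laplace approximation", "Wald CI", "natural log",
                "cover floored at 1 m"),
    )
    if not opt.success:
        fr.stats["warning"] = f"optimizer: {opt.message}"
    return fr


# ---------------------------------------------------------------------------
# Positioning GAM
# ---------------------------------------------------------------------------

def positioning_gam(records: pd.DataFrame, spline_df: int = 6) -> FitResult:
    """Binomial GAM of front/behind positioning on distance to cover.

    ``records`` are positioning records (side, GDC, zone), one per
    vulnerable individual.  The model is binomial with a zone fixed factor
    and a B-spline smooth of the group's distance to cover, penalised with
    a weight chosen by generalised cross-validation.  Pairwise zone
    contrasts are Wald tests on differences of the zone offsets (numerically
    identical to refitting with each zone as the reference level).
    """
    import statsmodels.api as sm
    from statsmodels.gam.api import BSplines, GLMGam

    df = records.copy()
    df["front"] = (df["side"] == "front").astype(int)
    zones = [z for z in DISTURBANCE_LABELS if z in set(df["zone"])]
    zones += sorted(set(df["zone"]) - set(zones))
    df["zone"] = pd.Categorical(df["zone"], categories=zones)

    ndist = df["GDC"].nunique()
    sdf = min(spline_df, max(ndist - 1, 3))
    reduced = sdf < spline_df
    bs = BSplines(df[["GDC"]].to_numpy(), df=[sdf], degree=[3])
    nz_ = df["zone"].nunique()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # penalty weight by AIC over a log-spaced grid (effective df shrinks
        # towards 1 as the weight grows, so a flat truth selects a line)
        best = None
        for la in np.arange(0.0, 13.0, 1.0):
            m = GLMGam.from_formula("front ~ C(zone)", data=df, smoother=bs,
                                    family=sm.families.Binomial(),
                                    alpha=10.0 ** la)
            try:
                r = m.fit()
            except Exception:
                continue
            if best is None or r.aic < best[0]:
                best = (r.aic, 10.0 ** la, r)
        if best is None:
            raise RuntimeError("GAM failed to fit at any penalty weight")
        _, alpha, res = best

    params = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    names = list(res.model.exog_names)
    nz = len(zones)
    se = np.sqrt(np.diag(cov))
    pframe = _params_frame(names, params, se)

    # pairwise zone contrasts from the coefficient covariance
    rows = []
    zone_cols = {zones[0]: None}
    for i, z in enumerate(zones[1:], start=1):
        zone_cols[z] = i  # C(zone)[T.z] columns follow the intercept
    for i in range(nz):
        for j in range(i + 1, nz):
            c = np.zeros(len(params))
            if zone_cols[zones[i]] is not None:
                c[zone_cols[zones[i]]] += 1.0
            if zone_cols[zones[j]] is not None:
                c[zone_cols[zones[j]]] -= 1.0
            est = float(c @ params)
            s = float(np.sqrt(c @ cov @ c))
            z_stat = est / s if s > 0 else 0.0
            rows.append({"pair": f"{zones[i]}-{zones[j]}",
                         "estimate": est, "stat": z_stat,
                         "p_adj": 2.0 * float(sps.norm.sf(abs(z_stat)))})
    contrasts = pd.DataFrame(rows)

    try:
        edf = np.asarray(res.edf)
        edf_smooth = float(edf[nz:].sum())
    except Exception:
        edf_smooth = np.nan

    return FitResult(
        family="binomial GAM",
        formula="front ~ zone + s(GDC)",
        params=pframe, n_obs=len(df), contrasts=contrasts,
        stats={"edf_smooth": edf_smooth, "spline_df": sdf,
               "basis_reduced": reduced,
               "alpha": float(np.atleast_1d(alpha)[0])},
        method=("GLMGam", "B-splines", "GCV penalty weight",
                "zone contrasts via coefficient covariance"),
    )


def predicted_front_proportion(fit_records: pd.DataFrame,
                               fit: FitResult | None = None) -> pd.DataFrame:
    """Observed front proportion per zone across GDC quantile bins.

    A monotonicity summary used to check the planted edge-bias decay.
    """
    df = fit_records.copy()
    df["front"] = (df["side"] == "front").astype(int)
    df["bin"] = pd.qcut(df["GDC"], q=min(6, df["GDC"].nunique()),
                        duplicates="drop")
    out = (df.groupby(["zone", "bin"], observed=True)
             .agg(prop_front=("front", "mean"), gdc=("GDC", "mean"),
                  n=("front", "size"))
             .reset_index())
    return out


# ---------------------------------------------------------------------------
# Greenness models
# ---------------------------------------------------------------------------

def greenness_models(green: pd.DataFrame) -> tuple[FitResult, FitResult]:
    """Greenness differences across zones, and group size on greenness.

    ``green`` needs columns greenness (fraction), zone, session, size.
    Model A: greenness (%) ~ zone with a random session intercept, ML LRT
    and Tukey contrasts.  Model B: log group size ~ greenness (%) nested
    in zone with a random session intercept and Wald CIs per-zone slope
    ("<zone>:Green" terms).
    """
    df = green.copy()
    df["green_pct"] = 100.0 * df["greenness"].astype(float)

    model_a = _mixed_zone_model(df, "green_pct", ("session",),
                                family_tag="gaussian-lmm (greenness)")

    zones = [z for z in DISTURBANCE_LABELS if z in set(df["zone"])]
    zones += sorted(set(df["zone"]) - set(zones))
    df["zone"] = pd.Categorical(df["zone"], categories=zones)
    df["log_size"] = np.log(df["size"].astype(float))
    formula = "log_size ~ C(zone) + C(zone):green_pct"
    res, fb = _fit_mixedlm(formula, df, ("session",), reml=False)
    fe = res.fe_params if hasattr(res, "fe_params") else res.params
    nfe = len(fe)
    terms = []
    for name in fe.index:
        if name == "Intercept":
            terms.append(f"Intercept ({zones[0]})")
        elif ":green_pct" in name:
            z = name.split("[")[1].split("]")[0].lstrip("T.")
            terms.append(f"{z}:Green")
        elif name.startswith("C(zone)"):
            terms.append(name.split("[T.")[1].rstrip("]"))
        else:
            terms.append(name)
    model_b = FitResult(
        family="gaussian-lmm (size~greenness)",
        formula="log(size) ~ zone / greenness + (1 | session)",
        params=_params_frame(terms, np.asarray(fe), np.asarray(res.bse)[:nfe]),
        n_obs=len(df), random_sd=_random_sds(res, fb, ("session",)),
        stats={"sigma0_fallback": fb},
        method=("MixedLM", "Wald CI"),
    )
    return model_a, model_b
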