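"""Binomial GLM / GLMM stages of the recruitment chain.

Four experimental stages are modelled with binomial regressions:

* nursery germination versus fruit handling treatment (whole fruit,
  manually de-pulped, bird-ingested) — GLM, fit per species;
* proportion of trapped seeds ingested versus island, and versus distance
  to the nearest conspecific on the bird islands — GLMMs with a collection
  -site random intercept;
* outplanted-seedling survival versus bird presence, near/far distance
  class, canopy openness and their interactions — GLMM with a site random
  intercept (openness mean-centred before fitting);
* seed-addition germination and early seedling survival versus distance
  class, openness and site — GLMs.

Model selection uses the small-sample-corrected Akaike criterion (AICc,
with ``n`` = the number of binomial observations, i.e. traps or plots);
within two AICc units the simplest model is preferred.  Inference on
coefficients uses 95% profile-likelihood intervals, with an explicit
includes-zero flag.

Fixed-effect GLMs are fit with statsmodels; the random-intercept GLMM uses
an adaptive Gauss-Hermite approximation to the marginal likelihood (the
integral factorizes over groups, so each group needs only a one-dimensional
quadrature centred on its conditional mode).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import chi2

__all__ = [
    "StageModelFit",
    "aicc",
    "profile_ci",
    "fit_binomial_glm",
    "fit_binomial_glmm",
    "fit_germination_glm",
    "fit_ingestion_island",
    "fit_ingestion_distance",
    "fit_seedling_survival",
    "fit_field_germination",
    "TREATMENTS",
]

TREATMENTS = ("whole_fruit", "depulped", "ingested")

_CHI2_95_1DF = float(chi2.ppf(0.95, 1))  # 3.8415


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: ``-2 loglik + 2k + 2k(k+1)/(n-k-1)``."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


# ---------------------------------------------------------------------------
# fitted-stage container


@dataclass
class StageModelFit:
    """A fitted binomial stage model.

    Holds the AICc-best model's coefficients on the log-odds scale, the
    covariance of the fixed effects, the full AICc comparison table, and
    profile 95% confidence intervals keyed by coefficient name.
    """

    tag: str
    terms: list[str]
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    k: int
    n_obs: int
    aicc: float
    table: pd.DataFrame
    sigma_group: float | None = None
    profile_cis: dict[str, tuple[float, float, bool]] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)
    _profile_fn: Callable[[int, float], float] | None = field(
        default=None, repr=False, compare=False
    )

    def coef_dict(self) -> dict[str, float]:
        return dict(zip(self.terms, self.coef))

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def predict_logodds(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef

    def to_dict(self) -> dict:
        return {
            "tag": self.tag,
            "terms": self.terms,
            "coef": self.coef.tolist(),
            "cov": self.cov.tolist(),
            "loglik": self.loglik,
            "k": self.k,
            "n_obs": self.n_obs,
            "aicc": self.aicc,
            "sigma_group": self.sigma_group,
            "profile_cis": {
                k: [v[0], v[1], bool(v[2])] for k, v in self.profile_cis.items()
            },
            "aicc_table": self.table.to_dict(orient="records"),
            "extras": {k: v for k, v in self.extras.items() if _jsonable(v)},
        }


def _jsonable(v) -> bool:
    return isinstance(v, (str, int, float, bool, list, dict, type(None)))


# ---------------------------------------------------------------------------
# binomial GLM (statsmodels behind the surface)

_SEPARATION_CUTOFF = 12.0  # |log-odds| beyond this is treated as separation


def fit_binomial_glm(
    X: np.ndarray,
    successes: np.ndarray,
    trials: np.ndarray,
    terms: Sequence[str],
    tag: str = "",
) -> StageModelFit:
    """Maximum-likelihood binomial GLM on an explicit design matrix.

    Detects (quasi-)complete separation by divergent coefficients and
    refits with a tiny ridge penalty so that reported log-odds stay finite;
    the condition is flagged in ``extras['separation']``.
    """
    X = np.asarray(X, dtype=float)
    successes = np.asarray(successes, dtype=float)
    trials = np.asarray(trials, dtype=float)
    endog = np.column_stack([successes, trials - successes])
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=200)
            coef = np.asarray(res.params, dtype=float)
            separated = bool(np.any(np.abs(coef) > _SEPARATION_CUTOFF)) or not np.all(
                np.isfinite(coef)
            )
        except Exception:
            separated = True
        if separated:
            res = model.fit_regularized(alpha=1e-4, L1_wt=0.0, maxiter=500)
            # fit_regularized gives no covariance; fall back to a penalized
            # observed-information covariance
            coef = np.asarray(res.params, dtype=float)
            cov = _binom_cov(X, trials, coef, ridge=1e-4)
            llf = float(_binom_loglik(X, successes, trials, coef))
        else:
            cov = np.asarray(res.cov_params(), dtype=float)
            llf = float(res.llf)
            coef = np.asarray(res.params, dtype=float)
    n = len(successes)
    k = X.shape[1]
    fit = StageModelFit(
        tag=tag,
        terms=list(terms),
        coef=coef,
        cov=cov,
        loglik=llf,
        k=k,
        n_obs=n,
        aicc=aicc(llf, k, n) if n > k + 1 else math.inf,
        table=pd.DataFrame(),
        extras={"separation": bool(separated)},
    )
    fit._profile_fn = _glm_profile_fn(X, successes, trials)
    return fit


def _binom_loglik(X, successes, trials, coef):
    eta = X @ coef
    ll = (
        successes * eta
        - trials * np.logaddexp(0.0, eta)
        + gammaln(trials + 1)
        - gammaln(successes + 1)
        - gammaln(trials - successes + 1)
    )
    return np.sum(ll)


def _binom_cov(X, trials, coef, ridge=0.0):
    p = expit(X @ coef)
    w = trials * p * (1 - p)
    H = (X * w[:, None]).T @ X + ridge * np.eye(X.shape[1])
    return np.linalg.pinv(H)


def _glm_profile_fn(X, successes, trials):
    def profile(j: int, value: float) -> float:
        offset = X[:, j] * value
        Xr = np.delete(X, j, axis=1)
        endog = np.column_stack([successes, trials - successes])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if Xr.shape[1] == 0:
                return float(
                    np.sum(
                        successes * offset
                        - trials * np.logaddexp(0.0, offset)
                        + gammaln(trials + 1)
                        - gammaln(successes + 1)
                        - gammaln(trials - successes + 1)
                    )
                )
            model = sm.GLM(endog, Xr, family=sm.families.Binomial(), offset=offset)
            try:
                res = model.fit(maxiter=200)
                return float(res.llf)
            except Exception:
                res = model.fit_regularized(alpha=1e-6, L1_wt=0.0, maxiter=500)
                coef = np.asarray(res.params, dtype=float)
                eta = Xr @ coef + offset
                ll = (
                    successes * eta
                    - trials * np.logaddexp(0.0, eta)
                    + gammaln(trials + 1)
                    - gammaln(successes + 1)
                    - gammaln(trials - successes + 1)
                )
                return float(np.sum(ll))

    return profile


# ---------------------------------------------------------------------------
# binomial GLMM with a single random intercept (adaptive Gauss-Hermite)

_GH_NODES = 25
_gh_z, _gh_w = np.polynomial.hermite.hermgauss(_GH_NODES)


def _glmm_marginal_loglik(
    beta: np.ndarray,
    log_sigma: float,
    X: np.ndarray,
    successes: np.ndarray,
    trials: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
) -> float:
    """Marginal log-likelihood, groups integrated out by adaptive GH.

    For each group the conditional mode of the random intercept is found by
    a few Newton steps; quadrature nodes are then centred and scaled there.
    """
    sigma = math.exp(log_sigma)
    eta0 = X @ beta
    const = float(
        np.sum(
            gammaln(trials + 1) - gammaln(successes + 1) - gammaln(trials - successes + 1)
        )
    )

    # Newton search for the per-group mode of l_g(u) + log phi(u; sigma)
    u = np.zeros(n_groups)
    for _ in range(25):
        p = expit(eta0 + u[group_idx])
        grad = np.bincount(group_idx, weights=successes - trials * p, minlength=n_groups)
        grad -= u / sigma**2
        hess = -np.bincount(
            group_idx, weights=trials * p * (1 - p), minlength=n_groups
        ) - 1.0 / sigma**2
        step = grad / hess
        u_new = u - step
        if np.max(np.abs(u_new - u)) < 1e-10:
            u = u_new
            break
        u = u_new
    tau = 1.0 / np.sqrt(-hess)  # curvature scale at the mode

    # adaptive nodes u_gk = u_g + sqrt(2) tau_g z_k
    nodes = u[:, None] + math.sqrt(2.0) * tau[:, None] * _gh_z[None, :]  # (G, K)
    eta = eta0[:, None] + nodes[group_idx, :]  # (N, K)
    ll_obs = successes[:, None] * eta - trials[:, None] * np.logaddexp(0.0, eta)
    ll_group = np.zeros((n_groups, _GH_NODES))
    for kk in range(_GH_NODES):
        ll_group[:, kk] = np.bincount(
            group_idx, weights=ll_obs[:, kk], minlength=n_groups
        )
    log_phi = -0.5 * math.log(2 * math.pi) - math.log(sigma) - 0.5 * (nodes / sigma) ** 2
    log_weights = np.log(_gh_w)[None, :] + _gh_z[None, :] ** 2
    log_scale = 0.5 * math.log(2.0) + np.log(tau)[:, None]
    integrand = log_weights + log_scale + ll_group + log_phi
    return float(np.sum(logsumexp(integrand, axis=1))) + const


def fit_binomial_glmm(
    X: np.ndarray,
    successes: np.ndarray,
    trials: np.ndarray,
    groups: Sequence,
    terms: Sequence[str],
    tag: str = "",
    sigma_bounds: tuple[float, float] = (1e-4, 10.0),
) -> StageModelFit:
    """Binomial GLMM with a random intercept per group, by maximizing the
    adaptive Gauss-Hermite marginal likelihood.

    Returns fixed-effect estimates with their observed-information
    covariance evaluated at the variance-component MLE (the conventional
    conditional covariance).
    """
    X = np.asarray(X, dtype=float)
    successes = np.asarray(successes, dtype=float)
    trials = np.asarray(trials, dtype=float)
    labels, group_idx = np.unique(np.asarray(groups), return_inverse=True)
    n_groups = len(labels)
    p = X.shape[1]

    # start from the GLM fit
    glm = fit_binomial_glm(X, successes, trials, terms)
    x0 = np.concatenate([glm.coef, [math.log(0.3)]])

    def negll(params):
        beta, log_sigma = params[:p], params[p]
        if not (math.log(sigma_bounds[0]) <= log_sigma <= math.log(sigma_bounds[1])):
            return 1e12
        try:
            return -_glmm_marginal_loglik(
                beta, log_sigma, X, successes, trials, group_idx, n_groups
            )
        except FloatingPointError:  # pragma: no cover - defensive
            return 1e12

    with np.errstate(over="ignore"):
        res = optimize.minimize(
            negll,
            x0,
            method="L-BFGS-B",
            bounds=[(None, None)] * p
            + [(math.log(sigma_bounds[0]), math.log(sigma_bounds[1]))],
        )
    beta_hat = res.x[:p]
    log_sigma_hat = res.x[p]
    llf = -float(res.fun)
    sigma_hat = math.exp(log_sigma_hat)

    # observed information for the fixed effects at the sigma MLE
    def negll_beta(beta):
        return -_glmm_marginal_loglik(
            beta, log_sigma_hat, X, successes, trials, group_idx, n_groups
        )

    H = _num_hessian(negll_beta, beta_hat)
    cov = np.linalg.pinv(H)

    separated = bool(np.any(np.abs(beta_hat) > _SEPARATION_CUTOFF))
    n = len(successes)
    k = p + 1  # fixed effects + random-intercept variance
    fit = StageModelFit(
        tag=tag,
        terms=list(terms),
        coef=beta_hat,
        cov=cov,
        loglik=llf,
        k=k,
        n_obs=n,
        aicc=aicc(llf, k, n) if n > k + 1 else math.inf,
        table=pd.DataFrame(),
        sigma_group=sigma_hat,
        extras={"separation": separated, "groups": [str(g) for g in labels]},
    )

    def profile(j: int, value: float) -> float:
        free = [i for i in range(p) if i != j]

        def negll_fixed(params):
            beta = np.empty(p)
            beta[free] = params[:-1]
            beta[j] = value
            return negll(np.concatenate([beta, [params[-1]]]))

        x0p = np.concatenate([beta_hat[free], [log_sigma_hat]])
        r = optimize.minimize(negll_fixed, x0p, method="L-BFGS-B")
        return -float(r.fun)

    fit._profile_fn = profile
    return fit


def _num_hessian(fn, x, eps=1e-4):
    x = np.asarray(x, dtype=float)
    d = len(x)
    H = np.empty((d, d))
    f0 = fn(x)
    step = eps * np.maximum(1.0, np.abs(x))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = step[i]
            ej[j] = step[j]
            fpp = fn(x + ei + ej)
            fpm = fn(x + ei - ej)
            fmp = fn(x - ei + ej)
            fmm = fn(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * step[i] * step[j])
    return H


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals


def profile_ci(
    fit: StageModelFit, coefficient: str, level: float = 0.95
) -> tuple[float, float, bool]:
    """Profile-likelihood confidence interval for one coefficient.

    Endpoints are where the profile deviance rises by the chi-square(1)
    quantile above its minimum.  Returns ``(lo, hi, includes_zero)``; an
    unbounded profile yields an infinite endpoint (flagged by the caller
    seeing ``inf``).
    """
    if fit._profile_fn is None:
        raise ValueError("fit carries no profiling machinery")
    j = fit.terms.index(coefficient)
    crit = float(chi2.ppf(level, 1)) / 2.0
    mle = fit.coef[j]
    ll_hat = fit.loglik
    target = ll_hat - crit

    se = math.sqrt(max(fit.cov[j, j], 1e-12))

    def f(v):
        return fit._profile_fn(j, v) - target

    def endpoint(direction: int) -> float:
        width = 1.5 * se if se > 1e-6 else 0.5
        prev = mle  # last point known to be inside the interval
        for _ in range(40):
            v = mle + direction * width
            if f(v) < 0:
                lo, hi = sorted([prev, v])
                return float(optimize.brentq(f, lo, hi, xtol=1e-6))
            prev = v
            width *= 1.7
        return math.copysign(math.inf, direction)

    lo = endpoint(-1)
    hi = endpoint(+1)
    includes_zero = lo <= 0.0 <= hi
    return lo, hi, includes_zero


def _attach_profiles(fit: StageModelFit, names: Sequence[str], level=0.95) -> None:
    for name in names:
        if name in fit.terms:
            try:
                fit.profile_cis[name] = profile_ci(fit, name, level)
            except Exception as exc:  # pragma: no cover - defensive
                fit.profile_cis[name] = (-math.inf, math.inf, True)
                fit.extras.setdefault("profile_failures", []).append(
                    f"{name}: {exc}"
                )


# ---------------------------------------------------------------------------
# design-matrix helpers


def _design(df: pd.DataFrame, terms: list[str], factors: dict[str, str]) -> np.ndarray:
    """Build a design matrix from term names.

    ``factors`` maps a factor column to its reference level; a term
    ``col[level]`` is that level's dummy.  ``a:b`` denotes a product."""
    cols = []
    for t in terms:
        cols.append(_term_column(df, t))
    return np.column_stack(cols)


def _term_column(df: pd.DataFrame, term: str) -> np.ndarray:
    if term == "intercept":
        return np.ones(len(df))
    if ":" in term:
        a, b = term.split(":", 1)
        return _term_column(df, a) * _term_column(df, b)
    if "[" in term:
        col, level = term[:-1].split("[")
        return (df[col].astype(str) == level).to_numpy(dtype=float)
    return df[term].to_numpy(dtype=float)


def _select_best(
    candidates: dict[str, tuple[StageModelFit, int]],
) -> tuple[str, pd.DataFrame]:
    """AICc ranking; ties within 2 units resolved toward fewer parameters."""
    rows = [
        {"tag": tag, "k": fit.k, "loglik": fit.loglik, "aicc": fit.aicc}
        for tag, (fit, _) in candidates.items()
    ]
    table = pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    table["delta_aicc"] = table.aicc - table.aicc.min()
    close = table[table.delta_aicc <= 2.0]
    best_tag = close.sort_values(["k", "aicc"], kind="mergesort").iloc[0]["tag"]
    return str(best_tag), table


def _fit_candidates(
    df: pd.DataFrame,
    successes,
    trials,
    candidates: dict[str, list[str]],
    groups=None,
) -> tuple[StageModelFit, pd.DataFrame]:
    fits: dict[str, tuple[StageModelFit, int]] = {}
    for tag, terms in candidates.items():
        X = _design(df, terms, {})
        if groups is None:
            fit = fit_binomial_glm(X, successes, trials, terms, tag=tag)
        else:
            fit = fit_binomial_glmm(X, successes, trials, groups, terms, tag=tag)
        fits[tag] = (fit, len(terms))
    best_tag, table = _select_best(fits)
    best = fits[best_tag][0]
    best.table = table
    return best, table


# ---------------------------------------------------------------------------
# stage-specific fits


def fit_germination_glm(records: pd.DataFrame, reference: str = "whole_fruit") -> StageModelFit:
    """Nursery germination versus fruit-handling treatment (one species).

    ``records`` has one row per seed with columns ``treatment`` (among
    ``whole_fruit``, ``depulped``, ``ingested``) and ``germinated`` (0/1).
    Fits treatment and intercept-only models, compares them by AICc, and
    attaches profile CIs for contrasts under both the whole-fruit and the
    de-pulped reference levels.
    """
    levels = [t for t in TREATMENTS if t in set(records.treatment)]
    if len(levels) < 2:
        raise ValueError("need at least two treatment levels")
    successes = records.germinated.to_numpy(dtype=float)
    trials = np.ones(len(records))

    def contrast_fit(ref: str) -> StageModelFit:
        terms = ["intercept"] + [f"treatment[{t}]" for t in levels if t != ref]
        X = _design(records, terms, {})
        return fit_binomial_glm(X, successes, trials, terms, tag=f"treatment|ref={ref}")

    candidates = {
        "treatment": ["intercept"] + [f"treatment[{t}]" for t in levels if t != reference],
        "null": ["intercept"],
    }
    best, table = _fit_candidates(records, successes, trials, candidates)

    primary = contrast_fit(reference)
    primary.table = table
    primary.tag = best.tag
    _attach_profiles(primary, [t for t in primary.terms if t != "intercept"])

    other_ref = "depulped" if reference == "whole_fruit" else "whole_fruit"
    if other_ref in levels:
        alt = contrast_fit(other_ref)
        _attach_profiles(alt, [t for t in alt.terms if t != "intercept"])
        primary.extras["alt_reference"] = other_ref
        primary.extras["alt_coefs"] = alt.coef_dict()
        for name, ci in alt.profile_cis.items():
            primary.profile_cis[f"{name}|ref={other_ref}"] = ci
    primary.extras["levels"] = levels
    primary.extras["best_tag"] = best.tag
    return primary


def fit_ingestion_island(traps: pd.DataFrame) -> StageModelFit:
    """Proportion of trapped seeds ingested versus island (GLMM).

    Site enters as a random intercept; the island factor uses Guam as the
    reference level.  Islands with no classified seeds are excluded with a
    warning; an island arm whose every trap has zero ingested seeds (as on
    Guam, where birds are absent) would drive its contrast to -infinity, so
    such structurally-zero arms are dropped from estimation and recorded in
    ``extras['excluded_islands']``.
    """
    df = traps[traps.total_classified > 0].copy()
    skipped = sorted(set(traps.island) - set(df.island))
    if skipped:
        warnings.warn(f"islands with zero classified seeds excluded: {skipped}")
    zero_arms = [
        isl
        for isl, grp in df.groupby("island")
        if grp.ingested_count.sum() == 0
    ]
    df = df[~df.island.isin(zero_arms)].copy()
    islands = sorted(df.island.unique())
    reference = "Guam" if "Guam" in islands else islands[0]
    terms = ["intercept"] + [f"island[{i}]" for i in islands if i != reference]
    candidates = {"island": terms, "null": ["intercept"]}
    best, table = _fit_candidates(
        df,
        df.ingested_count.to_numpy(float),
        df.total_classified.to_numpy(float),
        candidates,
        groups=df.site_id,
    )
    _attach_profiles(best, [t for t in best.terms if t != "intercept"])
    best.extras["excluded_islands"] = zero_arms + skipped
    best.extras["reference"] = reference
    return best


def fit_ingestion_distance(traps: pd.DataFrame) -> StageModelFit:
    """Ingested proportion versus distance to the nearest conspecific on
    the bird islands (Guam excluded), GLMM with site random intercept.

    Fits the full island-by-distance model and all four submodels and
    returns the AICc-best, binomially weighted by the number of classified
    seeds per trap.
    """
    df = traps[(traps.island != "Guam") & (traps.total_classified > 0)].copy()
    if "nearest_conspecific_distance" not in df.columns:
        raise ValueError("traps need a nearest_conspecific_distance column")
    df["distance"] = df.nearest_conspecific_distance
    islands = sorted(df.island.unique())
    isl_terms = [f"island[{i}]" for i in islands[1:]]
    candidates = {
        "island*distance": ["intercept"] + isl_terms + ["distance"]
        + [f"{t}:distance" for t in isl_terms],
        "island+distance": ["intercept"] + isl_terms + ["distance"],
        "island": ["intercept"] + isl_terms,
        "distance": ["intercept", "distance"],
        "null": ["intercept"],
    }
    best, table = _fit_candidates(
        df,
        df.ingested_count.to_numpy(float),
        df.total_classified.to_numpy(float),
        candidates,
        groups=df.site_id,
    )
    _attach_profiles(best, [t for t in best.terms if t != "intercept"])
    best.extras["islands"] = islands
    return best


_SURVIVAL_CANDIDATES = {
    "birds*far+open*far": [
        "intercept", "birds_present", "far", "birds_present:far",
        "openness_c", "openness_c:far",
    ],
    "birds*far+open": [
        "intercept", "birds_present", "far", "birds_present:far", "openness_c",
    ],
    "birds+far+open*far": [
        "intercept", "birds_present", "far", "openness_c", "openness_c:far",
    ],
    "birds+far+open": ["intercept", "birds_present", "far", "openness_c"],
    "birds+far": ["intercept", "birds_present", "far"],
    "far+open": ["intercept", "far", "openness_c"],
    "far": ["intercept", "far"],
    "birds": ["intercept", "birds_present"],
    "null": ["intercept"],
}


def fit_seedling_survival(plots: pd.DataFrame) -> StageModelFit:
    """Outplanted-seedling survival versus bird presence, near/far class
    and canopy openness; site random intercept.

    Reference levels are no-birds (Guam) and 'near'; canopy openness is
    mean-centred before fitting.  The AICc-best model among the candidate
    set (full model with both interactions down to the null) is returned.
    """
    df = plots.copy()
    df["far"] = (df.distance_class.astype(str) == "far").astype(float)
    df["openness_c"] = df.canopy_openness - df.canopy_openness.mean()
    best, table = _fit_candidates(
        df,
        df.n_survived.to_numpy(float),
        df.n_planted.to_numpy(float),
        _SURVIVAL_CANDIDATES,
        groups=df.site_id,
    )
    _attach_profiles(best, [t for t in best.terms if t != "intercept"])
    best.extras["openness_mean"] = float(plots.canopy_openness.mean())
    return best


_FIELD_CANDIDATES_BASE = {
    "far*open+site": ["intercept", "far", "openness_c", "far:openness_c"],
    "far+open+site": ["intercept", "far", "openness_c"],
    "far+open": ["intercept", "far", "openness_c"],
    "far+site": ["intercept", "far"],
    "far": ["intercept", "far"],
    "open": ["intercept", "openness_c"],
    "null": ["intercept"],
}


def fit_field_germination(
    plots: pd.DataFrame, response: str = "n_germinated"
) -> StageModelFit:
    """Seed-addition germination (or early seedling survival) versus
    distance class, canopy openness and site — binomial GLM.

    ``plots`` rows are 50-seed sowing plots with columns ``site_id``,
    ``distance_class``, ``canopy_openness``, ``n_sown`` and the response
    count.  Site enters as a fixed factor (few sites, no random effect
    needed at this stage).  Returns the AICc-best submodel; the distance
    coefficient of the selected model feeds the recruitment integral's
    germination term.
    """
    df = plots.copy()
    df["far"] = (df.distance_class.astype(str) == "far").astype(float)
    df["openness_c"] = df.canopy_openness - df.canopy_openness.mean()
    sites = sorted(df.site_id.unique())
    site_terms = [f"site_id[{s}]" for s in sites[1:]]
    candidates = {}
    for tag, terms in _FIELD_CANDIDATES_BASE.items():
        terms = list(terms)
        if tag.endswith("+site"):
            terms += site_terms
        candidates[tag] = terms
    best, table = _fit_candidates(
        df,
        df[response].to_numpy(float),
        df.n_sown.to_numpy(float),
        candidates,
    )
    _attach_profiles(best, [t for t in best.terms if t != "intercept" and not t.startswith("site_id")])
    best.extras["openness_mean"] = float(plots.canopy_openness.mean())
    best.extras["response"] = response
    return best
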