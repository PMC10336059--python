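"""Bayesian mixed-model inference for behavioral repeatability and syndromes.

`BayesianLMM` fits the univariate Gaussian random-intercept model by Gibbs
sampling and yields the adjusted repeatability

    R = V_ind / (V_ind + V_e)

computed per posterior draw, with 95% credibility intervals after the
confounding fixed effects (trial, body length, sample origin) are
controlled.  Significance follows the DIC rule: the random intercept (or,
for syndromes, the between/within covariances) is removed, the constrained
model refitted, and a DIC increase larger than 2 counts as significant.

`BivariateBayesianLMM` fits paired traits with 2×2 between-individual (G)
and residual (R) covariance matrices, from which the between-individual,
within-individual, and phenotypic correlations

    r_ind = G12 / sqrt(G11 G22)
    r_e   = R12 / sqrt(R11 R22)
    r_p   = (G12 + R12) / sqrt((G11 + R11)(G22 + R22))

are computed per draw — the decomposition used to detect behavioral
syndromes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import gibbs

__all__ = [
    "BayesianLMM",
    "BivariateBayesianLMM",
    "RepeatabilityEstimate",
    "SyndromeEstimate",
    "FTestResult",
    "fit_univariate_lmm",
    "fit_bivariate_lmm",
    "adjusted_repeatability",
    "dic",
    "pmcmc",
    "repeatability_significance",
    "backward_reduce",
    "syndrome_estimate",
    "syndrome_from_draws",
    "variance_f_test",
    "geweke_z",
]

#: Order in which removable fixed terms are considered; also the tie-break
#: order in backward reduction (later-listed term dropped on a DIC tie).
FIXED_TERMS = ("trial", "length", "sample")


def _bci(draws) -> tuple[float, float]:
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return float(lo), float(hi)


@dataclass
class RepeatabilityEstimate:
    """Adjusted repeatability with its credibility interval and DIC test.

    ``r_mean`` is the posterior mean of the per-draw ratio; ``r_plugin``
    the ratio of posterior-mean variances (the two summaries differ
    slightly because the ratio is nonlinear; both are reported).
    """

    r_mean: float
    bci: tuple[float, float]
    r_plugin: float
    r_draws: np.ndarray = field(repr=False, default=None)
    delta_dic: float | None = None
    significant: bool | None = None
    dic: float | None = None
    dic_constrained: float | None = None


@dataclass
class SyndromeEstimate:
    """Between-/within-individual correlation decomposition for a trait pair."""

    traits: tuple[str, str]
    r_ind: float
    r_ind_bci: tuple[float, float]
    r_e: float
    r_e_bci: tuple[float, float]
    r_p: float
    r_p_bci: tuple[float, float]
    delta_dic: float | None = None
    significant: bool | None = None
    dic: float | None = None
    dic_constrained: float | None = None


@dataclass
class FTestResult:
    statistic: float
    pvalue: float
    df: tuple[int, int]
    infinite: bool = False


def adjusted_repeatability(v_ind_draws, v_e_draws=None) -> RepeatabilityEstimate:
    """Per-draw adjusted repeatability R = V_ind / (V_ind + V_e).

    Accepts either a `gibbs.UnivariateDraws` or two arrays of variance
    draws (degenerate single-value arrays reproduce a plug-in ratio).
    """
    if v_e_draws is None:
        v_ind_draws, v_e_draws = v_ind_draws.v_ind, v_ind_draws.v_e
    vi = np.atleast_1d(np.asarray(v_ind_draws, float))
    ve = np.atleast_1d(np.asarray(v_e_draws, float))
    r = vi / (vi + ve)
    plugin = float(vi.mean() / (vi.mean() + ve.mean()))
    return RepeatabilityEstimate(r_mean=float(r.mean()), bci=_bci(r),
                                 r_plugin=plugin, r_draws=r)


def pmcmc(draws) -> float:
    """Two-sided MCMC tail probability of a parameter against zero,
    ``2 * min(P(draw > 0), P(draw < 0))``, floored at 1/n_draws."""
    d = np.asarray(draws, float)
    if d.size < 2:
        raise ValueError("pmcmc needs at least 2 draws")
    frac_pos = np.mean(d > 0)
    frac_neg = np.mean(d < 0)
    return float(max(2.0 * min(frac_pos, frac_neg), 1.0 / d.size))


def geweke_z(draws, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain means."""
    d = np.asarray(draws, float)
    a = d[: max(int(first * d.size), 2)]
    b = d[-max(int(last * d.size), 2):]
    denom = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    return float((a.mean() - b.mean()) / denom) if denom > 0 else 0.0


def _design(data: pd.DataFrame, fixed_terms) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept; continuous covariates mean-centered."""
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for term in fixed_terms:
        if term == "trial":
            v = data["trial"].to_numpy(float)
            cols.append(v - v.mean())
        elif term == "length":
            v = data["length_cm"].to_numpy(float)
            cols.append(v - v.mean())
        elif term == "sample":
            cols.append((data["sample"].to_numpy() == "reared").astype(float))
        else:
            raise ValueError(f"unknown fixed term {term!r}")
        names.append(term)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify offending columns via vanishing R diagonal of the QR
        diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = [n for n, d in zip(names, diag) if d < 1e-8 * max(diag.max(), 1.0)]
        raise ValueError(f"singular fixed-effect design; collinear column(s): {bad}")
    return X, names


def _check_response(y: np.ndarray) -> None:
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    if y.var() == 0:
        raise ValueError("response has zero variance")


class BayesianLMM(BaseEstimator):
    """Univariate Gaussian mixed model fitted by Gibbs sampling.

    Parameters
    ----------
    response : str
        Column of the long-format table holding the trait values.
    fixed_terms : sequence of {"trial", "length", "sample"}
        Fixed effects besides the (always present) intercept.  Trial and
        body length enter mean-centered; sample as a reared indicator.
    include_random : bool
        Include the individual random intercept; ``False`` gives the
        constrained model used as the DIC reference for repeatability.
    n_iter, burn_in, thin : int
        Chain settings; defaults 13,000 / 3,000 / 10.
    beta_prior_var, prior_scale, prior_df : float
        N(0, ``beta_prior_var``) prior on fixed effects and scaled
        inverse-chi-square(``prior_df``, ``prior_scale``) on variances.
    random_state : int
        Chain seed; fits are bit-reproducible given it.

    Attributes
    ----------
    beta_draws_ : DataFrame of retained fixed-effect draws.
    v_ind_draws_, v_e_draws_, deviance_draws_ : ndarray
    dic_, pd_, dbar_ : float — DIC = Dbar + pD with pD = Dbar − D(posterior
        means), the deviance being conditional on the random effects.
    """

    def __init__(self, response="value", fixed_terms=FIXED_TERMS,
                 include_random=True, n_iter=13000, burn_in=3000, thin=10,
                 beta_prior_var=1e10, prior_scale=1.0, prior_df=0.002,
                 random_state=0, check_convergence=True):
        self.response = response
        self.fixed_terms = fixed_terms
        self.include_random = include_random
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.beta_prior_var = beta_prior_var
        self.prior_scale = prior_scale
        self.prior_df = prior_df
        self.random_state = random_state
        self.check_convergence = check_convergence

    def fit(self, data: pd.DataFrame, y=None):
        y_arr = data[self.response].to_numpy(float)
        _check_response(y_arr)
        groups, labels = pd.factorize(data["id"])
        if self.include_random:
            sizes = np.bincount(groups)
            if len(labels) < 2 or sizes.max() < 2:
                raise ValueError("need >= 2 observations for >= 2 individuals")
        X, names = _design(data, self.fixed_terms)
        draws = gibbs.gibbs_univariate(
            y_arr, X, groups, n_iter=self.n_iter, burn_in=self.burn_in,
            thin=self.thin, beta_prior_var=self.beta_prior_var,
            prior_scale=self.prior_scale, prior_df=self.prior_df,
            include_random=self.include_random, seed=self.random_state)
        self.terms_ = names
        self.group_labels_ = labels
        self.draws_ = draws
        self.beta_draws_ = pd.DataFrame(draws.beta, columns=names)
        self.v_ind_draws_ = draws.v_ind
        self.v_e_draws_ = draws.v_e
        self.deviance_draws_ = draws.deviance
        self.u_mean_ = draws.u_mean
        self.dbar_ = float(draws.deviance.mean())
        d_hat = gibbs.deviance_univariate(
            y_arr, X, groups, draws.beta.mean(axis=0),
            draws.u_mean if self.include_random else None,
            float(draws.v_e.mean()))
        self.pd_ = self.dbar_ - d_hat
        self.dic_ = self.dbar_ + self.pd_
        self.n_obs_ = len(y_arr)
        if self.check_convergence:
            for name, d in (("v_e", draws.v_e),
                            ("v_ind", draws.v_ind if self.include_random else None)):
                if d is not None and abs(geweke_z(d)) >= 2.0:
                    warnings.warn(f"Geweke |z| >= 2 for {name}: chain may not "
                                  "have converged", UserWarning, stacklevel=2)
        return self

    def repeatability(self) -> RepeatabilityEstimate:
        check_is_fitted(self, "v_ind_draws_")
        if not self.include_random:
            raise ValueError("repeatability requires the random intercept")
        return adjusted_repeatability(self.v_ind_draws_, self.v_e_draws_)

    def pmcmc(self, term: str) -> float:
        check_is_fitted(self, "beta_draws_")
        return pmcmc(self.beta_draws_[term].to_numpy())

    def summary(self) -> pd.DataFrame:
        """Posterior means, 95% BCIs and pMCMC per fixed effect, plus the
        variance components — one row per parameter, Table-style."""
        check_is_fitted(self, "beta_draws_")
        rows = []
        for term in self.terms_:
            d = self.beta_draws_[term].to_numpy()
            lo, hi = _bci(d)
            rows.append({"parameter": term, "post_mean": d.mean(),
                         "l_bci": lo, "u_bci": hi, "pmcmc": pmcmc(d)})
        for name, d in (("V_ind", self.v_ind_draws_), ("V_e", self.v_e_draws_)):
            if name == "V_ind" and not self.include_random:
                continue
            lo, hi = _bci(d)
            rows.append({"parameter": name, "post_mean": d.mean(),
                         "l_bci": lo, "u_bci": hi, "pmcmc": np.nan})
        return pd.DataFrame(rows)


class BivariateBayesianLMM(BaseEstimator):
    """Paired-trait Gaussian mixed model with 2×2 G and R covariances.

    ``fit`` takes the long-format table and pivots the two traits named in
    ``responses`` onto shared (id, trial) rows.  ``constrained=True``
    zeroes both covariances (the DIC reference model for syndrome
    detection).  Chain defaults are the longer paired-trait settings:
    100,000 iterations, 10,000 burn-in, thinning 100.
    """

    def __init__(self, responses=("trait", "trait_b"), fixed_terms=FIXED_TERMS,
                 constrained=False, n_iter=100000, burn_in=10000, thin=100,
                 beta_prior_var=1e10, prior_scale=None, prior_df=1.002,
                 random_state=0):
        self.responses = responses
        self.fixed_terms = fixed_terms
        self.constrained = constrained
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.beta_prior_var = beta_prior_var
        self.prior_scale = prior_scale
        self.prior_df = prior_df
        self.random_state = random_state

    def _pivot(self, data: pd.DataFrame) -> pd.DataFrame:
        t1, t2 = self.responses
        value_col = "value" if "value" in data.columns else "score_lmm"
        trait_col = "trait" if "trait" in data.columns else "axis"
        keep = [c for c in ("sample", "length_cm") if c in data.columns]
        wide = data.pivot_table(index=["id", "trial"] + keep, columns=trait_col,
                                values=value_col, aggfunc="first").reset_index()
        if t1 not in wide.columns or t2 not in wide.columns:
            raise ValueError(f"traits {self.responses} not both present")
        return wide.dropna(subset=[t1, t2])

    def fit(self, data: pd.DataFrame, y=None):
        wide = self._pivot(data)
        t1, t2 = self.responses
        Y = wide[[t1, t2]].to_numpy(float)
        for j in range(2):
            _check_response(Y[:, j])
        groups, labels = pd.factorize(wide["id"])
        X, names = _design(wide, self.fixed_terms)
        draws = gibbs.gibbs_bivariate(
            Y, X, groups, n_iter=self.n_iter, burn_in=self.burn_in,
            thin=self.thin, beta_prior_var=self.beta_prior_var,
            prior_scale=self.prior_scale, prior_df=self.prior_df,
            constrained=self.constrained, seed=self.random_state)
        self.terms_ = names
        self.group_labels_ = labels
        self.draws_ = draws
        self.beta_draws_ = draws.beta
        self.G_draws_ = draws.G
        self.R_draws_ = draws.R
        self.deviance_draws_ = draws.deviance
        self.dbar_ = float(draws.deviance.mean())
        d_hat = gibbs.deviance_bivariate(Y, X, groups, draws.beta.mean(axis=0),
                                         draws.u_mean, draws.R.mean(axis=0))
        self.pd_ = self.dbar_ - d_hat
        self.dic_ = self.dbar_ + self.pd_
        self.n_obs_ = len(Y)
        return self

    def correlations(self) -> SyndromeEstimate:
        check_is_fitted(self, "G_draws_")
        return syndrome_from_draws(self.G_draws_, self.R_draws_,
                                   traits=tuple(self.responses))


def fit_univariate_lmm(data, **params) -> BayesianLMM:
    """Fit the univariate mixed model; returns the fitted estimator whose
    trailing-underscore attributes hold the posterior draws."""
    return BayesianLMM(**params).fit(data)


def fit_bivariate_lmm(data, **params) -> BivariateBayesianLMM:
    return BivariateBayesianLMM(**params).fit(data)


def dic(model) -> float:
    """Deviance information criterion of a fitted model.

    DIC = Dbar + pD with pD = Dbar − D(posterior means); the deviance is
    conditional on the random effects (individual-level focus).
    """
    check_is_fitted(model, "dic_")
    return float(model.dic_)


def repeatability_significance(data, *, response="value",
                               fixed_terms=FIXED_TERMS, random_state=0,
                               **mcmc) -> RepeatabilityEstimate:
    """Adjusted repeatability with its DIC significance test.

    Fits the full model and the constrained one (random intercept removed,
    V_ind = 0); ΔDIC = DIC_constrained − DIC_full, significant when > 2.
    """
    full = BayesianLMM(response=response, fixed_terms=fixed_terms,
                       include_random=True, random_state=random_state,
                       **mcmc).fit(data)
    constrained = BayesianLMM(response=response, fixed_terms=fixed_terms,
                              include_random=False,
                              random_state=random_state + 1, **mcmc).fit(data)
    est = full.repeatability()
    est.dic = full.dic_
    est.dic_constrained = constrained.dic_
    est.delta_dic = constrained.dic_ - full.dic_
    est.significant = bool(est.delta_dic > 2.0)
    return est


def backward_reduce(data, *, response="value", fixed_terms=FIXED_TERMS,
                    random_state=0, tie_tol=0.01,
                    **mcmc) -> tuple[tuple[str, ...], pd.DataFrame]:
    """Step-by-step backward reduction of fixed effects by DIC.

    At each step the removable term whose removal lowers DIC most is
    dropped; the search stops when no removal lowers DIC.  The intercept
    and the random intercept are never candidates.  Ties within
    ``tie_tol`` drop the later-listed term (deterministic).  Returns the
    retained terms and a history of every candidate fit.
    """
    terms = list(fixed_terms)
    seed = random_state
    history = []

    def _fit(t, s):
        return BayesianLMM(response=response, fixed_terms=tuple(t),
                           random_state=s, **mcmc).fit(data).dic_

    current_dic = _fit(terms, seed)
    history.append({"step": 0, "removed": None, "terms": tuple(terms),
                    "dic": current_dic})
    step = 0
    while terms:
        step += 1
        candidates = []
        for term in terms:
            seed += 1
            reduced = [t for t in terms if t != term]
            candidates.append((term, _fit(reduced, seed)))
            history.append({"step": step, "removed": term,
                            "terms": tuple(reduced), "dic": candidates[-1][1]})
        best_dic = min(d for _, d in candidates)
        if best_dic >= current_dic:
            break
        tied = [t for t, d in candidates if d <= best_dic + tie_tol]
        drop = max(tied, key=lambda t: list(fixed_terms).index(t))
        terms.remove(drop)
        current_dic = dict(candidates)[drop]
    return tuple(terms), pd.DataFrame(history)


def syndrome_from_draws(G_draws, R_draws, traits=("trait_1", "trait_2")) -> SyndromeEstimate:
    """Correlation decomposition from per-draw G and R matrices.

    r_p is computed from the summed covariances per draw, so it equals the
    direct formula evaluation draw by draw.
    """
    G = np.asarray(G_draws, float).reshape(-1, 2, 2)
    R = np.asarray(R_draws, float).reshape(-1, 2, 2)
    r_ind = G[:, 0, 1] / np.sqrt(G[:, 0, 0] * G[:, 1, 1])
    r_e = R[:, 0, 1] / np.sqrt(R[:, 0, 0] * R[:, 1, 1])
    P = G + R
    r_p = P[:, 0, 1] / np.sqrt(P[:, 0, 0] * P[:, 1, 1])
    return SyndromeEstimate(
        traits=tuple(traits),
        r_ind=float(r_ind.mean()), r_ind_bci=_bci(r_ind),
        r_e=float(r_e.mean()), r_e_bci=_bci(r_e),
        r_p=float(r_p.mean()), r_p_bci=_bci(r_p))


def syndrome_estimate(data, *, responses, fixed_terms=FIXED_TERMS,
                      random_state=0, **mcmc) -> SyndromeEstimate:
    """Full syndrome test for one trait pair: bivariate fit, constrained
    (zero-covariance) refit, and the ΔDIC > 2 significance rule."""
    full = BivariateBayesianLMM(responses=responses, fixed_terms=fixed_terms,
                                constrained=False, random_state=random_state,
                                **mcmc).fit(data)
    constrained = BivariateBayesianLMM(responses=responses,
                                       fixed_terms=fixed_terms,
                                       constrained=True,
                                       random_state=random_state + 1,
                                       **mcmc).fit(data)
    est = full.correlations()
    est.dic = full.dic_
    est.dic_constrained = constrained.dic_
    est.delta_dic = constrained.dic_ - full.dic_
    est.significant = bool(est.delta_dic > 2.0)
    return est


def variance_f_test(values_a, values_b) -> FTestResult:
    """Two-sided F-test for equality of two sample variances.

    F is the larger sample variance over the smaller; the two-sided p
    doubles the upper tail of F(n−1, m−1) with the larger-variance group's
    df first.  Used on per-individual mean trait values per sample.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va >= vb:
        num, den, df = va, vb, (a.size - 1, b.size - 1)
    else:
        num, den, df = vb, va, (b.size - 1, a.size - 1)
    if den == 0:
        return FTestResult(statistic=np.inf, pvalue=0.0, df=df, infinite=True)
    F = num / den
    p = min(1.0, 2.0 * float(stats.f.sf(F, *df)))
    return FTestResult(statistic=float(F), pvalue=p, df=df)
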