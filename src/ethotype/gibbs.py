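"""Conjugate Gibbs samplers for Gaussian mixed models with an individual
random intercept.

Univariate model:  y_ij = x_ij' b + u_i + e_ij,
    u_i ~ N(0, s2_u),  e_ij ~ N(0, s2_e)
Bivariate model:   y_ij (2-vector) = B' x_ij + u_i + e_ij,
    u_i ~ N2(0, G),  e_ij ~ N2(0, R)

Priors follow the conventional flat/uninformative structure for this model
class: independent N(0, 1e10) on fixed effects and inverse-Wishart
(scale = identity, df = dim - 1 + 0.002) on each (co)variance — for a
scalar variance that is the scaled inverse-chi-square with 0.002 degrees
of freedom.  All full conditionals are conjugate: Gaussian for fixed
effects and random intercepts, inverse-chi-square / inverse-Wishart for
the variances, so the chain is a pure Gibbs sweep with no tuning.

Each retained draw also stores the model deviance (−2 log-likelihood
conditional on the random effects), from which the deviance information
criterion is computed downstream.  Samplers are deterministic given the
integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["UnivariateDraws", "BivariateDraws", "gibbs_univariate", "gibbs_bivariate"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class UnivariateDraws:
    beta: np.ndarray        # (S, p)
    v_ind: np.ndarray       # (S,) — zeros when the random term is excluded
    v_e: np.ndarray         # (S,)
    deviance: np.ndarray    # (S,)
    u_mean: np.ndarray      # (q,) posterior mean of random intercepts
    include_random: bool


@dataclass
class BivariateDraws:
    beta: np.ndarray        # (S, p, 2)
    G: np.ndarray           # (S, 2, 2) between-individual covariance
    R: np.ndarray           # (S, 2, 2) residual covariance
    deviance: np.ndarray    # (S,)
    u_mean: np.ndarray      # (q, 2)


def _n_retained(n_iter: int, burn_in: int, thin: int) -> int:
    if not 0 <= burn_in < n_iter:
        raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    return len(range(burn_in, n_iter)[::thin])


def gibbs_univariate(y, X, groups, *, n_iter=13000, burn_in=3000, thin=10,
                     beta_prior_var=1e10, prior_scale=1.0, prior_df=0.002,
                     include_random=True, seed=0) -> UnivariateDraws:
    """Gibbs chain for the univariate random-intercept model.

    ``groups`` are integer individual indices in ``[0, q)``.  Defaults are
    the univariate MCMC settings used throughout: 13,000 iterations, the
    first 3,000 discarded, thinning interval 10 (1,000 retained draws).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    g = np.asarray(groups, int)
    n, p = X.shape
    q = int(g.max()) + 1 if include_random else 0
    rng = np.random.default_rng(seed)

    XtX = X.T @ X
    counts = np.bincount(g, minlength=q).astype(float) if include_random else None

    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid0 = y - X @ beta
    s2_e = max(float(resid0.var()), 1e-8)
    s2_u = s2_e if include_random else 0.0
    u = np.zeros(q)

    S = _n_retained(n_iter, burn_in, thin)
    out_beta = np.empty((S, p))
    out_vu = np.zeros(S)
    out_ve = np.empty(S)
    out_dev = np.empty(S)
    u_acc = np.zeros(q)
    eye_p = np.eye(p)

    k = 0
    for it in range(n_iter):
        # fixed effects | u, s2_e
        r = y - u[g] if include_random else y
        P = XtX / s2_e + eye_p / beta_prior_var
        L = np.linalg.cholesky(P)
        mean = np.linalg.solve(P, X.T @ r / s2_e)
        beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))
        res = y - X @ beta

        if include_random:
            # random intercepts | beta, variances (independent Gaussians)
            s_i = np.bincount(g, weights=res, minlength=q)
            var_i = 1.0 / (counts / s2_e + 1.0 / s2_u)
            u = var_i * s_i / s2_e + np.sqrt(var_i) * rng.standard_normal(q)
            # between-individual variance | u
            s2_u = (prior_df * prior_scale + u @ u) / rng.chisquare(prior_df + q)
            e = res - u[g]
        else:
            e = res
        # residual variance | everything
        sse = e @ e
        s2_e = (prior_df * prior_scale + sse) / rng.chisquare(prior_df + n)

        if it >= burn_in and (it - burn_in) % thin == 0:
            out_beta[k] = beta
            out_ve[k] = s2_e
            if include_random:
                out_vu[k] = s2_u
                u_acc += u
            out_dev[k] = n * (_LOG2PI + np.log(s2_e)) + sse / s2_e
            k += 1
    return UnivariateDraws(out_beta, out_vu, out_ve, out_dev,
                           u_acc / max(S, 1), include_random)


def _inv2(M):
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    return np.array([[M[1, 1], -M[0, 1]], [-M[1, 0], M[0, 0]]]) / det


def _rinvwishart2(rng, df: float, scale: np.ndarray) -> np.ndarray:
    """Draw from the 2x2 inverse-Wishart(scale, df) via Bartlett decomposition."""
    L = np.linalg.cholesky(_inv2(scale))
    A = np.zeros((2, 2))
    A[0, 0] = np.sqrt(rng.chisquare(df))
    A[1, 1] = np.sqrt(rng.chisquare(df - 1.0))
    A[1, 0] = rng.standard_normal()
    W = L @ A
    W = W @ W.T
    return _inv2(W)


def gibbs_bivariate(Y, X, groups, *, n_iter=100000, burn_in=10000, thin=100,
                    beta_prior_var=1e10, prior_scale=None, prior_df=1.002,
                    constrained=False, seed=0) -> BivariateDraws:
    """Gibbs chain for the bivariate (paired-trait) random-intercept model.

    ``constrained=True`` fixes the off-diagonals of both G and R at zero
    (the no-covariance model used as the DIC reference when testing for a
    behavioral syndrome); diagonal variances then update by independent
    inverse-chi-squares with the same marginal prior df.  Defaults are the
    paired-trait chain settings: 100,000 iterations, 10,000 burn-in,
    thinning 100 (900 retained draws).
    """
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    g = np.asarray(groups, int)
    n, p = X.shape
    q = int(g.max()) + 1
    rng = np.random.default_rng(seed)
    V0 = np.eye(2) if prior_scale is None else np.asarray(prior_scale, float)
    if np.any(np.linalg.eigvalsh(V0) <= 0):
        raise ValueError("variance prior scale matrix must be positive-definite")

    XtX = X.T @ X
    counts = np.bincount(g, minlength=q).astype(float)
    uniq_counts = np.unique(counts)

    B = np.linalg.lstsq(X, Y, rcond=None)[0]
    E0 = Y - X @ B
    R = np.cov(E0, rowvar=False, ddof=1) + 1e-8 * np.eye(2)
    if constrained:
        R = np.diag(np.diag(R))
    G = R.copy()
    U = np.zeros((q, 2))

    S = _n_retained(n_iter, burn_in, thin)
    out_B = np.empty((S, p, 2))
    out_G = np.empty((S, 2, 2))
    out_R = np.empty((S, 2, 2))
    out_dev = np.empty(S)
    u_acc = np.zeros((q, 2))
    eye2p = np.eye(2 * p)

    k = 0
    for it in range(n_iter):
        Rinv = _inv2(R)
        # fixed effects | U, R : vec(B) is Gaussian with kron precision
        M = Y - U[g]
        P = np.kron(Rinv, XtX) + eye2p / beta_prior_var
        L = np.linalg.cholesky(P)
        b = np.ravel(X.T @ M @ Rinv, order="F")
        mean = np.linalg.solve(P, b)
        vecB = mean + np.linalg.solve(L.T, rng.standard_normal(2 * p))
        B = vecB.reshape((p, 2), order="F")

        # random intercepts | B, G, R (2x2 Gaussian per individual)
        M = Y - X @ B
        Sg = np.column_stack([np.bincount(g, weights=M[:, j], minlength=q)
                              for j in range(2)])
        Ginv = _inv2(G)
        SR = Sg @ Rinv.T
        for c in uniq_counts:  # shared posterior covariance per group size
            Lam = c * Rinv + Ginv
            Sig = _inv2(Lam)
            Lu = np.linalg.cholesky(Sig)
            sel = counts == c
            mu_u = SR[sel] @ Sig.T
            U[sel] = mu_u + rng.standard_normal((int(sel.sum()), 2)) @ Lu.T

        # G | U   and   R | residuals
        Su = U.T @ U
        if constrained:
            G = np.diag([(prior_df * V0[j, j] + Su[j, j])
                         / rng.chisquare(prior_df + q) for j in range(2)])
        else:
            G = _rinvwishart2(rng, prior_df + q, V0 + Su)
        E = M - U[g]
        Se = E.T @ E
        if constrained:
            R = np.diag([(prior_df * V0[j, j] + Se[j, j])
                         / rng.chisquare(prior_df + n) for j in range(2)])
        else:
            R = _rinvwishart2(rng, prior_df + n, V0 + Se)

        if it >= burn_in and (it - burn_in) % thin == 0:
            out_B[k] = B
            out_G[k] = G
            out_R[k] = R
            Rinv = _inv2(R)
            logdet = np.log(R[0, 0] * R[1, 1] - R[0, 1] * R[1, 0])
            out_dev[k] = n * (2.0 * _LOG2PI + logdet) + float(np.sum(E @ Rinv * E))
            u_acc += U
            k += 1
    return BivariateDraws(out_B, out_G, out_R, out_dev, u_acc / max(S, 1))


def deviance_univariate(y, X, groups, beta, u, s2_e) -> float:
    """−2 Gaussian log-likelihood conditional on the random effects."""
    y = np.asarray(y, float)
    e = y - np.asarray(X, float) @ beta
    if u is not None and len(u):
        e = e - u[np.asarray(groups, int)]
    return float(len(y) * (_LOG2PI + np.log(s2_e)) + (e @ e) / s2_e)


def deviance_bivariate(Y, X, groups, B, U, R) -> float:
    Y = np.asarray(Y, float)
    E = Y - np.asarray(X, float) @ B - U[np.asarray(groups, int)]
    Rinv = _inv2(R)
    logdet = np.log(R[0, 0] * R[1, 1] - R[0, 1] * R[1, 0])
    return float(len(Y) * (2.0 * _LOG2PI + logdet) + np.sum(E @ Rinv * E))
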