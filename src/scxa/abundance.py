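"""Genotype effects on relative cell-type abundance.

Each contrast reduces cells to a binary outcome (e.g. germline vs cyst) and
fits a random-intercept logistic model, outcome ~ treatment + (1|sample),
by Laplace-approximated maximum likelihood (cells collapse to one binomial
observation per sample since covariates are sample-level). A 15-node
adaptive Gauss-Hermite fit is available as a cross-check, and a
boundary estimate of the random-effect standard deviation (sigma_u = 0)
falls back to ordinary logistic regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .config import GERMLINE_STAGES, HAPLOID_TYPES, SOMATIC_TYPES

__all__ = ["AbundanceFit", "CONTRASTS", "build_contrast", "fit_binomial_glmm", "BinomialGLMM"]

#: contrast name -> (class coded 1, class coded 0); secondary spermatocytes
#: are meiotically active and excluded from the pre/post-meiotic contrast
CONTRASTS = {
    "germline-vs-cyst": (
        set(GERMLINE_STAGES),
        {"early_cyst", "late_cyst"},
    ),
    "early-vs-late-cyst": ({"early_cyst"}, {"late_cyst"}),
    "premeiotic-vs-postmeiotic": (
        {"gsc_spermatogonia", "primary_spermatocytes"},
        set(HAPLOID_TYPES),
    ),
}


@dataclass
class AbundanceFit:
    contrast: str
    beta_treatment: float
    se: float
    p: float
    sigma_u: float
    beta_intercept: float
    n_cells: int
    n_samples: int
    converged: bool
    method: str

    def ci(self, level: float = 0.95) -> tuple:
        """Confidence interval for the treatment log-odds.

        Uses a t quantile with ``n_samples - 2`` degrees of freedom: the
        effective replication is the sample, and with few samples the ML
        estimate of sigma_u is biased low, so a normal quantile undercovers.
        """
        df = max(self.n_samples - 2, 1)
        q = stats.t.ppf(0.5 + level / 2, df)
        return (self.beta_treatment - q * self.se, self.beta_treatment + q * self.se)


def build_contrast(cell_types, contrast: str, mapping: dict | None = None):
    """Binary outcome vector for a named contrast; unmapped cells get NaN.

    Returns ``(outcome, keep_mask)`` where outcome is 1 for the contrast's
    first class and 0 for the second.
    """
    table = mapping or CONTRASTS
    if contrast not in table:
        raise ValueError(f"unknown contrast {contrast!r}; have {sorted(table)}")
    ones, zeros = (set(x) for x in table[contrast])
    ct = pd.Series(np.asarray(cell_types, dtype=object))
    outcome = np.where(ct.isin(ones), 1.0, np.where(ct.isin(zeros), 0.0, np.nan))
    keep = ~np.isnan(outcome)
    if outcome[keep].size == 0 or len(np.unique(outcome[keep])) < 2:
        raise ValueError(f"a contrast class is empty for {contrast!r}")
    return outcome, keep


def _collapse(outcome, treatment, sample):
    df = pd.DataFrame({"y": outcome, "treat": treatment, "sample": sample})
    g = df.groupby("sample", observed=True)
    k = g["y"].sum().to_numpy()
    n = g["y"].count().to_numpy()
    t = g["treat"].first().to_numpy()
    if df.groupby("sample", observed=True)["treat"].nunique().max() > 1:
        raise ValueError("treatment must be constant within sample")
    return k, n, t


def _binll(k, n, eta):
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return k * np.log(p) + (n - k) * np.log(1 - p)


def _mode_per_sample(k, n, eta0, sigma2, n_iter: int = 50):
    """Posterior mode and curvature of each sample's random intercept."""
    u = np.zeros_like(eta0)
    for _ in range(n_iter):
        p = 1.0 / (1.0 + np.exp(-(eta0 + u)))
        grad = (k - n * p) - u / sigma2
        hess = -(n * p * (1 - p)) - 1.0 / sigma2
        step = grad / hess
        u = u - step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = 1.0 / (1.0 + np.exp(-(eta0 + u)))
    curv = n * p * (1 - p) + 1.0 / sigma2  # -d2/du2 at the mode
    return u, curv


def _neg_marginal_ll(params, k, n, t, method: str, gh_nodes: int = 15):
    b0, b1, log_sigma = params
    sigma = np.exp(log_sigma)
    sigma2 = sigma**2
    eta0 = b0 + b1 * t
    u_hat, curv = _mode_per_sample(k, n, eta0, sigma2)
    if method == "laplace":
        ll = (
            _binll(k, n, eta0 + u_hat)
            - 0.5 * u_hat**2 / sigma2
            - 0.5 * np.log(sigma2)
            + 0.5 * np.log(2 * np.pi)  # from the normal density...
            - 0.5 * np.log(2 * np.pi)  # ...cancelled by the Laplace factor
            - 0.5 * np.log(curv)
        )
        return -float(ll.sum())
    # adaptive Gauss-Hermite centred at the mode, scaled by the curvature
    z, w = hermegauss(gh_nodes)  # weights for exp(-z^2/2)
    s = 1.0 / np.sqrt(curv)
    ll = np.zeros(len(k))
    for i in range(len(k)):
        u = u_hat[i] + s[i] * z
        integrand = (
            _binll(k[i], n[i], eta0[i] + u)
            - 0.5 * u**2 / sigma2
            + 0.5 * z**2  # undo the hermegauss kernel
        )
        m = integrand.max()
        ll[i] = m + np.log(np.sum(w * np.exp(integrand - m))) + np.log(s[i]) - 0.5 * np.log(
            2 * np.pi * sigma2
        )
    return -float(ll.sum())


def _reml_penalty(params, k, n, t):
    """Half log-det of the fixed-effects information (REML adjustment).

    Uses the Gaussian group-level approximation: each sample contributes
    weight 1 / (sigma^2 + 1 / (n p (1-p))) evaluated at its conditional
    mode, which corrects the downward small-group bias of the ML sigma_u.
    """
    b0, b1, log_sigma = params
    sigma2 = max(np.exp(2 * log_sigma), 1e-12)
    eta0 = b0 + b1 * t
    u, _ = _mode_per_sample(k, n, eta0, sigma2)
    p = 1.0 / (1.0 + np.exp(-(eta0 + u)))
    w = 1.0 / (sigma2 + 1.0 / np.maximum(n * p * (1 - p), 1e-12))
    X = np.column_stack([np.ones_like(t), t])
    sign, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
    return 0.5 * logdet if sign > 0 else 10.0


def fit_binomial_glmm(
    outcome,
    treatment,
    sample,
    contrast: str = "custom",
    method: str = "laplace",
    gh_nodes: int = 15,
    reml: bool = True,
) -> AbundanceFit:
    """Random-intercept logistic fit of a binary outcome on treatment.

    ``treatment`` is 0/1 (or ST/SR) per cell; ``sample`` the grouping
    factor. Wald z p-value for the treatment log-odds; ``reml`` (default)
    applies the restricted-likelihood adjustment when estimating sigma_u.
    If the sigma_u estimate collapses to the boundary the model reduces to
    ordinary logistic regression (reported via ``method='logistic'``).
    """
    treatment = np.asarray(
        [1.0 if str(v) in ("1", "1.0", "SR") else 0.0 for v in np.asarray(treatment)]
    )
    k, n, t = _collapse(np.asarray(outcome, dtype=float), treatment, sample)
    if min((t == 0).sum(), (t == 1).sum()) < 2:
        raise ValueError("need >= 2 samples per treatment")

    p_bar = np.clip(k.sum() / n.sum(), 1e-6, 1 - 1e-6)
    x0 = np.array([np.log(p_bar / (1 - p_bar)), 0.0, np.log(0.3)])
    nll = lambda th: _neg_marginal_ll(th, k, n, t, method, gh_nodes)
    if reml:
        obj = lambda th: nll(th) + _reml_penalty(th, k, n, t)
    else:
        obj = nll
    res = optimize.minimize(obj, x0, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    polish = optimize.minimize(obj, res.x, method="BFGS", options={"gtol": 1e-7})
    if polish.fun <= res.fun:  # keep the better optimum; BFGS may flag
        res, converged_opt = polish, True  # precision loss at convergence
    else:
        converged_opt = bool(res.success)
    b0, b1, log_sigma = res.x
    sigma = float(np.exp(log_sigma))
    used = method

    if sigma < 1e-3:  # boundary: plain logistic
        used = "logistic"
        sigma = 0.0

        def nll_fixed(th):
            return -float(_binll(k, n, th[0] + th[1] * t).sum())

        r2 = optimize.minimize(nll_fixed, np.array([b0, b1]), method="BFGS")
        b0, b1 = r2.x
        h = _num_hessian(nll_fixed, r2.x)
        cov = np.linalg.inv(h)
        se = float(np.sqrt(cov[1, 1]))
        converged = bool(r2.success)
    else:
        h = _num_hessian(nll, res.x)  # SE from the unpenalized information
        try:
            cov = np.linalg.inv(h)
            se = float(np.sqrt(max(cov[1, 1], 0.0)))
        except np.linalg.LinAlgError:
            se = float("nan")
        converged = converged_opt
    if not converged:
        warnings.warn("GLMM optimizer reported non-convergence")
    z = b1 / se if se > 0 else 0.0
    return AbundanceFit(
        contrast=contrast,
        beta_treatment=float(b1),
        se=se,
        p=float(2 * stats.norm.sf(abs(z))),
        sigma_u=sigma,
        beta_intercept=float(b0),
        n_cells=int(n.sum()),
        n_samples=len(n),
        converged=converged,
        method=used,
    )


def _num_hessian(f, x, eps: float = 1e-4):
    d = len(x)
    H = np.zeros((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = eps
            ej = np.zeros(d); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps**2)
    return H


def abundance_analysis(obs: pd.DataFrame, contrasts=None, method: str = "laplace") -> pd.DataFrame:
    """Fit every contrast on a cell table with genotype/sample_id/cell_type."""
    results = []
    for name in contrasts or CONTRASTS:
        outcome, keep = build_contrast(obs["cell_type"].to_numpy(), name)
        fit = fit_binomial_glmm(
            outcome[keep],
            obs["genotype"].to_numpy()[keep],
            obs["sample_id"].to_numpy()[keep],
            contrast=name,
            method=method,
        )
        results.append(fit.__dict__)
    return pd.DataFrame(results)


class BinomialGLMM(BaseEstimator):
    """Estimator form of the random-intercept logistic model.

    ``fit(X, y, groups=...)`` with X a 1-column treatment indicator.
    """

    def __init__(self, method: str = "laplace", gh_nodes: int = 15):
        self.method = method
        self.gh_nodes = gh_nodes

    def fit(self, X, y, groups=None):
        if groups is None:
            raise ValueError("groups (sample ids) required")
        X = np.asarray(X).reshape(len(y), -1)
        fit = fit_binomial_glmm(
            y, X[:, 0], groups, method=self.method, gh_nodes=self.gh_nodes
        )
        self.fit_ = fit
        self.coef_ = np.array([fit.beta_treatment])
        self.intercept_ = fit.beta_intercept
        self.sigma_u_ = fit.sigma_u
        return self
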