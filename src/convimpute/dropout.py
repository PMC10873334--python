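"""Dropout-probability model: per-(gene, cluster) gamma-normal mixture.

Within one cell cluster, the log-space expression of a gene is modelled as a
two-component mixture

    f(x) = eta * Gamma(x; alpha, beta) + (1 - eta) * Normal(x; mu, sigma)

where the gamma component (shape ``alpha``, rate ``beta``) captures
dropout-depressed values piled up near zero and the normal component
captures genuinely expressed values.  The mixture is fitted by EM and the
posterior weight of the gamma component at an observed value is the
dropout probability

    DP = eta * Gamma(x) / (eta * Gamma(x) + (1 - eta) * Normal(x)).

Exact zeros (log1p of a zero count) are evaluated at a small positive
offset so they inform the dropout weight despite the gamma density's
singularity at 0 when alpha < 1.

The per-iteration M-step uses responsibility-weighted method-of-moments for
the gamma parameters; because that update is not an exact maximiser, it is
accepted only when the observed-data log-likelihood does not decrease
(otherwise the previous gamma parameters are retained for the iteration),
which makes the likelihood monotone non-decreasing by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .clustering import CellClustering
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

EPS_ZERO = 1e-10  # offset at which exact zeros are evaluated
_TINY = 1e-300


@dataclass
class GammaNormalParams:
    """Fitted mixture parameters for one gene in one cluster."""

    eta: float
    alpha: float
    beta: float
    mu: float
    sigma: float
    converged: bool = True
    n_obs: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError("eta must lie in [0, 1]")
        if min(self.alpha, self.beta, self.sigma) <= 0:
            raise ValueError("alpha, beta, sigma must be positive")


@dataclass
class DropoutProbMatrix:
    """Posterior dropout probabilities aligned to an ExpressionMatrix."""

    dp: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.dp = np.asarray(self.dp, dtype=np.float64)
        if self.dp.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("dp shape does not match identifiers")
        if ((self.dp < 0) | (self.dp > 1)).any():
            raise ValueError("dropout probabilities must lie in [0, 1]")

    def dropout_fraction(self, cells: np.ndarray | None = None) -> np.ndarray:
        """Per-gene share of (selected) cells called dropout (DP > T)."""
        d = self.dp if cells is None else self.dp[:, cells]
        return (d > self.threshold).mean(axis=1)


def _gamma_logpdf(x: np.ndarray, alpha, beta) -> np.ndarray:
    x = np.maximum(x, EPS_ZERO)
    return alpha * np.log(beta) - gammaln(alpha) + (alpha - 1) * np.log(x) - beta * x


def _normal_logpdf(x: np.ndarray, mu, sigma) -> np.ndarray:
    return -0.5 * ((x - mu) / sigma) ** 2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)


def mixture_density(x: float, p: GammaNormalParams) -> tuple[float, float, float]:
    """Evaluate the mixture at ``x``: (total, gamma part, normal part)."""
    if x < 0:
        raise ValueError("expression values must be non-negative")
    xa = np.asarray(float(x))
    fg = float(np.exp(_gamma_logpdf(xa, p.alpha, p.beta)))
    fn = float(np.exp(_normal_logpdf(xa, p.mu, p.sigma)))
    return p.eta * fg + (1 - p.eta) * fn, fg, fn


def dropout_probability(x: float, p: GammaNormalParams) -> float:
    """Posterior probability that ``x`` came from the dropout component."""
    if p.eta == 0.0:
        return 0.0
    if p.eta == 1.0:
        return 1.0
    _, fg, fn = mixture_density(x, p)
    num = p.eta * fg
    den = num + (1 - p.eta) * fn
    if den <= _TINY:
        warnings.warn("both component densities vanish; returning prior eta")
        return p.eta
    return float(num / den)


def _fallback_params(x: np.ndarray) -> GammaNormalParams:
    """Degenerate-data fallback: eta from the zero fraction."""
    zero_frac = float((x <= 0).mean())
    pos = x[x > 0]
    mu = float(pos.mean()) if pos.size else 1.0
    sigma = float(pos.std()) if pos.size > 1 and pos.std() > 0 else 1.0
    return GammaNormalParams(
        eta=zero_frac, alpha=1.0, beta=1.0, mu=mu, sigma=sigma,
        converged=False, n_obs=x.size,
    )


def fit_gamma_normal_em(
    x: np.ndarray, tol: float = 1e-6, max_iter: int = 500
) -> GammaNormalParams:
    """Fit the gamma-normal mixture to one gene's values in one cluster.

    Returns fallback parameters (``converged=False``) for constant input;
    otherwise runs EM to a relative log-likelihood change below ``tol``.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size < 10:
        raise ValueError("need at least 10 observations; use the fallback path")
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    if np.allclose(x, x[0]):
        return _fallback_params(x)
    params, ll, conv, _ = _em_batch(x[None, :], tol=tol, max_iter=max_iter)
    eta, alpha, beta, mu, sigma = (float(a[0]) for a in params)
    return GammaNormalParams(eta, alpha, beta, mu, sigma, bool(conv[0]), x.size)


def _em_batch(
    X: np.ndarray, tol: float = 1e-6, max_iter: int = 500
) -> tuple[tuple[np.ndarray, ...], np.ndarray, np.ndarray, list[np.ndarray]]:
    """Vectorised EM over many genes sharing one cell set.

    X is (n_genes, n_cells).  Returns ((eta, alpha, beta, mu, sigma),
    final log-likelihood, converged flags, per-iteration LL trace).
    """
    G, n = X.shape
    Xe = np.maximum(X, EPS_ZERO)

    # initialisation: low mass = zeros plus values below the 20th percentile
    # of positives, capped at 1.0 on the log scale so genes without a
    # low-value pile-up start from a small dropout weight; normal moments
    # from the upper part, gamma moments below
    pos_mask = X > 0
    q20 = np.full(G, EPS_ZERO)
    for g in range(G):
        pos = X[g, pos_mask[g]]
        if pos.size:
            q20[g] = min(np.percentile(pos, 20), 1.0)
    low = X <= q20[:, None]
    low_frac = low.mean(axis=1)
    eta = np.clip(low_frac, 0.01, 0.95)
    w_hi = (~low).astype(float)
    w_hi_sum = np.maximum(w_hi.sum(axis=1), 1.0)
    mu = (w_hi * X).sum(axis=1) / w_hi_sum
    sigma = np.sqrt((w_hi * (X - mu[:, None]) ** 2).sum(axis=1) / w_hi_sum)
    sigma = np.maximum(sigma, 1e-3)
    w_lo = low.astype(float)
    w_lo_sum = np.maximum(w_lo.sum(axis=1), 1.0)
    m_lo = np.maximum((w_lo * Xe).sum(axis=1) / w_lo_sum, EPS_ZERO)
    v_lo = np.maximum((w_lo * (Xe - m_lo[:, None]) ** 2).sum(axis=1) / w_lo_sum, 1e-6)
    alpha = np.clip(m_lo**2 / v_lo, 1e-3, 1e3)
    beta = np.clip(m_lo / v_lo, 1e-3, 1e6)

    def loglik(eta, alpha, beta, mu, sigma):
        lg = _gamma_logpdf(Xe, alpha[:, None], beta[:, None])
        ln = _normal_logpdf(X, mu[:, None], sigma[:, None])
        mix = eta[:, None] * np.exp(lg) + (1 - eta[:, None]) * np.exp(ln)
        return np.log(mix + _TINY).sum(axis=1)

    ll = loglik(eta, alpha, beta, mu, sigma)
    trace = [ll.copy()]
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)

    def loglik_sub(Xs, Xes, eta, alpha, beta, mu, sigma):
        lg = alpha[:, None] * np.log(beta[:, None]) - gammaln(alpha)[:, None] \
            + (alpha[:, None] - 1) * np.log(Xes) - beta[:, None] * Xes
        ln = _normal_logpdf(Xs, mu[:, None], sigma[:, None])
        mix = eta[:, None] * np.exp(lg) + (1 - eta[:, None]) * np.exp(ln)
        return np.log(mix + _TINY).sum(axis=1)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        Xs, Xes = X[idx], Xe[idx]
        e_a, a_a, b_a, m_a, s_a = eta[idx], alpha[idx], beta[idx], mu[idx], sigma[idx]

        # E-step on the still-active genes only
        lg = a_a[:, None] * np.log(b_a[:, None]) - gammaln(a_a)[:, None] \
            + (a_a[:, None] - 1) * np.log(Xes) - b_a[:, None] * Xes
        ln = _normal_logpdf(Xs, m_a[:, None], s_a[:, None])
        num = e_a[:, None] * np.exp(lg)
        den = num + (1 - e_a[:, None]) * np.exp(ln)
        r = np.where(den > _TINY, num / np.maximum(den, _TINY), e_a[:, None])

        # M-step
        eta_new = np.clip(r.mean(axis=1), 0.0, 1.0)
        w_n = 1.0 - r
        w_n_sum = np.maximum(w_n.sum(axis=1), 1e-12)
        mu_new = (w_n * Xs).sum(axis=1) / w_n_sum
        sigma_new = np.sqrt(
            (w_n * (Xs - mu_new[:, None]) ** 2).sum(axis=1) / w_n_sum
        )
        sigma_new = np.maximum(sigma_new, 1e-4)
        w_g_sum = np.maximum(r.sum(axis=1), 1e-12)
        m_g = np.maximum((r * Xes).sum(axis=1) / w_g_sum, EPS_ZERO)
        v_g = np.maximum((r * (Xes - m_g[:, None]) ** 2).sum(axis=1) / w_g_sum,
                         1e-12)
        alpha_new = np.clip(m_g**2 / v_g, 1e-3, 1e3)
        beta_new = np.clip(m_g / v_g, 1e-3, 1e6)

        # guard: accept the moment-based gamma update only where it does not
        # lower the likelihood (the eta/mu/sigma part is an exact M-step)
        ll_keep = loglik_sub(Xs, Xes, eta_new, a_a, b_a, mu_new, sigma_new)
        ll_new = loglik_sub(Xs, Xes, eta_new, alpha_new, beta_new,
                            mu_new, sigma_new)
        take = ll_new >= ll_keep
        alpha[idx] = np.where(take, alpha_new, a_a)
        beta[idx] = np.where(take, beta_new, b_a)
        eta[idx], mu[idx], sigma[idx] = eta_new, mu_new, sigma_new
        ll_iter = np.where(take, ll_new, ll_keep)

        rel = np.abs(ll_iter - ll[idx]) / np.maximum(np.abs(ll[idx]), 1.0)
        ll[idx] = ll_iter
        done = rel < tol
        converged[idx[done]] = True
        active[idx[done]] = False
        trace.append(ll.copy())
    return (eta, alpha, beta, mu, sigma), ll, converged, trace


def compute_dropout_matrix(
    m: ExpressionMatrix,
    c: CellClustering,
    threshold: float = 0.5,
    min_obs: int = 10,
) -> DropoutProbMatrix:
    """Posterior dropout probability for every entry of ``m``.

    The mixture is fitted independently for every (gene, cluster) pair on
    the gene's log-space values within that cluster.  Genes with fewer than
    ``min_obs`` non-zero observations in a cluster take the fallback: DP = 1
    at zeros, 0 elsewhere, with eta set to the zero fraction.
    """
    if m.space == "counts":
        raise ValueError("compute_dropout_matrix expects log (or cpm) space")
    if len(c.labels) != m.n_cells:
        raise ValueError("clustering does not cover the matrix's cells")
    dp = np.zeros_like(m.values)
    for cl in range(c.k):
        cells = np.flatnonzero(c.labels == cl)
        X = m.values[:, cells]
        nonzero = (X > 0).sum(axis=1)
        fit_mask = nonzero >= min_obs
        # degenerate (near-constant) genes go to the fallback as well
        if fit_mask.any():
            const = np.ptp(X[fit_mask], axis=1) < 1e-12
            idx = np.flatnonzero(fit_mask)
            fit_mask[idx[const]] = False
        fallback = ~fit_mask
        if fallback.any():
            dp[np.ix_(fallback, cells)] = (X[fallback] <= 0).astype(float)
        if fit_mask.any():
            (eta, alpha, beta, mu, sigma), _, conv, _ = _em_batch(X[fit_mask])
            Xe = np.maximum(X[fit_mask], EPS_ZERO)
            lg = _gamma_logpdf(Xe, alpha[:, None], beta[:, None])
            ln = _normal_logpdf(X[fit_mask], mu[:, None], sigma[:, None])
            num = eta[:, None] * np.exp(lg)
            den = num + (1 - eta[:, None]) * np.exp(ln)
            post = np.where(den > _TINY, num / np.maximum(den, _TINY), eta[:, None])
            # non-converged fits fall back to the zero-indicator rule
            bad = ~conv
            if bad.any():
                post[bad] = (X[fit_mask][bad] <= 0).astype(float)
            dp[np.ix_(fit_mask, cells)] = np.clip(post, 0.0, 1.0)
            if bad.any():
                logger.info(
                    "cluster %d: %d/%d gene fits did not converge (fallback)",
                    cl, int(bad.sum()), int(fit_mask.sum()),
                )
    return DropoutProbMatrix(dp, list(m.gene_ids), list(m.cell_ids), threshold)


def select_targets(dp: DropoutProbMatrix, T: float = 0.5) -> np.ndarray:
    """Indices of genes whose dropout probability exceeds T in any cell."""
    return np.flatnonzero(dp.dp.max(axis=1) > T)
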