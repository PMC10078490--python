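"""Binomial generalized linear latent variable models (model-based ordination).

Each taxon's occurrence at a site is Bernoulli with

    logit p_ij = alpha_j + u_i' lambda_j,      u_i ~ N(0, I_d)

where the d-dimensional latent site scores u_i absorb the common (unmeasured)
sources of covariation among taxa. The latent scores are integrated out
approximately with a variational Gaussian approximation: each site gets
q(u_i) = N(m_i, V_i), and the Bernoulli-logit likelihood is handled with the
Jaakkola-Jordan quadratic bound, giving closed-form coordinate updates that
increase the evidence lower bound (ELBO) monotonically. The ELBO plays the
role of the marginal log-likelihood in the AIC used to select the latent
dimension -- the same device as variational GLLVM software. At d = 0 the
model has no latent terms and the likelihood is exact and closed-form.

The fitted probability matrix (inverse logit of alpha_j + m_i' lambda_j) is
the low-rank, denoised response that downstream GAMs model in place of the
raw binary data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .community import CommunityMatrix

__all__ = [
    "LatentFit",
    "fit_binomial_gllvm",
    "select_latent_dimension",
    "predicted_response",
]

PROB_CLAMP = 1e-6


@dataclass
class LatentFit:
    """A fitted binomial latent-variable model.

    ``log_likelihood`` is the exact likelihood at d = 0 and the variational
    lower bound (ELBO) at d > 0; ``aic = 2 n_params - 2 log_likelihood`` with
    latent scores treated as integrated out (not counted as parameters).
    ``loadings`` rows for invariant (all-0/all-1) taxa are zero: such taxa
    are fitted as clamped intercept-only columns and excluded from the
    latent structure.
    """

    n_latent: int
    intercepts: np.ndarray  # (n_taxa,)
    loadings: np.ndarray  # (n_taxa, d)
    site_scores: np.ndarray  # (n_sites, d), posterior means
    log_likelihood: float
    n_params: int
    aic: float
    predicted: np.ndarray  # (n_sites, n_taxa), clamped probabilities
    converged: bool
    n_restarts_used: int
    taxon_id: list
    site_id: list

    @property
    def linear_predictor(self) -> np.ndarray:
        return self.intercepts[None, :] + self.site_scores @ self.loadings.T


def _closed_form_d0(y: np.ndarray) -> tuple[np.ndarray, float]:
    """Intercept-only fit: per-taxon MLE is the prevalence; exact likelihood
    with the 0*log(0) = 0 convention for invariant taxa."""
    n = y.shape[0]
    k = y.sum(axis=0)
    p_hat = k / n
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_terms = k * np.log(p_hat) + (n - k) * np.log(1.0 - p_hat)
    ll_terms = np.where(np.isfinite(ll_terms), ll_terms, 0.0)
    return p_hat, float(ll_terms.sum())


def _jj_lambda(xi: np.ndarray) -> np.ndarray:
    """tanh(xi/2) / (4 xi), with the xi -> 0 limit of 1/8."""
    out = np.full_like(xi, 0.125)
    nz = np.abs(xi) > 1e-6
    out[nz] = np.tanh(xi[nz] / 2.0) / (4.0 * xi[nz])
    return out


def _canonicalize(loadings: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-invariant identification: make loadings\'loadings diagonal
    with decreasing scale and the largest-|loading| positive per factor.
    This is equivariant under taxon permutation, unlike a triangular
    constraint."""
    if loadings.shape[1] == 0:
        return loadings, scores
    u_svd, s, vt = np.linalg.svd(loadings, full_matrices=False)
    lam = u_svd * s
    scr = scores @ vt.T
    flip = np.sign(lam[np.argmax(np.abs(lam), axis=0), np.arange(lam.shape[1])])
    flip[flip == 0] = 1.0
    return lam * flip, scr * flip


def _elbo(y, alpha, lam, m, v, xi) -> float:
    """Jaakkola-Jordan evidence lower bound at the current variational state.

    Assumes xi has just been set to sqrt(E[eta^2]), which zeroes the
    quadratic slack term.
    """
    n, d = m.shape
    eta_mean = alpha[None, :] + m @ lam.T
    bound = np.sum(np.log(expit(xi)) + (y - 0.5) * eta_mean - xi / 2.0)
    sign, logdet = np.linalg.slogdet(v)
    trace = np.trace(v, axis1=1, axis2=2)
    kl = 0.5 * float(np.sum(logdet - trace - np.sum(m * m, axis=1) + d))
    return float(bound) + kl


def fit_binomial_gllvm(
    Y: CommunityMatrix | np.ndarray,
    d: int,
    seed: int = 0,
    n_restarts: int = 3,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> LatentFit:
    """Fit a d-dimensional binomial GLLVM by variational coordinate ascent.

    Parameters
    ----------
    Y : CommunityMatrix or binary ndarray
    d : latent dimension (0 gives the closed-form independent-taxon model)
    seed : controls initialization jitter across restarts; the best restart
        (highest ELBO) is kept.
    """
    if isinstance(Y, CommunityMatrix):
        y = Y.values
        taxon_id, site_id = Y.taxon_id, Y.site_id
    else:
        y = np.asarray(Y, dtype=float)
        taxon_id = [f"sp_{j:03d}" for j in range(y.shape[1])]
        site_id = [f"site_{i:03d}" for i in range(y.shape[0])]
    n, m_taxa = y.shape
    if d < 0:
        raise ValueError("latent dimension must be non-negative")
    if d >= min(n, m_taxa):
        raise ValueError(
            f"latent dimension d={d} must be < min(n_sites, n_taxa)={min(n, m_taxa)}"
        )

    prevalence = y.mean(axis=0)
    invariant = (prevalence == 0.0) | (prevalence == 1.0)
    variable = ~invariant
    m_var = int(variable.sum())
    n_params = m_taxa + d * m_var - d * (d - 1) // 2

    if d == 0 or m_var == 0:
        p_hat, ll = _closed_form_d0(y)
        predicted = np.clip(np.tile(p_hat, (n, 1)), PROB_CLAMP, 1.0 - PROB_CLAMP)
        alpha = logit(np.clip(p_hat, PROB_CLAMP, 1.0 - PROB_CLAMP))
        return LatentFit(
            n_latent=0,
            intercepts=alpha,
            loadings=np.zeros((m_taxa, 0)),
            site_scores=np.zeros((n, 0)),
            log_likelihood=ll,
            n_params=m_taxa,
            aic=2 * m_taxa - 2 * ll,
            predicted=predicted,
            converged=True,
            n_restarts_used=0,
            taxon_id=taxon_id,
            site_id=site_id,
        )

    yv = y[:, variable]
    yc = yv - yv.mean(axis=0, keepdims=True)
    u_svd, _, _ = np.linalg.svd(yc, full_matrices=False)
    m_init_base = u_svd[:, :d] * np.sqrt(n)
    flip = np.sign(m_init_base[np.argmax(np.abs(m_init_base), axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    m_init_base = m_init_base * flip  # deterministic SVD sign

    best = None
    for restart in range(n_restarts):
        rng = np.random.default_rng([seed, 90_001 + restart])
        state = _va_fit(
            yv,
            m_init=m_init_base + 0.3 * rng.standard_normal((n, d)) * (restart > 0),
            max_iter=max_iter,
            tol=tol,
        )
        if best is None or state["elbo"] > best["elbo"]:
            best = state | {"restart": restart}

    if not best["converged"]:
        warnings.warn("GLLVM did not converge after all restarts", stacklevel=2)
    lam, scores = _canonicalize(best["lam"], best["m"])

    alpha = np.empty(m_taxa)
    loadings = np.zeros((m_taxa, d))
    alpha[variable] = best["alpha"]
    loadings[variable] = lam
    alpha[invariant] = logit(np.clip(prevalence[invariant], PROB_CLAMP, 1.0 - PROB_CLAMP))

    predicted = np.clip(expit(alpha[None, :] + scores @ loadings.T), PROB_CLAMP, 1.0 - PROB_CLAMP)
    return LatentFit(
        n_latent=d,
        intercepts=alpha,
        loadings=loadings,
        site_scores=scores,
        log_likelihood=best["elbo"],
        n_params=n_params,
        aic=2 * n_params - 2 * best["elbo"],
        predicted=predicted,
        converged=best["converged"],
        n_restarts_used=best["restart"],
        taxon_id=taxon_id,
        site_id=site_id,
    )


def _va_fit(y, m_init, max_iter, tol):
    """Variational coordinate ascent for one restart. Returns the final state."""
    n, m_taxa = y.shape
    d = m_init.shape[1]
    eye = np.eye(d)
    m = m_init.copy()
    v = np.tile(eye, (n, 1, 1))
    alpha = logit(np.clip(y.mean(axis=0), PROB_CLAMP, 1.0 - PROB_CLAMP))
    lam = 0.1 * np.ones((m_taxa, d))
    yc = y - 0.5
    converged = False
    elbo_prev = -np.inf
    elbo = -np.inf
    for _ in range(max_iter):
        # variational tilts: xi^2 = E[eta^2]
        eta_mean = alpha[None, :] + m @ lam.T
        quad = np.einsum("mi,nij,mj->nm", lam, v, lam)
        xi = np.sqrt(eta_mean**2 + quad)
        w = 2.0 * _jj_lambda(xi)  # n x m

        # taxon step: (alpha_j, lambda_j) by weighted least squares
        z = np.column_stack([np.ones(n), m])  # n x (d+1)
        outer = z[:, :, None] * z[:, None, :]
        outer[:, 1:, 1:] += v
        a_mat = np.einsum("nm,nij->mij", w, outer) + 1e-8 * np.eye(d + 1)[None]
        b_vec = yc.T @ z  # m x (d+1)
        coef = np.linalg.solve(a_mat, b_vec[:, :, None])[:, :, 0]
        alpha, lam = coef[:, 0], coef[:, 1:]

        # site step: q(u_i) = N(m_i, V_i)
        precision = np.einsum("nm,mi,mj->nij", w, lam, lam) + eye[None]
        v = np.linalg.inv(precision)
        rhs = yc @ lam - (w * alpha[None, :]) @ lam  # n x d
        m = np.einsum("nij,nj->ni", v, rhs)

        eta_mean = alpha[None, :] + m @ lam.T
        quad = np.einsum("mi,nij,mj->nm", lam, v, lam)
        xi = np.sqrt(eta_mean**2 + quad)
        elbo = _elbo(y, alpha, lam, m, v, xi)
        if np.isfinite(elbo_prev) and abs(elbo - elbo_prev) < tol * (1.0 + abs(elbo)):
            converged = True
            break
        elbo_prev = elbo
    return {"alpha": alpha, "lam": lam, "m": m, "v": v, "elbo": elbo, "converged": converged}


def select_latent_dimension(
    Y: CommunityMatrix | np.ndarray,
    d_candidates=(0, 1, 2, 3),
    seed: int = 0,
    n_restarts: int = 3,
) -> LatentFit:
    """Fit each candidate latent dimension and return the lowest-AIC model.

    Ties break toward the smaller dimension; candidates that are infeasible
    (d >= min(n, m)) are skipped, and non-convergent fits are used only if no
    convergent candidate exists.
    """
    d_candidates = list(d_candidates)
    if not d_candidates:
        raise ValueError("d_candidates must be non-empty")
    fits: list[LatentFit] = []
    diagnostics = []
    for d in sorted(d_candidates):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_binomial_gllvm(Y, d, seed=seed, n_restarts=n_restarts)
        except ValueError as exc:
            diagnostics.append(f"d={d}: {exc}")
            continue
        fits.append(fit)
    if not fits:
        raise ValueError("no candidate dimension could be fitted: " + "; ".join(diagnostics))
    convergent = [f for f in fits if f.converged]
    pool = convergent if convergent else fits
    return min(pool, key=lambda f: (f.aic, f.n_latent))


def predicted_response(fit: LatentFit, allow_nonconverged: bool = False) -> np.ndarray:
    """The probability matrix used as the GAM response: inverse logit of the
    linear predictor, clamped to [1e-6, 1 - 1e-6]."""
    if not fit.converged and not allow_nonconverged:
        raise ValueError("fit did not converge; pass allow_nonconverged=True to override")
    return np.clip(expit(fit.linear_predictor), PROB_CLAMP, 1.0 - PROB_CLAMP)
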