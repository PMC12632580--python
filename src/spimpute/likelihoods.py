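"""Count likelihoods: negative binomial and zero-inflated negative binomial.

Both distributions are parameterized by their mean ``mu`` and a per-gene
inverse-dispersion ``theta`` (variance = mu + mu^2 / theta), the convention
used throughout single-cell variational models.  The ZINB adds a point mass
at zero with mixing weight sigmoid(dropout_logit).

Two flavours are provided: plain numpy functions (used by the samplers,
uncertainty scores and tests) and ``*_ad`` versions operating on autodiff
``Var`` nodes (used inside the training objective).
"""

from __future__ import annotations

import numpy as np
from scipy import special

from . import _autodiff as ad

__all__ = [
    "nb_log_likelihood",
    "zinb_log_likelihood",
    "nb_log_likelihood_ad",
    "zinb_log_likelihood_ad",
    "sample_nb",
]

_EPS = 1e-8


def _check_counts(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    return x


def nb_log_likelihood(x, mean, theta) -> np.ndarray:
    """Log pmf of NB(mean, theta) at counts ``x``.

    Stable for x = 0 (reduces to ``-theta * log1p(mean/theta)``) and for
    large theta (Poisson limit).
    """
    x = _check_counts(x)
    mean = np.asarray(mean, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    log_theta_mu = np.log(theta + mean + _EPS)
    return (
        special.gammaln(x + theta)
        - special.gammaln(theta)
        - special.gammaln(x + 1.0)
        + theta * (np.log(theta + _EPS) - log_theta_mu)
        + x * (np.log(mean + _EPS) - log_theta_mu)
    )


def zinb_log_likelihood(x, mean, theta, dropout_logit) -> np.ndarray:
    """Log pmf of the zero-inflated NB.

    The zero component has weight ``sigmoid(dropout_logit)``; the limit
    ``dropout_logit -> -inf`` recovers the plain NB exactly.
    """
    x = _check_counts(x)
    mean = np.asarray(mean, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    logit = np.asarray(dropout_logit, dtype=np.float64)
    nb_all = nb_log_likelihood(x, mean, theta)
    log_norm = np.logaddexp(0.0, logit)  # log(1 + e^logit)
    # at x = 0 nb_all is exactly log NB(0), so the mixture reuses it and the
    # dropout -> -inf limit recovers the NB bit-for-bit
    case_zero = np.logaddexp(logit, nb_all) - log_norm
    case_pos = nb_all - log_norm
    return np.where(x > 0, case_pos, np.broadcast_to(case_zero, case_pos.shape))


def nb_log_likelihood_ad(x: np.ndarray, mean: ad.Var, theta: ad.Var) -> ad.Var:
    """Autodiff NB log pmf; ``x`` is a constant count array."""
    x = _check_counts(x)
    log_theta_mu = ad.log(theta + mean + _EPS)
    return (
        ad.gammaln(theta + x)
        - ad.gammaln(theta)
        - special.gammaln(x + 1.0)
        + theta * (ad.log(theta + _EPS) - log_theta_mu)
        + x * (ad.log(mean + _EPS) - log_theta_mu)
    )


def zinb_log_likelihood_ad(
    x: np.ndarray, mean: ad.Var, theta: ad.Var, dropout_logit: ad.Var
) -> ad.Var:
    """Autodiff ZINB log pmf; ``x`` is a constant count array."""
    x = _check_counts(x)
    nb_all = nb_log_likelihood_ad(x, mean, theta)
    log_norm = ad.softplus(dropout_logit)
    case_zero = ad.logaddexp(dropout_logit + np.zeros_like(x), nb_all) - log_norm
    case_pos = nb_all - log_norm
    return ad.where(x > 0, case_pos, case_zero)


def sample_nb(rng: np.random.Generator, mean, theta, size=None) -> np.ndarray:
    """Draw NB counts via the gamma-Poisson mixture."""
    mean = np.asarray(mean, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    if size is None:
        size = np.broadcast_shapes(mean.shape, theta.shape)
    theta_b = np.broadcast_to(theta, size)
    scale_b = np.broadcast_to(np.clip(mean / theta, _EPS, None), size)
    lam = rng.gamma(shape=theta_b, scale=scale_b)
    return rng.poisson(lam).astype(np.int64)
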