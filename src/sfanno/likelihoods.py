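"""Count-data likelihood losses.

The zero-inflated negative binomial (ZINB) law models a dropout event with
probability ``omega`` and otherwise a negative binomial draw parameterized by
mean ``mu`` and dispersion ``phi``, so that ``Var = mu + mu^2 / phi``:

    P(x) = omega * 1[x = 0]
           + (1 - omega) * C(x + phi - 1, x) * (phi/(phi+mu))^phi * (mu/(phi+mu))^x

This parameterization is shared by the simulator (`sfanno.simulate.zinb_sample`)
and the autoencoder decoder; it is defined once here.  All likelihoods are
evaluated in log space (log-add-exp for the zero branch, log-gamma for the
binomial coefficient) and are differentiable through `sfanno.autodiff`.

For binarized scATAC gene-activity matrices the Bernoulli negative
log-likelihood replaces the ZINB one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .autodiff import Tensor, logaddexp

_EPS = 1e-12

ArrayLike = Union[np.ndarray, Tensor]


@dataclass
class ZINBParams:
    """Per-entry ZINB parameters: dropout in (0,1), mean > 0, dispersion > 0."""

    dropout: ArrayLike
    mean: ArrayLike
    dispersion: ArrayLike


@dataclass
class BernoulliParams:
    """Per-entry Bernoulli mean parameter in (0,1)."""

    theta: ArrayLike


def _as_tensor(a) -> Tensor:
    return a if isinstance(a, Tensor) else Tensor(np.asarray(a, dtype=np.float64))


def _check_shapes(x: np.ndarray, *arrs):
    for a in arrs:
        d = a.data if isinstance(a, Tensor) else np.asarray(a)
        if np.broadcast_shapes(d.shape, x.shape) != x.shape:
            raise ValueError(f"parameter shape {d.shape} incompatible with counts {x.shape}")
        if np.isnan(d).any():
            raise ValueError("NaN in likelihood parameters")


def zinb_nll(x, params: ZINBParams) -> Tensor:
    """Mean negative log-likelihood of counts ``x`` under per-entry ZINB laws.

    Returns a scalar Tensor: ``-(1/(N*p)) * sum_ij log P_zinb(x_ij)``.
    """
    x = np.asarray(x, dtype=np.float64)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    _check_shapes(x, params.dropout, params.mean, params.dispersion)
    om = _as_tensor(params.dropout).clip(_EPS, 1.0 - _EPS)
    mu = _as_tensor(params.mean).clip(_EPS, np.inf)
    phi = _as_tensor(params.dispersion).clip(_EPS, np.inf)

    log_om = om.log()
    log_1m_om = (1.0 - om).log()
    log_phi_frac = phi.log() - (phi + mu).log()   # log(phi/(phi+mu))
    log_mu_frac = mu.log() - (phi + mu).log()     # log(mu/(phi+mu))

    xt = Tensor(x)
    log_nb = (
        (xt + phi).lgamma()
        - phi.lgamma()
        - Tensor(_lgamma_const(x + 1.0))
        + phi * log_phi_frac
        + xt * log_mu_frac
    )
    # x = 0: log(omega + (1-omega) * (phi/(phi+mu))^phi)
    log_p_zero = logaddexp(log_om, log_1m_om + phi * log_phi_frac)
    log_p_pos = log_1m_om + log_nb

    zero_mask = (x == 0).astype(np.float64)
    ll = Tensor(zero_mask) * log_p_zero + Tensor(1.0 - zero_mask) * log_p_pos
    return -ll.mean()


def nb_nll(x, mean, dispersion) -> Tensor:
    """Negative binomial NLL; the ZINB law with the dropout component removed."""
    return zinb_nll(x, ZINBParams(np.full(np.shape(x), _EPS), mean, dispersion))


def bernoulli_nll(x, params: BernoulliParams) -> Tensor:
    """Mean Bernoulli NLL for a binary matrix; theta clamped to [1e-7, 1-1e-7]."""
    x = np.asarray(x, dtype=np.float64)
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("Bernoulli likelihood requires a binary matrix")
    _check_shapes(x, params.theta)
    th = _as_tensor(params.theta).clip(1e-7, 1.0 - 1e-7)
    ll = Tensor(x) * th.log() + Tensor(1.0 - x) * (1.0 - th).log()
    return -ll.mean()


def _lgamma_const(a: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(a)
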