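"""Reconstruction objectives for masked-embedding language modeling.

All three losses operate on the residuals r = x - xbar and rhat = xhat - xbar,
where x is the true protein embedding, xhat the model's reconstruction and
xbar the functional-encoding baseline used for masking.

The polar loss decouples residual direction and magnitude:

    L(xhat, x, xbar) = (1 - cos theta) + (||rhat|| - ||r||)^2

with theta the angle between r and rhat.  It is zero iff xhat = x, and —
unlike the mean squared error — keeps penalizing wrong residual directions
even as ||r|| shrinks, which is what prevents the degenerate solution of
simply reproducing the baseline xbar.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor

__all__ = ["polar_loss", "mse_loss", "cosine_residual_loss", "LOSSES",
           "polar_loss_t", "mse_loss_t", "cosine_residual_loss_t"]

EPS = 1e-8


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.atleast_2d(np.asarray(x)))


def _check(x_hat: Tensor, x: Tensor, x_bar: Tensor | None) -> None:
    if x_hat.shape != x.shape or (x_bar is not None and x_bar.shape != x.shape):
        raise ValueError(
            f"shape mismatch: x_hat {x_hat.shape}, x {x.shape}"
            + (f", x_bar {x_bar.shape}" if x_bar is not None else ""))


def _cos_and_norms(x_hat: Tensor, x: Tensor, x_bar: Tensor,
                   eps: float) -> tuple[Tensor, Tensor, Tensor]:
    r = x - x_bar
    r_hat = x_hat - x_bar
    norm_r = (r ** 2).sum(axis=-1).sqrt()
    norm_rhat = (r_hat ** 2).sum(axis=-1).sqrt()
    dot = (r * r_hat).sum(axis=-1)
    denom = (norm_r * norm_rhat).maximum(eps)
    cos = dot / denom
    # both residuals (numerically) zero: perfect baseline reconstruction,
    # the angle is undefined and the angular term is defined to vanish
    both_zero = (norm_r.data < eps) & (norm_rhat.data < eps)
    if np.any(both_zero):
        cos = cos + Tensor((1.0 - cos.data) * both_zero)
    return cos, norm_r, norm_rhat


def polar_loss_t(x_hat: Tensor, x: Tensor, x_bar: Tensor,
                 eps: float = EPS) -> Tensor:
    """Polar loss, mean over rows.  Differentiable (tape) version."""
    _check(x_hat, x, x_bar)
    if eps <= 0:
        raise ValueError("eps must be positive")
    cos, norm_r, norm_rhat = _cos_and_norms(x_hat, x, x_bar, eps)
    angular = 1.0 - cos
    magnitude = (norm_rhat - norm_r) ** 2
    return (angular + magnitude).mean()


def mse_loss_t(x_hat: Tensor, x: Tensor, x_bar: Tensor | None = None) -> Tensor:
    """Mean squared error between x and xhat (xbar plays no role)."""
    _check(x_hat, x, x_bar)
    return ((x_hat - x) ** 2).mean()


def cosine_residual_loss_t(x_hat: Tensor, x: Tensor, x_bar: Tensor,
                           eps: float = EPS) -> Tensor:
    """1 - cos(theta) between the residuals; scale-invariant in rhat."""
    _check(x_hat, x, x_bar)
    if eps <= 0:
        raise ValueError("eps must be positive")
    cos, _, _ = _cos_and_norms(x_hat, x, x_bar, eps)
    return (1.0 - cos).mean()


def polar_loss(x_hat, x, x_bar, eps: float = EPS) -> float:
    """Numpy-facing polar loss (mean over rows for 2-D inputs)."""
    return float(polar_loss_t(_lift(x_hat), _lift(x), _lift(x_bar), eps).data)


def mse_loss(x_hat, x, x_bar=None) -> float:
    return float(mse_loss_t(_lift(x_hat), _lift(x),
                            None if x_bar is None else _lift(x_bar)).data)


def cosine_residual_loss(x_hat, x, x_bar, eps: float = EPS) -> float:
    return float(cosine_residual_loss_t(_lift(x_hat), _lift(x), _lift(x_bar),
                                        eps).data)


LOSSES = {
    "polar": polar_loss_t,
    "mse": mse_loss_t,
    "cosine": cosine_residual_loss_t,
}
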