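"""Discrete orthonormal Laguerre basis and the linear decay forward model.

A fluorescence decay h(n) is represented as a linear combination of
discrete orthonormal Laguerre functions b_l(n; alpha), l = 0..L-1.  The
scale parameter alpha in (0,1) sets how slowly the basis decays (the
order-0 function is sqrt(1-alpha) * alpha^(n/2)); higher orders add sign
changes, so a modest number of coefficients captures multi-exponential
decay shapes.  The measured waveform is the decay convolved with the
instrument response function (IRF), which keeps the estimation problem
linear in the coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, ShapeError

__all__ = ["LaguerreBasis", "build_laguerre_basis", "forward_decay", "convolve_irf"]


@dataclass(frozen=True)
class LaguerreBasis:
    """Orthonormal discrete Laguerre function matrix (n_samples x order_count)."""

    alpha: float
    order_count: int
    n_samples: int
    matrix: np.ndarray

    @property
    def columns(self) -> np.ndarray:
        return self.matrix


def build_laguerre_basis(alpha: float, order_count: int, n_samples: int) -> LaguerreBasis:
    """Construct the discrete Laguerre basis by the standard recursion.

        b_0(0) = sqrt(1 - alpha)
        b_0(n) = sqrt(alpha) * b_0(n - 1)
        b_l(n) = sqrt(alpha) * b_l(n - 1) + sqrt(alpha) * b_{l-1}(n) - b_{l-1}(n - 1)

    The columns are orthonormal once n_samples is large enough for all
    orders to have decayed.
    """
    if not (0.0 < alpha < 1.0):
        raise InvalidParameterError(f"alpha must be in (0, 1), got {alpha}")
    if order_count < 1:
        raise InvalidParameterError("order_count must be >= 1")
    if n_samples <= order_count:
        raise InvalidParameterError("n_samples must exceed order_count")

    sa = np.sqrt(alpha)
    B = np.zeros((n_samples, order_count))
    B[0, 0] = np.sqrt(1.0 - alpha)
    for l in range(1, order_count):
        # recursion at n = 0 with b(-1) = 0
        B[0, l] = sa * B[0, l - 1]
    for n in range(1, n_samples):
        B[n, 0] = sa * B[n - 1, 0]
        for l in range(1, order_count):
            B[n, l] = sa * B[n - 1, l] + sa * B[n, l - 1] - B[n - 1, l - 1]
    return LaguerreBasis(alpha=alpha, order_count=order_count, n_samples=n_samples, matrix=B)


def forward_decay(coeffs: np.ndarray, basis: LaguerreBasis) -> np.ndarray:
    """Decay curve h(n) = B @ c for a coefficient vector c."""
    coeffs = np.asarray(coeffs, float)
    if coeffs.shape != (basis.order_count,):
        raise ShapeError(
            f"expected {basis.order_count} coefficients, got shape {coeffs.shape}"
        )
    return basis.matrix @ coeffs


def convolve_irf(h: np.ndarray, irf: np.ndarray, n_out: int | None = None) -> np.ndarray:
    """Discrete linear convolution of a decay with the IRF kernel,
    truncated to ``n_out`` samples (default: len(h)).

    A delta-function kernel returns ``h`` unchanged.
    """
    h = np.asarray(h, float)
    irf = np.asarray(irf, float)
    if h.size == 0 or irf.size == 0:
        raise ShapeError("decay and IRF must be nonempty")
    if n_out is None:
        n_out = h.size
    return np.convolve(h, irf)[:n_out]
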