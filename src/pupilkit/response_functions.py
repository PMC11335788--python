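"""Pupil response functions (RFs).

Two gamma-shaped impulse-response families are provided, both with a fixed
onset delay (the pupil takes ~200 ms to start responding to a visual event):

* the Erlang gamma function ``h(t) = t^n exp(-n t / t_max)``, whose peak time
  is controlled by the single parameter ``t_max`` while ``n`` sets the
  shape/width, and
* the gamma probability density ``d(t) = c/(θ^k Γ(k)) t^(k-1) exp(-t/θ)``,
  where ``k`` and ``θ`` jointly control timing and shape and ``c`` is the
  area under the curve.

Erlang kernels are peak-normalized before the amplitude is applied, so the
amplitude parameter reads directly as the peak response; the raw peak value
``t_max^n e^{-n}`` underflows for realistic shapes (n ≈ 14), which is the
other reason the normalized form is used internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class DegenerateKernelError(ValueError):
    """Raised when a kernel has no positive mass to normalize."""


@dataclass(frozen=True)
class ErlangParams:
    """Erlang gamma RF: shape ``n``, peak time ``t_max`` (s), peak amplitude."""

    n: float
    t_max: float
    amplitude: float = 1.0
    delay: float = 0.2

    def __post_init__(self) -> None:
        if self.n <= 0 or self.t_max <= 0:
            raise ValueError("n and t_max must be positive")
        if self.delay < 0:
            raise ValueError("delay must be nonnegative")


@dataclass(frozen=True)
class GammaPdfParams:
    """Gamma-density RF: area ``c``, shape ``k``, scale ``theta`` (s)."""

    c: float
    k: float
    theta: float
    delay: float = 0.2

    def __post_init__(self) -> None:
        if self.k <= 0 or self.theta <= 0:
            raise ValueError("k and theta must be positive")
        if self.delay < 0:
            raise ValueError("delay must be nonnegative")


def _tau(dt: float, duration: float, delay: float) -> np.ndarray:
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration <= delay:
        raise ValueError("duration must exceed the onset delay")
    t = np.arange(0.0, duration, dt)
    return t - delay


def erlang_rf(params: ErlangParams, dt: float, duration: float = 4.0) -> np.ndarray:
    """Sampled Erlang gamma kernel, zero until the onset delay.

    The kernel is normalized to a peak of 1 (reached at ``delay + t_max``)
    and scaled by ``params.amplitude``; computed in log space so large
    shapes (n ≈ 40) do not underflow.
    """
    tau = _tau(dt, duration, params.delay)
    kernel = np.zeros_like(tau)
    pos = tau > 0
    x = tau[pos] / params.t_max
    kernel[pos] = np.exp(params.n * (np.log(x) - x + 1.0))
    return params.amplitude * kernel


def gamma_pdf_rf(params: GammaPdfParams, dt: float, duration: float = 4.0) -> np.ndarray:
    """Sampled gamma-density kernel; integrates to ``c`` for long durations."""
    tau = _tau(dt, duration, params.delay)
    kernel = np.zeros_like(tau)
    pos = tau > 0
    kernel[pos] = params.c * stats.gamma.pdf(tau[pos], params.k, scale=params.theta)
    return kernel


def normalize_peak(kernel: np.ndarray) -> np.ndarray:
    """Scale a kernel so its maximum equals 1 (shape preserved)."""
    kernel = np.asarray(kernel, dtype=float)
    peak = kernel.max() if kernel.size else 0.0
    if peak <= 0:
        raise DegenerateKernelError("kernel has no positive maximum")
    return kernel / peak
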