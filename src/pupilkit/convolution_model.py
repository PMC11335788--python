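"""Forward model: event traces → predicted pupil trace.

The pupil is treated as the output of linear time-invariant systems.  The
signed luminance-change trace of each region is convolved with a luminance
RF and cumulated over time, giving the *sustained* component (a brightness
step settles the pupil at a new size).  The contrast-change trace (absolute
luminance change) is convolved with a second RF without accumulation, giving
the *transient* orienting constriction that scales with event salience.
Regions are combined through six visual-field weight groups, the two
components are summed with a relative contrast weight, and the result is
z-standardized.

Sign convention: constriction is negative.  A positive luminance change
(brighter) therefore drives the predicted trace downward, and the transient
contrast component is always negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .response_functions import (
    ErlangParams,
    GammaPdfParams,
    erlang_rf,
    gamma_pdf_rf,
    normalize_peak,
)
from .video_events import EventTraces, RegionGrid

COMPONENT_LUMINANCE = "sustained_luminance"
COMPONENT_CONTRAST = "transient_contrast"


@dataclass(frozen=True)
class RegionalWeights:
    """Weights of the six visual-field groups; W1 (top-central) is fixed to 1."""

    w: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.w) != RegionGrid.N_GROUPS:
            raise ValueError("expected six group weights (W1..W6)")
        if self.w[0] != 1.0:
            raise ValueError("W1 is the reference group and must equal 1")
        if any(v < 0 for v in self.w):
            raise ValueError("weights must be nonnegative")

    @classmethod
    def from_free(cls, free: Sequence[float]) -> "RegionalWeights":
        """Build from the five free weights (W2..W6)."""
        return cls((1.0, *map(float, free)))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.w, dtype=float)


@dataclass(frozen=True)
class ModelSpec:
    """Which model variant to run.

    ``contrast_weight`` is the gain of the transient contrast component
    relative to the sustained luminance component.
    """

    rf_family: str = "erlang"  # "erlang" | "gamma_pdf"
    components: tuple[str, ...] = (COMPONENT_LUMINANCE, COMPONENT_CONTRAST)
    contrast_weight: float = 0.42
    use_regions: bool = False
    use_gaze: bool = False
    kernel_duration: float = 4.0

    def __post_init__(self) -> None:
        if self.rf_family not in ("erlang", "gamma_pdf"):
            raise ValueError(f"unknown rf_family {self.rf_family!r}")
        if not self.components:
            raise ValueError("at least one model component must be enabled")
        for comp in self.components:
            if comp not in (COMPONENT_LUMINANCE, COMPONENT_CONTRAST):
                raise ValueError(f"unknown component {comp!r}")


@dataclass
class PupilPrediction:
    """Predicted pupil traces (z-standardized) plus the raw model outputs."""

    timestamps: np.ndarray
    combined: np.ndarray
    luminance_only: np.ndarray
    contrast_only: np.ndarray
    combined_raw: np.ndarray
    luminance_raw: np.ndarray
    contrast_raw: np.ndarray


def zscore(trace: np.ndarray, return_flag: bool = False):
    """Standardize a trace to mean 0, SD 1.

    A zero-variance trace maps to all zeros; with ``return_flag=True`` the
    second return value reports whether the trace was degenerate.
    """
    trace = np.asarray(trace, dtype=float)
    sd = trace.std()
    degenerate = not (sd > 0)
    z = np.zeros_like(trace) if degenerate else (trace - trace.mean()) / sd
    return (z, degenerate) if return_flag else z


def convolve_trace(events: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal discrete convolution, truncated to the event-trace length.

    Accepts a 1-D series or an (n_steps, n_regions) matrix (the kernel is
    applied column-wise).
    """
    events = np.asarray(events, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if events.size == 0:
        return events.copy()
    if events.ndim == 1:
        return signal.fftconvolve(events, kernel)[: events.shape[0]]
    if events.ndim == 2:
        full = signal.fftconvolve(events, kernel[:, None], axes=0)
        return full[: events.shape[0]]
    raise ValueError("events must be 1-D or 2-D")


def sustained_response(transient: np.ndarray, dt: float) -> np.ndarray:
    """Accumulate a transient response into a sustained one (cumsum × dt)."""
    return np.cumsum(np.asarray(transient, dtype=float), axis=0) * dt


def build_kernel(params, rf_family: str, dt: float, duration: float) -> np.ndarray:
    """Peak-normalized sampled kernel for either RF family."""
    if rf_family == "erlang":
        if not isinstance(params, ErlangParams):
            raise TypeError("erlang family expects ErlangParams")
        return erlang_rf(params, dt, duration)  # already peak-normalized × amplitude
    if not isinstance(params, GammaPdfParams):
        raise TypeError("gamma_pdf family expects GammaPdfParams")
    return normalize_peak(gamma_pdf_rf(params, dt, duration))


def region_weight_vector(
    grid: RegionGrid, weights: Optional[RegionalWeights]
) -> np.ndarray:
    """Per-region weight vector from the six group weights."""
    if weights is None:
        weights = RegionalWeights()
    return weights.as_array()[grid.weight_group_of_region()]


def predict_pupil(
    traces: EventTraces,
    lum_params,
    contrast_params,
    spec: ModelSpec,
    weights: Optional[RegionalWeights] = None,
) -> PupilPrediction:
    """Run the forward model on one trial's event traces.

    Per region the sustained component is the cumulated convolution of the
    signed luminance change with the luminance RF (sign-flipped so brighter →
    constriction → negative), and the transient component is the convolution
    of the contrast change with the contrast RF (always negative).  Regions
    are weight-summed by group, components combined as
    ``luminance + contrast_weight × contrast``, and each output z-scored.
    """
    dt = traces.dt
    n_regions = traces.luminance_change.shape[1]
    if n_regions != traces.grid.n_regions:
        raise ValueError("trace region count does not match the grid")

    if spec.use_regions:
        w = region_weight_vector(traces.grid, weights)
    else:
        # full-field model: plain average over regions
        w = np.full(n_regions, 1.0 / n_regions)

    lum_raw = np.zeros(traces.n_steps)
    con_raw = np.zeros(traces.n_steps)
    if COMPONENT_LUMINANCE in spec.components:
        kernel = build_kernel(lum_params, spec.rf_family, dt, spec.kernel_duration)
        weighted = traces.luminance_change @ w
        lum_raw = -sustained_response(convolve_trace(weighted, kernel), dt)
    if COMPONENT_CONTRAST in spec.components:
        kernel = build_kernel(contrast_params, spec.rf_family, dt, spec.kernel_duration)
        weighted = traces.contrast_change @ w
        con_raw = -convolve_trace(weighted, kernel)

    combined_raw = lum_raw + spec.contrast_weight * con_raw
    return PupilPrediction(
        timestamps=traces.timestamps.copy(),
        combined=zscore(combined_raw),
        luminance_only=zscore(lum_raw),
        contrast_only=zscore(con_raw),
        combined_raw=combined_raw,
        luminance_raw=lum_raw,
        contrast_raw=con_raw,
    )
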