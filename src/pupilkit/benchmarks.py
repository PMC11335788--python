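"""Event-related (temporally discrete) benchmark models.

Three reference pipelines against which the temporally continuous convolution
model is compared:

* a prior-less polynomial of within-trial time, fitted jointly to all trials
  of a participant;
* a two-LTI model in the style of classic pupillometry work: discrete
  luminance events are detected with a threshold (±3 cd/m²) and a minimum
  separation (1 s), 3-s pupil epochs are extracted and baseline-corrected
  (first 250 ms), one RF is fitted to the grand-mean dilation through its
  cumulative, and a second RF captures the constriction "overshoot";
* a discrete contrast-response model in which event magnitudes are binned
  into five percentile bins and a sustained-luminance RF plus a transient
  contrast RF (with a relative weight) are fitted to the bin-mean epochs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .convolution_model import sustained_response
from .response_functions import ErlangParams, GammaPdfParams, erlang_rf, gamma_pdf_rf
from .video_events import Recording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiscreteEvent:
    """A thresholded luminance-change event."""

    index: int
    time: float
    magnitude: float  # signed, cd/m² per step

    @property
    def direction(self) -> str:
        return "brighter" if self.magnitude > 0 else "darker"


@dataclass
class Epoch:
    """Baseline-corrected pupil segment time-locked to one event."""

    event: DiscreteEvent
    values: np.ndarray
    rate: float


def detect_events(
    lum_change: np.ndarray,
    timestamps: np.ndarray,
    threshold: float = 3.0,
    min_separation: float = 1.0,
) -> list[DiscreteEvent]:
    """Threshold-then-greedy event detection.

    Samples with |change| ≥ threshold are candidate events; scanning in time
    order, any candidate closer than ``min_separation`` to the previously
    kept event is dropped.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    lum_change = np.asarray(lum_change, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    events: list[DiscreteEvent] = []
    last_time = -math.inf
    for i in np.flatnonzero(np.abs(lum_change) >= threshold):
        t = timestamps[i]
        if t - last_time >= min_separation:
            events.append(DiscreteEvent(int(i), float(t), float(lum_change[i])))
            last_time = t
    return events


def extract_epochs(
    recording: Recording,
    events: Sequence[DiscreteEvent],
    window: float = 3.0,
    baseline_window: float = 0.25,
) -> list[Epoch]:
    """3-s pupil segments per event, baseline-corrected and pooled-SD scaled.

    The baseline (mean of the first ``baseline_window`` seconds after onset,
    during which the pupil has not yet responded) is subtracted per epoch;
    all epochs are then divided by one pooled standard deviation so the
    set is jointly z-standardized.  Epochs overrunning the recording are
    skipped with a log entry.
    """
    rate = recording.rate
    n_win = int(round(window * rate))
    n_base = max(int(round(baseline_window * rate)), 1)
    epochs: list[Epoch] = []
    for ev in events:
        onset = int(round((ev.time - recording.timestamps[0]) * rate))
        if onset < 0 or onset + n_win > len(recording.pupil):
            logger.info("skipping epoch at t=%.3f s: overruns the recording", ev.time)
            continue
        seg = recording.pupil[onset : onset + n_win].astype(float).copy()
        seg -= seg[:n_base].mean()
        epochs.append(Epoch(ev, seg, rate))
    if epochs:
        pooled_sd = np.concatenate([e.values for e in epochs]).std()
        if pooled_sd > 0:
            for e in epochs:
                e.values = e.values / pooled_sd
    return epochs


@dataclass
class MagnitudeBins:
    """Events grouped into percentile bins of signed magnitude, darker→brighter."""

    edges: np.ndarray
    groups: list[list[int]]  # epoch indices per bin
    mean_epochs: list[np.ndarray]
    mean_magnitudes: np.ndarray


def bin_by_magnitude(epochs: Sequence[Epoch], n_bins: int = 5) -> MagnitudeBins:
    """Percentile-bin epochs by signed event magnitude (ties go to the lower bin)."""
    if len(epochs) < n_bins:
        raise ValueError("need at least one event per bin")
    mags = np.array([e.event.magnitude for e in epochs])
    qs = np.linspace(0, 100, n_bins + 1)[1:-1]
    edges = np.percentile(mags, qs)
    groups: list[list[int]] = [[] for _ in range(n_bins)]
    for i, m in enumerate(mags):
        b = int(np.sum(m > edges))  # equality → lower bin
        groups[b].append(i)
    mean_epochs = []
    mean_mags = np.empty(n_bins)
    for b, idx in enumerate(groups):
        if idx:
            mean_epochs.append(np.mean([epochs[i].values for i in idx], axis=0))
            mean_mags[b] = mags[idx].mean()
        else:
            mean_epochs.append(np.zeros_like(epochs[0].values))
            mean_mags[b] = math.nan
    return MagnitudeBins(edges, groups, mean_epochs, mean_mags)


def _r2(pred: np.ndarray, obs: np.ndarray) -> float:
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        return math.nan
    return 1.0 - float(np.sum((obs - pred) ** 2)) / float(ss_tot)


@dataclass
class KornBachFit:
    """Two-LTI event-related fit: sustained RF, overshoot RF, LTI2 weight."""

    rf1: GammaPdfParams
    rf2: GammaPdfParams
    weight: float
    r2_dilation: float
    r2_constriction: float
    pred_dilation: np.ndarray
    pred_constriction: np.ndarray


def _fit_gamma_to_curve(
    target: np.ndarray, dt: float, cumulative: bool, x0: tuple[float, float, float]
) -> GammaPdfParams:
    duration = len(target) * dt

    def model(x: np.ndarray) -> np.ndarray:
        params = GammaPdfParams(c=x[0], k=x[1], theta=x[2])
        kern = gamma_pdf_rf(params, dt, duration)[: len(target)]
        return sustained_response(kern, dt) if cumulative else kern

    def objective(x: np.ndarray) -> float:
        return float(np.sqrt(np.mean((model(x) - target) ** 2)))

    res = optimize.minimize(
        objective,
        np.asarray(x0, dtype=float),
        method="Nelder-Mead",
        bounds=[(1e-4, None), (1.05, 50.0), (0.005, 2.0)],
        options=dict(maxiter=4000, xatol=1e-5, fatol=1e-10),
    )
    return GammaPdfParams(c=float(res.x[0]), k=float(res.x[1]), theta=float(res.x[2]))


def fit_korn_bach(
    dilation_mean: np.ndarray,
    constriction_mean: np.ndarray,
    rate: float,
) -> KornBachFit:
    """Fit the two-LTI event-related model to grand-mean epochs.

    The sustained RF (LTI1) is fitted so its cumulative matches the dilation
    grand mean; the constriction is modeled as the inverted fitted dilation
    plus a weighted second RF capturing the extra transient constriction
    ("overshoot") to luminance increases.
    """
    dilation_mean = np.asarray(dilation_mean, dtype=float)
    constriction_mean = np.asarray(constriction_mean, dtype=float)
    if dilation_mean.std() == 0 or constriction_mean.std() == 0:
        raise ValueError("degenerate grand-mean epochs")
    dt = 1.0 / rate
    duration = len(dilation_mean) * dt

    rf1 = _fit_gamma_to_curve(
        dilation_mean, dt, cumulative=True,
        x0=(max(dilation_mean[-1], 1e-3), 14.0, 0.05),
    )
    pred_dil = sustained_response(
        gamma_pdf_rf(rf1, dt, duration)[: len(dilation_mean)], dt
    )

    overshoot = -(constriction_mean - (-pred_dil))  # positive transient to fit
    rf2 = _fit_gamma_to_curve(
        overshoot, dt, cumulative=False,
        x0=(max(np.trapezoid(np.clip(overshoot, 0, None), dx=dt), 1e-3), 4.7, 0.14),
    )
    kern2 = gamma_pdf_rf(rf2, dt, duration)[: len(constriction_mean)]

    # the weight enters linearly, so the RMSE-optimal value is the ordinary
    # least-squares projection of the unexplained constriction onto the RF2;
    # an overshoot below numerical noise (relative to the dilation) gets 0
    target = -(constriction_mean + pred_dil)
    denom = float(kern2 @ kern2)
    rms = lambda x: float(np.sqrt(np.mean(np.square(x))))
    if denom <= 0 or rms(target) <= 1e-6 * rms(dilation_mean):
        weight = 0.0
    else:
        weight = float(kern2 @ target) / denom
    pred_con = -pred_dil - weight * kern2
    return KornBachFit(
        rf1=rf1,
        rf2=rf2,
        weight=weight,
        r2_dilation=_r2(pred_dil, dilation_mean),
        r2_constriction=_r2(pred_con, constriction_mean),
        pred_dilation=pred_dil,
        pred_constriction=pred_con,
    )


@dataclass
class ContrastModelFit:
    """Discrete contrast-response model fitted to five bin-mean epochs."""

    lum_params: ErlangParams
    contrast_params: ErlangParams
    contrast_weight: float
    gain: float
    r2: float
    pred_epochs: list[np.ndarray]


def fit_contrast_response_model(
    bins: MagnitudeBins,
    rate: float,
    baseline_window: float = 0.25,
    delay: float = 0.2,
) -> ContrastModelFit:
    """Fit sustained + transient RFs to percentile-binned mean epochs.

    Each bin's predicted epoch is a gain times (−m·cumulative luminance RF −
    contrast_weight·|m|·contrast RF) for the bin's mean magnitude m, baseline
    corrected the same way as the data.  Free parameters: both Erlang shapes
    and peak times, the relative contrast weight, and the global gain.
    """
    dt = 1.0 / rate
    n_len = len(bins.mean_epochs[0])
    duration = n_len * dt
    n_base = max(int(round(baseline_window * rate)), 1)
    mags = bins.mean_magnitudes
    obs = np.concatenate(bins.mean_epochs)

    def predict(x: np.ndarray) -> list[np.ndarray]:
        lum = ErlangParams(x[0], x[1], delay=delay)
        con = ErlangParams(x[2], x[3], delay=delay)
        cw, gain = x[4], x[5]
        k_lum = erlang_rf(lum, dt, duration)[:n_len]
        k_con = erlang_rf(con, dt, duration)[:n_len]
        sus = sustained_response(k_lum, dt)
        out = []
        for m in mags:
            ep = gain * (-m * sus - cw * abs(m) * k_con)
            ep = ep - ep[:n_base].mean()
            out.append(ep)
        return out

    def objective(x: np.ndarray) -> float:
        return float(np.sqrt(np.mean((np.concatenate(predict(x)) - obs) ** 2)))

    x0 = np.array([10.0, 0.3, 3.0, 0.5, 0.5, 1.0])
    bounds = [(0.5, 40), (0.05, 2.0), (0.5, 40), (0.05, 2.0), (0.0, 10.0), (1e-6, None)]
    res = optimize.minimize(
        objective, x0, method="Nelder-Mead", bounds=bounds,
        options=dict(maxiter=6000, xatol=1e-5, fatol=1e-10, adaptive=True),
    )
    pred = predict(res.x)
    return ContrastModelFit(
        lum_params=ErlangParams(float(res.x[0]), float(res.x[1]), delay=delay),
        contrast_params=ErlangParams(float(res.x[2]), float(res.x[3]), delay=delay),
        contrast_weight=float(res.x[4]),
        gain=float(res.x[5]),
        r2=_r2(np.concatenate(pred), obs),
        pred_epochs=pred,
    )


@dataclass
class PolynomialFit:
    coefficients: np.ndarray
    r2: float


def polynomial_benchmark(
    pupil_traces: Sequence[np.ndarray],
    rate: float,
    degree: int = 5,
) -> PolynomialFit:
    """One polynomial of within-trial time fitted jointly to all trials.

    A single coefficient set is least-squares fitted to the pooled traces
    (each trial indexed by its own within-trial time), and the pooled R² is
    returned.  Serves as a prior-less control with the same number of free
    parameters as the contrast-response model.
    """
    if len(pupil_traces) < 2:
        raise ValueError("need at least two trials")
    xs, ys = [], []
    for trace in pupil_traces:
        trace = np.asarray(trace, dtype=float)
        xs.append(np.arange(len(trace)) / rate)
        ys.append(trace)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    # scale time to [0,1] for conditioning; coefficients reported on that scale
    x_scaled = x / x.max() if x.max() > 0 else x
    design = np.vander(x_scaled, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    pred = design @ coef
    return PolynomialFit(coefficients=coef, r2=_r2(pred, y))
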