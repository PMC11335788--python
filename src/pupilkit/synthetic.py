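"""Synthetic stimuli, gaze, and pupil traces with known ground truth.

Every downstream module is testable without external data: programmatic
videos with piecewise-constant (optionally per-region) gray levels, gaze
traces sampled faster than the video, and pupil traces produced by running
the forward convolution model under known parameters and adding white
Gaussian noise in z-units.

Default truth parameters describe a realistic observer for this kind of
stimulus: luminance RF n = 13.7, t_max = 0.28 s; contrast RF n = 3.0,
t_max = 0.53 s; relative contrast weight 0.42; regional weights
(1, 0.8, 0.5, 0.9, 0.7, 0.4) for the six visual-field groups, i.e. a
central > middle > peripheral and top > bottom anisotropy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .convolution_model import ModelSpec, RegionalWeights, predict_pupil
from .fitting import Trial
from .response_functions import ErlangParams
from .video_events import (
    EventTraces,
    GazeTrace,
    Recording,
    RegionGrid,
    extract_event_traces,
)


@dataclass
class VideoSpec:
    """A piecewise-constant programmatic video.

    ``segments`` is a list of (start_s, end_s, gray) entries tiling the
    duration without overlap; ``gray`` is either a scalar 0–255 level for a
    uniform frame or a (rows, cols) array of per-region levels.
    """

    resolution: tuple[int, int] = (64, 48)  # (width, height)
    frame_rate: float = 25.0
    duration: float = 60.0
    segments: Sequence[tuple[float, float, object]] = field(default_factory=list)
    grid: RegionGrid = field(default_factory=RegionGrid)

    def __post_init__(self) -> None:
        if not self.segments:
            self.segments = [(0.0, self.duration, 128)]
        prev_end = 0.0
        for start, end, gray in self.segments:
            if start != prev_end or end <= start:
                raise ValueError("segments must tile the duration without overlap")
            levels = np.asarray(gray)
            if np.any(levels < 0) or np.any(levels > 255):
                raise ValueError("gray levels must lie in [0, 255]")
            prev_end = end
        if prev_end != self.duration:
            raise ValueError("segments must cover the full duration")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


def _frame_from_gray(gray, resolution: tuple[int, int], grid: RegionGrid) -> np.ndarray:
    w, h = resolution
    levels = np.asarray(gray)
    img = np.empty((h, w), dtype=np.uint8)
    if levels.ndim == 0:
        img[:] = int(levels)
    else:
        if levels.shape != (grid.rows, grid.cols):
            raise ValueError("per-region gray must have shape (rows, cols)")
        row_edges, col_edges = grid.edges(h, w)
        for i in range(grid.rows):
            for j in range(grid.cols):
                img[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]] = int(
                    round(float(levels[i, j]))
                )
    return np.repeat(img[..., None], 3, axis=2)


def generate_video(spec: VideoSpec, out_path: Optional[str | Path] = None) -> np.ndarray:
    """Deterministic (n_frames, h, w, 3) uint8 frame stack from a VideoSpec.

    With ``out_path`` the stack is also written to disk (``.npy`` always
    works; other extensions are passed to imageio and require a suitable
    plugin).
    """
    frames = np.empty((spec.n_frames, spec.resolution[1], spec.resolution[0], 3), np.uint8)
    for t in range(spec.n_frames):
        time = t / spec.frame_rate
        for start, end, gray in spec.segments:
            if start <= time < end or (time >= end and end == spec.duration):
                frames[t] = _frame_from_gray(gray, spec.resolution, spec.grid)
                break
    if out_path is not None:
        out_path = Path(out_path)
        if out_path.suffix == ".npy":
            np.save(out_path, frames)
        else:
            import imageio.v3 as iio

            iio.imwrite(out_path, frames, fps=spec.frame_rate)
    return frames


def random_step_spec(
    n_steps: int = 10,
    duration: float = 60.0,
    seed: int = 0,
    resolution: tuple[int, int] = (64, 48),
    frame_rate: float = 25.0,
    per_region: bool = False,
    min_separation: float = 2.0,
    max_separation: Optional[float] = None,
    grid: Optional[RegionGrid] = None,
) -> VideoSpec:
    """VideoSpec with ``n_steps`` random luminance steps.

    Step times are drawn so consecutive steps are at least ``min_separation``
    seconds apart (default 2 s, keeping events well separated; pass e.g.
    ``min_separation=0.2, max_separation=0.8`` for a dense-events preset).
    Gray levels are uniform random in [10, 245]; with ``per_region`` each
    region gets its own independent level.
    """
    rng = np.random.default_rng(seed)
    grid = grid or RegionGrid()
    times: list[float] = []
    t = 0.0
    for _ in range(n_steps):
        lo = min_separation
        hi = max_separation if max_separation is not None else min_separation * 2.0
        t += rng.uniform(lo, hi)
        times.append(t)
    if times[-1] >= duration - min_separation:
        scale = (duration - min_separation) / times[-1]
        times = [x * scale for x in times]

    def draw_gray():
        if per_region:
            return rng.uniform(10, 245, size=(grid.rows, grid.cols))
        return float(rng.uniform(10, 245))

    # snap boundaries to frame times so steps are frame-aligned
    times = [round(x * frame_rate) / frame_rate for x in times]
    segments = []
    prev = 0.0
    for x in times:
        segments.append((prev, x, draw_gray()))
        prev = x
    segments.append((prev, duration, draw_gray()))
    return VideoSpec(
        resolution=resolution,
        frame_rate=frame_rate,
        duration=duration,
        segments=segments,
        grid=grid,
    )


def generate_gaze(
    duration: float,
    rate: float,
    pattern: str = "fixate_center",
    resolution: tuple[int, int] = (64, 48),
    seed: int = 0,
    point: Optional[tuple[float, float]] = None,
    gaps: Sequence[tuple[float, float]] = (),
) -> GazeTrace:
    """Deterministic gaze trace; validity gaps injectable as (start, end) s."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    w, h = resolution
    cx, cy = w / 2.0, h / 2.0
    if pattern == "fixate_center":
        x = np.full(n, cx)
        y = np.full(n, cy)
    elif pattern == "fixate_point":
        if point is None:
            raise ValueError("fixate_point requires a point")
        x = np.full(n, float(point[0]))
        y = np.full(n, float(point[1]))
    elif pattern == "smooth_drift":
        # random-walk drift, smoothed, clamped to the screen
        steps = rng.normal(0, 0.5, size=(2, n)).cumsum(axis=1)
        x = np.clip(cx + steps[0], 0, w - 1)
        y = np.clip(cy + steps[1], 0, h - 1)
    else:
        raise ValueError(f"unknown gaze pattern {pattern!r}")
    valid = np.ones(n, dtype=bool)
    for start, end in gaps:
        valid[(t >= start) & (t < end)] = False
    return GazeTrace(t, x, y, valid)


@dataclass
class SimulationTruth:
    """Ground-truth forward-model parameters for a simulation."""

    lum_params: ErlangParams = field(
        default_factory=lambda: ErlangParams(n=13.7, t_max=0.28)
    )
    contrast_params: ErlangParams = field(
        default_factory=lambda: ErlangParams(n=3.0, t_max=0.53)
    )
    contrast_weight: float = 0.42
    weights: RegionalWeights = field(
        default_factory=lambda: RegionalWeights((1.0, 0.8, 0.5, 0.9, 0.7, 0.4))
    )
    noise_sd: float = 0.5  # z-units
    seed: int = 0
    use_regions: bool = False

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def model_spec(self, rf_family: str = "erlang") -> ModelSpec:
        return ModelSpec(
            rf_family=rf_family,
            contrast_weight=self.contrast_weight,
            use_regions=self.use_regions,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "lum_params": asdict(self.lum_params),
            "contrast_params": asdict(self.contrast_params),
            "contrast_weight": self.contrast_weight,
            "weights": list(self.weights.w),
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "use_regions": self.use_regions,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def generate_pupil(
    traces: EventTraces,
    truth: SimulationTruth,
    pupil_rate: float = 500.0,
) -> Recording:
    """Forward-model pupil trace plus i.i.d. Gaussian noise, at ``pupil_rate``.

    The noiseless signal is the z-scored combined model prediction at the
    event rate, linearly interpolated up to the pupil sampling rate; noise is
    white Gaussian in the same z-units, seeded from the truth.
    """
    pred = predict_pupil(
        traces,
        truth.lum_params,
        truth.contrast_params,
        truth.model_spec(),
        truth.weights,
    )
    t_end = traces.timestamps[-1]
    n = int(round(t_end * pupil_rate)) + 1
    t = np.arange(n) / pupil_rate
    signal_hi = np.interp(t, traces.timestamps, pred.combined)
    rng = np.random.default_rng(truth.seed)
    pupil = signal_hi + rng.normal(0.0, truth.noise_sd, size=n)
    return Recording(
        timestamps=t,
        pupil=pupil,
        valid=np.ones(n, dtype=bool),
        rate=pupil_rate,
    )


def simulate_trials(
    n_trials: int,
    truth: SimulationTruth,
    seed: int = 0,
    n_steps: int = 10,
    duration: float = 60.0,
    resolution: tuple[int, int] = (64, 48),
    frame_rate: float = 25.0,
    per_region: bool = False,
    pupil_rate: float = 500.0,
    **spec_kwargs,
) -> list[Trial]:
    """End-to-end trial generator: video → event traces → noisy pupil."""
    rng = np.random.default_rng(seed)
    trials = []
    for i in range(n_trials):
        sub = int(rng.integers(0, 2**31 - 1))
        spec = random_step_spec(
            n_steps=n_steps,
            duration=duration,
            seed=sub,
            resolution=resolution,
            frame_rate=frame_rate,
            per_region=per_region,
            **spec_kwargs,
        )
        frames = generate_video(spec)
        traces = extract_event_traces(frames, frame_rate, grid=spec.grid)
        trial_truth = SimulationTruth(
            lum_params=truth.lum_params,
            contrast_params=truth.contrast_params,
            contrast_weight=truth.contrast_weight,
            weights=truth.weights,
            noise_sd=truth.noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            use_regions=truth.use_regions,
        )
        trials.append(Trial(traces=traces, recording=generate_pupil(traces, trial_truth, pupil_rate)))
    return trials
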