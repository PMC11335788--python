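"""File input/output: gaze CSVs, event-trace caches, result CSVs.

Naming conventions follow the tool's on-disk layout: event caches are stored
as ``[movieName]_[subjectName]_VF_LAB_6X8.npz`` in a ``Visual events``
directory, and fitted parameters / predictions go to
``[movieName]_[subjectName]_parameters.csv`` and
``[movieName]_[subjectName]_modelPrediction.csv`` in a ``csv results``
directory.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .convolution_model import PupilPrediction
from .fitting import FitResult
from .video_events import EventTraces, GazeTrace, Recording, RegionGrid

EVENTS_DIRNAME = "Visual events"
RESULTS_DIRNAME = "csv results"


def cache_stem(movie: str, subject: str, grid: Optional[RegionGrid] = None) -> str:
    grid = grid or RegionGrid()
    return f"{movie}_{subject}_VF_LAB_{grid.rows}X{grid.cols}"


def read_gaze_csv(
    path: str | Path,
    time_unit: str = "s",
    timestamp_col: str = "timestamp",
    x_col: str = "gaze_x",
    y_col: str = "gaze_y",
    pupil_col: str = "pupil",
) -> tuple[GazeTrace, Recording]:
    """Read an eye-tracking CSV into a gaze trace and a pupil recording.

    Expects a header row with timestamp (seconds or milliseconds), gaze x/y
    in screen pixels (origin top-left), and pupil size in arbitrary units.
    Samples with non-finite gaze or non-positive pupil are marked invalid.
    """
    df = pd.read_csv(path)
    for col in (timestamp_col, x_col, y_col, pupil_col):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    t = df[timestamp_col].to_numpy(dtype=float)
    if time_unit == "ms":
        t = t / 1000.0
    elif time_unit != "s":
        raise ValueError("time_unit must be 's' or 'ms'")
    t = t - t[0]
    x = df[x_col].to_numpy(dtype=float)
    y = df[y_col].to_numpy(dtype=float)
    pupil = df[pupil_col].to_numpy(dtype=float)
    gaze_valid = np.isfinite(x) & np.isfinite(y)
    pupil_valid = np.isfinite(pupil) & (pupil > 0)
    rate = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 1.0
    gaze = GazeTrace(t, x, y, gaze_valid)
    recording = Recording(t, pupil, pupil_valid, rate, gaze=gaze)
    return gaze, recording


def save_event_cache(
    traces: EventTraces, movie: str, subject: str, out_dir: str | Path
) -> Path:
    """Write an event-trace cache (.npz) under the 'Visual events' directory."""
    out_dir = Path(out_dir) / EVENTS_DIRNAME
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{cache_stem(movie, subject, traces.grid)}.npz"
    np.savez_compressed(
        path,
        timestamps=traces.timestamps,
        luminance_change=traces.luminance_change,
        contrast_change=traces.contrast_change,
        mode=np.array(traces.mode),
        frame_rate=np.array(traces.frame_rate),
        resolution=np.array(traces.resolution),
        grid_rows=np.array(traces.grid.rows),
        grid_cols=np.array(traces.grid.cols),
    )
    return path


def load_event_cache(path: str | Path) -> EventTraces:
    with np.load(path) as data:
        return EventTraces(
            timestamps=data["timestamps"],
            luminance_change=data["luminance_change"],
            contrast_change=data["contrast_change"],
            mode=str(data["mode"]),
            frame_rate=float(data["frame_rate"]),
            resolution=tuple(int(v) for v in data["resolution"]),
            grid=RegionGrid(int(data["grid_rows"]), int(data["grid_cols"])),
        )


def export_events_csv(traces: EventTraces, path: str | Path) -> Path:
    """Plain-CSV export of the event traces (one column pair per region)."""
    cols = {"timestamp": traces.timestamps}
    for r in range(traces.luminance_change.shape[1]):
        cols[f"lum_change_r{r}"] = traces.luminance_change[:, r]
    for r in range(traces.contrast_change.shape[1]):
        cols[f"contrast_change_r{r}"] = traces.contrast_change[:, r]
    path = Path(path)
    pd.DataFrame(cols).to_csv(path, index=False)
    return path


def write_parameters_csv(
    result: FitResult, movie: str, subject: str, out_dir: str | Path
) -> Path:
    """Two-column parameter CSV (name, value), incl. performance rows."""
    out_dir = Path(out_dir) / RESULTS_DIRNAME
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = list(result.param_values.items())
    rows += [
        ("test_r2_mean", result.test_r2_mean),
        ("test_r2_sd", result.test_r2_sd),
        ("correlation", result.test_r_mean),
        ("rmse", result.test_rmse_mean),
        ("bic", result.bic),
        ("n_free_parameters", result.n_free_parameters),
    ]
    path = out_dir / f"{movie}_{subject}_parameters.csv"
    pd.DataFrame(rows, columns=["parameter", "value"]).to_csv(path, index=False)
    return path


def write_prediction_csv(
    prediction: PupilPrediction,
    actual_pupil: np.ndarray,
    movie: str,
    subject: str,
    out_dir: str | Path,
) -> Path:
    """Prediction CSV with actual and per-component predicted pupil columns."""
    out_dir = Path(out_dir) / RESULTS_DIRNAME
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{movie}_{subject}_modelPrediction.csv"
    pd.DataFrame(
        {
            "timestamp": prediction.timestamps,
            "actual_pupil": np.asarray(actual_pupil, dtype=float),
            "predicted_combined": prediction.combined,
            "predicted_luminance": prediction.luminance_only,
            "predicted_contrast": prediction.contrast_only,
        }
    ).to_csv(path, index=False)
    return path


def write_gaze_csv(gaze: GazeTrace, pupil: np.ndarray, path: str | Path) -> Path:
    """Write a gaze+pupil CSV in the package's input format."""
    path = Path(path)
    pd.DataFrame(
        {
            "timestamp": gaze.timestamps,
            "gaze_x": np.where(gaze.valid, gaze.x, np.nan),
            "gaze_y": np.where(gaze.valid, gaze.y, np.nan),
            "pupil": np.asarray(pupil, dtype=float),
        }
    ).to_csv(path, index=False)
    return path
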