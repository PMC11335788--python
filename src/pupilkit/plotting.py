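"""Static plot export of model predictions and event traces."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .convolution_model import PupilPrediction
from .video_events import EventTraces


def plot_prediction(
    prediction: PupilPrediction,
    actual_pupil: Optional[np.ndarray] = None,
    traces: Optional[EventTraces] = None,
    path: str | Path = "prediction.png",
) -> Path:
    """Export a figure with event traces and predicted (vs actual) pupil size."""
    n_rows = 2 if traces is not None else 1
    fig, axes = plt.subplots(n_rows, 1, figsize=(10, 3 * n_rows), sharex=True, squeeze=False)
    ax_idx = 0
    if traces is not None:
        ax = axes[ax_idx, 0]
        ax.plot(traces.timestamps, traces.luminance_change.mean(axis=1), label="luminance change")
        ax.plot(traces.timestamps, traces.contrast_change.mean(axis=1), label="contrast change")
        ax.set_ylabel("cd/m² per step")
        ax.legend(loc="upper right", fontsize="small")
        ax_idx += 1
    ax = axes[ax_idx, 0]
    if actual_pupil is not None:
        ax.plot(prediction.timestamps, actual_pupil, color="0.6", label="actual")
    ax.plot(prediction.timestamps, prediction.combined, label="predicted (combined)")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("pupil size (z)")
    ax.legend(loc="upper right", fontsize="small")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
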