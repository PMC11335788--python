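"""Extraction of luminance and contrast events from video frames.

The pipeline mirrors how a video stimulus reaches the retina: each 8-bit RGB
frame is converted to CIELAB lightness (L*, rescaled to 0-255), mapped to
physical luminance in cd/m² through the display's gamma curve, optionally
re-projected onto a gaze-contingent canvas (so the gaze point sits at the
canvas center, approximating retinal coordinates), and aggregated over a
rectangular grid of visual-field regions.  Per-region luminance *changes* are
computed as a lag-2 sliding difference at the native frame rate — at 25 Hz
this compares frames 80 ms apart, roughly the integration window of the
visual system — and the contrast trace is the elementwise absolute value of
the luminance-change trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
from skimage.color import rgb2lab


class VideoDecodeError(RuntimeError):
    """A frame could not be decoded from a video source."""


@dataclass(frozen=True)
class FrameLuminanceMap:
    """Physical luminance (cd/m²) of one video frame."""

    values: np.ndarray
    frame_index: int
    timestamp: float


@dataclass(frozen=True)
class RegionGrid:
    """Rectangular tiling of the canvas into rows × cols regions.

    Regions are numbered row-major.  Each region belongs to one of six
    weight groups (labels ``W1`` … ``W6``): the vertical split separates the
    top half of the visual field from the bottom half, and columns are
    banded by eccentricity (central, middle, peripheral) symmetrically about
    the vertical midline.  ``W1`` is the top-central group.
    """

    rows: int = 6
    cols: int = 8

    N_GROUPS = 6
    GROUP_LABELS = ("W1", "W2", "W3", "W4", "W5", "W6")

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("grid needs at least 2 rows and 2 columns")

    @property
    def n_regions(self) -> int:
        return self.rows * self.cols

    def edges(self, height: int, width: int) -> tuple[np.ndarray, np.ndarray]:
        """Pixel boundaries of the tiling; trailing regions absorb remainders."""
        if height < self.rows or width < self.cols:
            raise ValueError("canvas smaller than the region grid")
        row_base, col_base = height // self.rows, width // self.cols
        row_edges = np.array([i * row_base for i in range(self.rows)] + [height])
        col_edges = np.array([j * col_base for j in range(self.cols)] + [width])
        return row_edges, col_edges

    def _eccentricity_band(self, col: int) -> int:
        # symmetric offset from the vertical midline, banded 0/1/2
        half = self.cols // 2
        offset = col - half if col >= half else half - 1 - col
        # innermost offset -> central, outermost -> peripheral
        band_of_offset = np.minimum((np.arange(half) * 3) // half, 2)
        return int(band_of_offset[offset])

    def weight_group_of_region(self) -> np.ndarray:
        """Group index (0..5, i.e. W1..W6) for every region, row-major."""
        groups = np.empty(self.n_regions, dtype=int)
        for r in range(self.rows):
            bottom = r >= (self.rows + 1) // 2
            for c in range(self.cols):
                band = self._eccentricity_band(c)
                groups[r * self.cols + c] = band + (3 if bottom else 0)
        return groups


@dataclass
class GazeTrace:
    """Gaze samples in screen pixels (origin top-left), with a validity mask."""

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.timestamps)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("gaze fields must have equal length")


@dataclass
class Recording:
    """Aligned pupil (and optionally gaze) time series for one trial."""

    timestamps: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray
    rate: float
    gaze: Optional[GazeTrace] = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)


@dataclass
class EventTraces:
    """Per-region luminance-change and contrast-change series for one video.

    ``luminance_change`` is signed (cd/m² per step); ``contrast_change`` is
    its elementwise absolute value.  Shapes are (n_steps, n_regions).
    """

    timestamps: np.ndarray
    luminance_change: np.ndarray
    contrast_change: np.ndarray
    mode: str  # "screen" | "gaze_contingent"
    frame_rate: float
    resolution: tuple[int, int]  # (width, height) of the source video
    grid: RegionGrid = field(default_factory=RegionGrid)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.luminance_change = np.asarray(self.luminance_change, dtype=float)
        self.contrast_change = np.asarray(self.contrast_change, dtype=float)
        if self.luminance_change.shape != self.contrast_change.shape:
            raise ValueError("luminance and contrast traces must share a shape")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def n_steps(self) -> int:
        return self.luminance_change.shape[0]


def rgb_to_lightness(frame: np.ndarray) -> np.ndarray:
    """CIELAB L* of an 8-bit sRGB frame, rescaled to the 0-255 range.

    Assumes sRGB primaries under the D65 white point.  Black maps to 0 and
    white to 255.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB frame, got shape {frame.shape}")
    lab = rgb2lab(frame.astype(np.uint8))
    return lab[..., 0] * (255.0 / 100.0)


def lightness_to_luminance(
    lightness: np.ndarray | float,
    gamma: float = 2.2,
    max_luminance: float = 212.0,
) -> np.ndarray | float:
    """Display gamma curve: luminance = max_luminance · (L*/255)^gamma (cd/m²)."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if max_luminance <= 0:
        raise ValueError("max_luminance must be positive")
    arr = np.asarray(lightness, dtype=float)
    if np.any(arr < 0) or np.any(arr > 255):
        raise ValueError("lightness values must lie in [0, 255]")
    out = max_luminance * (arr / 255.0) ** gamma
    return float(out) if np.isscalar(lightness) else out


def build_canvas(
    frame_luminance: np.ndarray,
    gaze: Optional[tuple[float, float]] = None,
    canvas_scale: float = 1.5,
) -> np.ndarray:
    """Place a luminance frame on the (gaze-contingent) canvas.

    Screen mode (``gaze is None``): the canvas is the frame itself.  Gaze
    mode: the frame is placed on a zero-luminance (black-surround) canvas of
    ``canvas_scale`` times the frame size so that the gaze pixel coincides
    with the canvas center; frame content falling outside is cropped.  Gaze
    coordinates are clamped to the screen bounds first.
    """
    frame_luminance = np.asarray(frame_luminance, dtype=float)
    if canvas_scale < 1:
        raise ValueError("canvas_scale must be >= 1")
    if gaze is None:
        return frame_luminance
    h, w = frame_luminance.shape
    ch, cw = int(round(h * canvas_scale)), int(round(w * canvas_scale))
    canvas = np.zeros((ch, cw), dtype=float)
    gx = int(round(min(max(gaze[0], 0.0), w - 1)))
    gy = int(round(min(max(gaze[1], 0.0), h - 1)))
    top, left = ch // 2 - gy, cw // 2 - gx
    # overlap of the shifted frame with the canvas
    r0, r1 = max(top, 0), min(top + h, ch)
    c0, c1 = max(left, 0), min(left + w, cw)
    if r0 < r1 and c0 < c1:
        canvas[r0:r1, c0:c1] = frame_luminance[r0 - top : r1 - top, c0 - left : c1 - left]
    return canvas


def region_means(canvas: np.ndarray, grid: RegionGrid) -> np.ndarray:
    """Mean luminance of each grid region, row-major, length rows×cols."""
    canvas = np.asarray(canvas, dtype=float)
    h, w = canvas.shape
    row_edges, col_edges = grid.edges(h, w)
    means = np.empty(grid.n_regions)
    k = 0
    for i in range(grid.rows):
        for j in range(grid.cols):
            block = canvas[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
            means[k] = block.mean()
            k += 1
    return means


def downsample_gaze(
    gaze: GazeTrace,
    frame_timestamps: np.ndarray,
    screen_center: tuple[float, float],
) -> GazeTrace:
    """Average gaze samples into one sample per video frame.

    Each frame's interval runs from its timestamp to the next frame's.  The
    value is the mean of the valid gaze samples falling in the interval;
    intervals with no valid sample carry the last valid position forward,
    and leading gaps use the screen center.  The validity flag marks frames
    that had at least one valid sample.
    """
    frame_timestamps = np.asarray(frame_timestamps, dtype=float)
    n = len(frame_timestamps)
    if n == 0:
        return GazeTrace(frame_timestamps, np.empty(0), np.empty(0), np.empty(0, bool))
    step = np.median(np.diff(frame_timestamps)) if n > 1 else np.inf
    edges = np.append(frame_timestamps, frame_timestamps[-1] + step)
    idx = np.searchsorted(edges, gaze.timestamps, side="right") - 1
    ok = (idx >= 0) & (idx < n) & gaze.valid

    x = np.empty(n)
    y = np.empty(n)
    valid = np.zeros(n, dtype=bool)
    sums_x = np.bincount(idx[ok], weights=gaze.x[ok], minlength=n)
    sums_y = np.bincount(idx[ok], weights=gaze.y[ok], minlength=n)
    counts = np.bincount(idx[ok], minlength=n)
    last = screen_center
    for f in range(n):
        if counts[f] > 0:
            last = (sums_x[f] / counts[f], sums_y[f] / counts[f])
            valid[f] = True
        x[f], y[f] = last
    return GazeTrace(frame_timestamps, x, y, valid)


def _as_frame_iter(frames) -> Iterator[np.ndarray]:
    if isinstance(frames, np.ndarray) and frames.ndim == 4:
        yield from frames
    else:
        yield from frames


def extract_event_traces(
    frames: Iterable[np.ndarray] | np.ndarray,
    frame_rate: float,
    gaze: Optional[GazeTrace] = None,
    *,
    gamma: float = 2.2,
    max_luminance: float = 212.0,
    grid: Optional[RegionGrid] = None,
    canvas_scale: float = 1.5,
    lag: int = 2,
) -> EventTraces:
    """Extract per-region luminance/contrast change traces from video frames.

    The change at frame t is region_mean(t) − region_mean(t − lag); for the
    first ``lag`` frames the reference is an all-black frame, so those steps
    carry the frames' own region means.  With a gaze trace the frames are
    first re-projected onto the gaze-contingent canvas (black surround,
    ``canvas_scale`` times the screen).
    """
    grid = grid or RegionGrid()
    mode = "screen" if gaze is None else "gaze_contingent"
    means: list[np.ndarray] = []
    resolution: Optional[tuple[int, int]] = None
    gaze_per_frame: Optional[GazeTrace] = None

    for i, frame in enumerate(_as_frame_iter(frames)):
        frame = np.asarray(frame)
        if frame.ndim != 3 or frame.shape[2] != 3:
            raise VideoDecodeError(f"frame {i} is not an H×W×3 RGB image")
        if resolution is None:
            resolution = (frame.shape[1], frame.shape[0])
        lum = lightness_to_luminance(rgb_to_lightness(frame), gamma, max_luminance)
        if mode == "gaze_contingent":
            if gaze_per_frame is None:
                # one gaze sample per frame; gaze must cover the video duration
                ts = np.arange(int(np.ceil(gaze.timestamps[-1] * frame_rate)) + 1) / frame_rate
                center = (resolution[0] / 2.0, resolution[1] / 2.0)
                gaze_per_frame = downsample_gaze(gaze, ts, center)
            if i < len(gaze_per_frame.x):
                point = (gaze_per_frame.x[i], gaze_per_frame.y[i])
            else:
                point = (gaze_per_frame.x[-1], gaze_per_frame.y[-1])
            canvas = build_canvas(lum, point, canvas_scale)
        else:
            canvas = lum
        means.append(region_means(canvas, grid))

    if not means:
        raise VideoDecodeError("no decodable frames in the input")

    m = np.stack(means)  # (n_frames, n_regions)
    n = m.shape[0]
    change = np.empty_like(m)
    change[: min(lag, n)] = m[: min(lag, n)]  # black-frame reference
    if n > lag:
        change[lag:] = m[lag:] - m[:-lag]
    timestamps = np.arange(n) / frame_rate
    return EventTraces(
        timestamps=timestamps,
        luminance_change=change,
        contrast_change=np.abs(change),
        mode=mode,
        frame_rate=frame_rate,
        resolution=resolution,
        grid=grid,
    )


def iter_video_frames(path: str | Path) -> Iterator[np.ndarray]:
    """Decode frames from a video file (or a .npy frame stack) as 8-bit RGB.

    Container decoding is delegated to imageio; which containers work depends
    on the plugins available at run time.
    """
    path = Path(path)
    if path.suffix == ".npy":
        arr = np.load(path)
        if arr.ndim != 4 or arr.shape[-1] != 3:
            raise VideoDecodeError(f"{path} does not hold an (n, h, w, 3) frame stack")
        yield from arr.astype(np.uint8)
        return
    import imageio.v3 as iio

    try:
        for frame in iio.imiter(path):
            frame = np.asarray(frame)
            if frame.ndim == 2:
                frame = np.stack([frame] * 3, axis=-1)
            yield frame[..., :3].astype(np.uint8)
    except Exception as exc:  # pragma: no cover - depends on plugins present
        raise VideoDecodeError(f"could not decode {path}: {exc}") from exc
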