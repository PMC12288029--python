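"""Dense single-level Lucas-Kanade optical flow and per-frame mean magnitude.

Each pair of consecutive grayscale frames yields a dense flow field by
solving, at every pixel, the 2x2 windowed least-squares normal equations
built from spatial gradients (central differences, replicate padding) and
the temporal difference.  Pixels whose structure tensor is near-singular
(smaller eigenvalue below a noise threshold) get zero flow.  The per-pixel
flow magnitude is then averaged over the whole frame, reducing a trial to a
single magnitude trace: one value per frame, with the first frame defined as
0 so the series length equals the frame count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

#: ITU-R BT.601 luma weights
GRAY_WEIGHTS = (0.299, 0.587, 0.114)

#: default LK parameters: 5x5 window, eigenvalue cutoff on [0,1] intensities
DEFAULT_WINDOW_RADIUS = 2
DEFAULT_NOISE_THRESHOLD = 0.0039


@dataclass(frozen=True)
class FlowField:
    """Dense flow between two frames: per-pixel displacement (px/frame)."""

    u: np.ndarray  # horizontal (column) displacement
    v: np.ndarray  # vertical (row) displacement

    def __post_init__(self) -> None:
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must share the frame's dimensions")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass(frozen=True)
class FrameMagnitudeSeries:
    """One mean flow magnitude per frame for one trial."""

    trial_id: str
    values: np.ndarray
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.values) < 0):
            raise ValueError("magnitudes must be >= 0")

    def __len__(self) -> int:
        return len(self.values)


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """BT.601 luminance of an H x W x 3 frame with intensities in [0, 1]."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("expected an H x W x 3 frame")
    if frame.min() < 0.0 or frame.max() > 1.0:
        raise ValueError("intensities must lie in [0, 1]")
    return frame @ np.asarray(GRAY_WEIGHTS)


def _central_gradients(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradients with replicate (edge) padding."""
    p = np.pad(img, 1, mode="edge")
    gx = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0  # d/dcol
    gy = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0  # d/drow
    return gx, gy


def lk_flow(
    prev: np.ndarray,
    nxt: np.ndarray,
    window_radius: int = DEFAULT_WINDOW_RADIUS,
    noise_threshold: float = DEFAULT_NOISE_THRESHOLD,
) -> FlowField:
    """Lucas-Kanade flow from ``prev`` to ``nxt`` (grayscale, same shape).

    Spatial gradients are taken on the mean of the two frames (the standard
    symmetric choice, which keeps sub-pixel estimates unbiased); the temporal
    gradient is ``nxt - prev``.  Windowed sums use a (2r+1)^2 box with
    replicate padding.  Where the smaller eigenvalue of the summed structure
    tensor falls below ``noise_threshold`` the flow is set to zero.
    """
    prev = np.asarray(prev, dtype=float)
    nxt = np.asarray(nxt, dtype=float)
    if prev.shape != nxt.shape:
        raise ValueError("frame dimension mismatch")
    if prev.ndim != 2:
        raise ValueError("expected 2-D grayscale frames")
    if window_radius < 1:
        raise ValueError("window_radius must be >= 1")
    size = 2 * window_radius + 1
    if size > min(prev.shape):
        raise ValueError("window larger than frame")

    gx, gy = _central_gradients(0.5 * (prev + nxt))
    gt = nxt - prev

    n_win = size * size

    def wsum(a: np.ndarray) -> np.ndarray:
        return ndimage.uniform_filter(a, size=size, mode="nearest") * n_win

    sxx = wsum(gx * gx)
    sxy = wsum(gx * gy)
    syy = wsum(gy * gy)
    sxt = wsum(gx * gt)
    syt = wsum(gy * gt)

    half_tr = 0.5 * (sxx + syy)
    disc = np.sqrt((0.5 * (sxx - syy)) ** 2 + sxy**2)
    lam_min = half_tr - disc

    det = sxx * syy - sxy**2
    reliable = (lam_min >= noise_threshold) & (det > np.finfo(float).tiny)
    safe_det = np.where(reliable, det, 1.0)
    u = np.where(reliable, -(syy * sxt - sxy * syt) / safe_det, 0.0)
    v = np.where(reliable, -(sxx * syt - sxy * sxt) / safe_det, 0.0)
    return FlowField(u=u, v=v)


def frame_mean_magnitude(flow: FlowField) -> float:
    """Arithmetic mean of the per-pixel flow magnitude (borders included)."""
    if flow.u.size == 0:
        raise ValueError("empty flow field")
    return float(flow.magnitude.mean())


def magnitude_series(
    frames,
    trial_id: str = "",
    frame_rate: float = 30.0,
    window_radius: int = DEFAULT_WINDOW_RADIUS,
    noise_threshold: float = DEFAULT_NOISE_THRESHOLD,
    resize_factor: float = 1.0,
) -> FrameMagnitudeSeries:
    """Reduce an ordered frame sequence to one mean magnitude per frame.

    ``values[0] = 0`` by convention (flow needs a predecessor frame), so the
    series length equals the frame count.  ``frames`` may be any iterable of
    2-D (grayscale) or H x W x 3 arrays; RGB frames are converted.  An
    optional ``resize_factor`` < 1 downsamples frames by local-mean blocks
    before flow, for large inputs.
    """
    values: list[float] = []
    prev: np.ndarray | None = None
    shape: tuple[int, ...] | None = None
    for frame in frames:
        frame = np.asarray(frame, dtype=float)
        if frame.ndim == 3:
            frame = to_grayscale(frame)
        if frame.ndim != 2:
            raise ValueError("frames must be 2-D grayscale or H x W x 3 RGB")
        if shape is None:
            shape = frame.shape
        elif frame.shape != shape:
            raise ValueError("odd-sized frame in sequence")
        if resize_factor != 1.0:
            step = max(1, int(round(1.0 / resize_factor)))
            h, w = frame.shape
            frame = frame[: h - h % step, : w - w % step]
            frame = frame.reshape(h // step, step, w // step, step).mean(axis=(1, 3))
        if prev is None:
            values.append(0.0)
        else:
            flow = lk_flow(prev, frame, window_radius, noise_threshold)
            values.append(frame_mean_magnitude(flow))
        prev = frame
    if len(values) < 2:
        raise ValueError("need at least 2 frames")
    return FrameMagnitudeSeries(trial_id=trial_id, values=np.asarray(values), frame_rate=frame_rate)


def read_frame_dir(path: str | Path) -> list[np.ndarray]:
    """Read a per-trial directory of PNG/JPEG frames in lexicographic order."""
    import imageio.v3 as iio

    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
    if not files:
        raise FileNotFoundError(f"no frame images under {path}")
    frames = []
    for f in files:
        arr = iio.imread(f)
        arr = arr.astype(float) / 255.0
        if arr.ndim == 3:
            arr = to_grayscale(arr[..., :3])
        frames.append(arr)
    return frames


def write_frame_dir(frames: np.ndarray, path: str | Path) -> None:
    """Write frames as zero-padded 8-bit grayscale PNGs."""
    import imageio.v3 as iio

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(path / f"frame_{i:06d}.png", (np.clip(frame, 0, 1) * 255).astype(np.uint8))


def write_series_csv(series: FrameMagnitudeSeries, path: str | Path) -> None:
    """Two-column per-trial CSV: frame_index (from 0), mean_magnitude."""
    pd.DataFrame(
        {"frame_index": np.arange(len(series.values)), "mean_magnitude": series.values}
    ).to_csv(path, index=False)


def read_series_csv(path: str | Path, trial_id: str = "", frame_rate: float = 30.0) -> FrameMagnitudeSeries:
    df = pd.read_csv(path)
    return FrameMagnitudeSeries(
        trial_id=trial_id or Path(path).stem,
        values=df["mean_magnitude"].to_numpy(dtype=float),
        frame_rate=frame_rate,
    )
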