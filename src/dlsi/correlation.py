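"""Temporal intensity autocorrelation estimation.

Estimates ``g2(tau) = <I(t) I(t+tau)> / <I>**2`` from per-pixel intensity
time series sampled at the camera frame rate. The numerator at lag ``k``
averages over the ``N - k`` available pairs; the denominator is the squared
full-series mean. The estimate is computed either by an FFT-accelerated
autocorrelation (default) or by direct summation; both give identical
results to rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.fft import next_fast_len, rfft, irfft

__all__ = [
    "AcquisitionMeta",
    "IntensitySeries",
    "G2Curve",
    "FrameStack",
    "subtract_black_level",
    "compute_g2",
    "compute_g2_stack",
]


class DegenerateInputError(ValueError):
    """The input carries no usable signal (e.g. non-positive mean intensity)."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """Camera acquisition metadata.

    Attributes
    ----------
    frame_rate : float
        Frames per second.
    exposure : float
        Exposure time per frame, seconds; must not exceed the frame interval.
    black_level : float
        Camera black level in counts (offset already present in raw data).
    total_duration : float
        Record length in seconds.
    """

    frame_rate: float
    exposure: float
    black_level: float
    total_duration: float

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.exposure < 0 or self.exposure > 1.0 / self.frame_rate + 1e-15:
            raise ValueError(
                f"exposure ({self.exposure}) must be within the frame interval "
                f"({1.0 / self.frame_rate})"
            )
        if self.black_level < 0:
            raise ValueError("black_level must be >= 0")
        if self.total_duration * self.frame_rate < 2:
            raise ValueError("record must contain at least two frames")

    @property
    def n_frames(self) -> int:
        return int(round(self.total_duration * self.frame_rate))

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.frame_rate


@dataclass(frozen=True)
class IntensitySeries:
    """Per-pixel intensity record (counts per frame) with its metadata."""

    values: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if len(self.values) != self.meta.n_frames:
            raise ValueError(
                f"series length {len(self.values)} inconsistent with metadata "
                f"({self.meta.n_frames} frames)"
            )


@dataclass(frozen=True)
class G2Curve:
    """Sampled intensity autocorrelation for one pixel or ROI.

    ``lags`` start at 0 with step ``1/frame_rate``; ``n_pairs[k]`` is the
    number of frame pairs averaged at lag ``k``.
    """

    lags: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        values = np.asarray(self.values, dtype=float)
        n_pairs = np.asarray(self.n_pairs, dtype=int)
        if not (len(lags) == len(values) == len(n_pairs)):
            raise ValueError("lags, values and n_pairs must have equal length")
        if len(lags) and (lags[0] != 0.0 or np.any(np.diff(lags) <= 0)):
            raise ValueError("lags must start at 0 and be strictly increasing")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "n_pairs", n_pairs)

    def __len__(self) -> int:
        return len(self.lags)


@dataclass(frozen=True)
class FrameStack:
    """T x H x W intensity stack with acquisition metadata."""

    frames: np.ndarray
    meta: AcquisitionMeta
    black_level_subtracted: float = 0.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        if frames.shape[0] < 2:
            raise ValueError("stack must contain at least two frames")
        object.__setattr__(self, "frames", frames)

    @property
    def shape(self):
        return self.frames.shape


def subtract_black_level(stack: FrameStack, level: float | None = None) -> FrameStack:
    """Subtract the camera black level from every sample.

    No clamping is applied: values may go negative. Clamping would bias the
    low-intensity tail of the distribution — the very statistics that give
    rise to the positive long-lag offset the noise term models.

    ``level`` defaults to the metadata black level. The returned stack
    records the cumulative subtraction and zeroes the metadata black level.
    """
    if level is None:
        level = stack.meta.black_level
    if level < 0:
        raise ValueError("black level must be >= 0")
    meta = replace(stack.meta, black_level=0.0)
    return FrameStack(
        frames=stack.frames.astype(float) - level,
        meta=meta,
        black_level_subtracted=stack.black_level_subtracted + level,
    )


def _lag_count(meta: AcquisitionMeta, max_lag: float, n: int) -> int:
    if max_lag >= meta.total_duration:
        raise ValueError(
            f"max_lag ({max_lag}) must be shorter than the record "
            f"({meta.total_duration})"
        )
    n_lags = int(np.floor(max_lag * meta.frame_rate + 1e-9)) + 1
    return min(n_lags, n)


def _raw_autocorr_fft(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Sum over t of x[t] * x[t+k] for k in [0, n_lags), via FFT."""
    n = x.shape[-1]
    m = next_fast_len(n + n_lags)
    fx = rfft(x, m)
    acf = irfft(fx * np.conj(fx), m)
    return acf[..., :n_lags]


def _raw_autocorr_direct(x: np.ndarray, n_lags: int) -> np.ndarray:
    n = len(x)
    return np.array([np.dot(x[: n - k], x[k:]) for k in range(n_lags)])


def compute_g2(series: IntensitySeries, max_lag: float, method: str = "fft") -> G2Curve:
    """Estimate g2(tau) for a single intensity series.

    Parameters
    ----------
    series : IntensitySeries
        Black-level-corrected intensity record.
    max_lag : float
        Longest lag to evaluate, seconds; must be shorter than the record.
    method : {"fft", "direct"}
        FFT-accelerated (default) or direct-sum evaluation; the two agree
        to rounding error.
    """
    x = series.values
    n = len(x)
    mean = x.mean()
    if mean <= 0:
        raise DegenerateInputError(f"mean intensity must be > 0, got {mean}")
    n_lags = _lag_count(series.meta, max_lag, n)
    if method == "fft":
        raw = _raw_autocorr_fft(x, n_lags)
    elif method == "direct":
        raw = _raw_autocorr_direct(x, n_lags)
    else:
        raise ValueError(f"unknown method {method!r}")
    n_pairs = n - np.arange(n_lags)
    values = raw / n_pairs / mean**2
    lags = np.arange(n_lags) * series.meta.frame_interval
    return G2Curve(lags=lags, values=values, n_pairs=n_pairs)


def compute_g2_stack(
    stack: FrameStack, max_lag: float, chunk_pixels: int = 256
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Estimate g2(tau) for every pixel of a stack.

    Returns ``(lags, g2, degenerate)`` where ``g2`` has shape ``H x W x L``
    and ``degenerate`` is a boolean ``H x W`` mask of pixels whose mean
    intensity is not positive. Degenerate pixels keep their position and
    carry NaN curves rather than being dropped.
    """
    t, h, w = stack.shape
    flat = stack.frames.reshape(t, h * w)  # view; per-chunk float64 copies below
    n_lags = _lag_count(stack.meta, max_lag, t)
    lags = np.arange(n_lags) * stack.meta.frame_interval
    n_pairs = t - np.arange(n_lags)

    means = flat.mean(axis=0, dtype=float)
    degenerate = means <= 0
    g2 = np.full((h * w, n_lags), np.nan)
    idx = np.nonzero(~degenerate)[0]
    for start in range(0, len(idx), chunk_pixels):
        sel = idx[start : start + chunk_pixels]
        x = np.ascontiguousarray(flat[:, sel].T, dtype=float)
        raw = _raw_autocorr_fft(x, n_lags)
        g2[sel] = raw / n_pairs / (means[sel, None] ** 2)
    return lags, g2.reshape(h, w, n_lags), degenerate.reshape(h, w)
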