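"""Laser speckle contrast imaging: contrast, flow indices and model inversion.

Contrast is ``K = sigma / <I>`` over either a 5x5 spatial neighborhood
(spatial contrast) or 25-frame temporal blocks (temporal contrast); the
per-frame / per-block contrast images are averaged over the record. The
conventional blood flow index is ``BFI = 1/K**2`` and relative flow is the
contrast ratio ``K_baseline / K_test``.

For multiple scattering from unordered motion (field correlation
``exp(-sqrt(tau/tau_c))``) the exposure-integrated contrast has the closed
form (``x = 2*sqrt(T/tau_c)``)::

    K^2 = (tau_c/T)*(1 + 2*exp(-x)) + 3*(tau_c/T)**1.5 * exp(-x)
          + 1.5*(tau_c/T)**2 * (exp(-x) - 1)

which equals the exposure integral
``(2/T) * int_0^T (1 - tau/T) * exp(-2*sqrt(tau/tau_c)) dtau``. Inverting
this relation for ``tau_c`` turns a contrast measurement into a correlation
time under the n = 0.5 assumption, from which relative flow follows as a
ratio of correlation times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.optimize import brentq

from .correlation import AcquisitionMeta, FrameStack

__all__ = [
    "ContrastImage",
    "emulate_exposure",
    "spatial_contrast",
    "temporal_contrast",
    "bfi",
    "contrast_model_n05",
    "invert_contrast_n05",
    "rcbf_lsci",
    "rcbf_lsci_n05",
]


class NoRootError(ValueError):
    """The measured contrast is outside the attainable range of the model."""


@dataclass(frozen=True)
class ContrastImage:
    """Speckle contrast map with its provenance.

    ``K`` is NaN where the contrast is undefined (zero local mean, or the
    2-pixel border for spatial contrast). ``exposure_equivalent`` is the
    effective exposure represented by the underlying frames.
    """

    K: np.ndarray
    kind: str  # "spatial" | "temporal"
    window: int
    exposure_equivalent: float

    def __post_init__(self) -> None:
        if self.kind not in ("spatial", "temporal"):
            raise ValueError("kind must be 'spatial' or 'temporal'")
        object.__setattr__(self, "K", np.asarray(self.K, dtype=float))


def emulate_exposure(stack: FrameStack, n_avg: int) -> FrameStack:
    """Average non-overlapping blocks of ``n_avg`` frames.

    Emulates a longer camera exposure of ``n_avg / frame_rate`` seconds from
    a high-frame-rate stack; trailing frames that do not fill a block are
    dropped. A stack of T frames yields ``T // n_avg`` output frames.
    """
    if n_avg < 1:
        raise ValueError("n_avg must be >= 1")
    t = stack.frames.shape[0]
    if n_avg > t:
        raise ValueError(f"n_avg ({n_avg}) exceeds the frame count ({t})")
    n_out = t // n_avg
    frames = stack.frames[: n_out * n_avg].reshape(
        n_out, n_avg, *stack.frames.shape[1:]
    ).mean(axis=1)
    meta = AcquisitionMeta(
        frame_rate=stack.meta.frame_rate / n_avg,
        exposure=n_avg / stack.meta.frame_rate,
        black_level=stack.meta.black_level,
        total_duration=n_out * n_avg / stack.meta.frame_rate,
    )
    return FrameStack(frames=frames, meta=meta,
                      black_level_subtracted=stack.black_level_subtracted)


def _local_contrast(frame: np.ndarray, size: int) -> np.ndarray:
    """Population SD / mean over a centered size x size window; NaN at the
    border (within size//2 of an edge) and where the local mean is <= 0."""
    mean = uniform_filter(frame, size=size, mode="constant")
    mean_sq = uniform_filter(frame * frame, size=size, mode="constant")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.sqrt(var) / mean
    k[mean <= 0] = np.nan
    b = size // 2
    k[:b, :] = np.nan
    k[-b:, :] = np.nan
    k[:, :b] = np.nan
    k[:, -b:] = np.nan
    return k


def spatial_contrast(stack: FrameStack, size: int = 5) -> ContrastImage:
    """Per-frame spatial contrast in a ``size x size`` neighborhood,
    averaged over all frames.

    Edge pixels (within ``size // 2`` of a border) are flagged NaN rather
    than padded: padding would bias K. The SD is the population SD
    (normalized by the window size).
    """
    h, w = stack.frames.shape[1:]
    if h < size or w < size:
        raise ValueError(f"frames must be at least {size} x {size}")
    acc = np.zeros((h, w))
    for frame in stack.frames.astype(float):
        acc += _local_contrast(frame, size)
    return ContrastImage(
        K=acc / stack.frames.shape[0], kind="spatial", window=size,
        exposure_equivalent=stack.meta.exposure,
    )


def temporal_contrast(
    stack: FrameStack, block: int = 25, spatial_mean_size: int | None = None
) -> ContrastImage:
    """Per-pixel contrast over non-overlapping ``block``-frame windows,
    averaged over blocks.

    With static scattering the per-pixel temporal mean is not the true
    ensemble mean intensity (the frozen speckle pattern survives temporal
    averaging), which makes plain temporal contrast vary unphysically from
    pixel to pixel; ``spatial_mean_size`` optionally replaces the
    denominator with a local spatial average of the temporal mean to
    correct this.
    """
    t = stack.frames.shape[0]
    if t < block:
        raise ValueError(f"need at least {block} frames, got {t}")
    n_blocks = t // block
    frames = stack.frames[: n_blocks * block].astype(float)
    blocks = frames.reshape(n_blocks, block, *frames.shape[1:])
    mean = blocks.mean(axis=1)
    sd = blocks.std(axis=1)  # population SD
    if spatial_mean_size is not None:
        mean = np.stack(
            [uniform_filter(m, size=spatial_mean_size, mode="nearest") for m in mean]
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(mean > 0, sd / mean, np.nan)
    return ContrastImage(
        K=k.mean(axis=0), kind="temporal", window=block,
        exposure_equivalent=stack.meta.exposure,
    )


def bfi(K):
    """Blood flow index of the simplified contrast model: ``1 / K**2``.

    Zero contrast has no finite flow index and maps to +inf.
    """
    k = np.asarray(K, dtype=float)
    if np.any(k < 0):
        raise ValueError("contrast must be >= 0")
    with np.errstate(divide="ignore"):
        out = 1.0 / (k * k)
    return out if out.ndim else float(out)


def contrast_model_n05(T: float, tau_c):
    """Squared contrast K^2 for exposure T under n = 0.5 field dynamics.

    Equals ``(2/T) * int_0^T (1 - tau/T) * exp(-2*sqrt(tau/tau_c)) dtau``
    evaluated in closed form; assumes full coherence and no static
    scattering (beta = rho = 1). Monotonically increasing in tau_c at fixed
    T, from 0 (fast dynamics) to 1 (frozen speckle).
    """
    if T <= 0:
        raise ValueError("exposure T must be > 0")
    tc = np.asarray(tau_c, dtype=float)
    if np.any(tc <= 0):
        raise ValueError("tau_c must be > 0")
    r = tc / T
    x = 2.0 / np.sqrt(r)
    # closed form suffers catastrophic cancellation for small x (slow
    # dynamics); switch to the Maclaurin series of the exposure integral
    small = x < 0.05
    ex = np.exp(-np.where(small, 1.0, x))
    core = (r * (1.0 + 2.0 * ex) + 3.0 * r**1.5 * ex + 1.5 * r**2 * (ex - 1.0))
    if np.any(small):
        xs = np.where(small, x, 1.0)
        series = (1.0 - 8.0 * xs / 15.0 + xs**2 / 6.0 - 4.0 * xs**3 / 105.0
                  + xs**4 / 144.0 - 8.0 * xs**5 / 945.0)
        core = np.where(small, series, core)
    return core if core.ndim else float(core)


def invert_contrast_n05(K: float, T: float) -> float:
    """Solve the n = 0.5 contrast model for tau_c given measured contrast.

    Bracketed root finding on log(tau_c), using the strict monotonicity of
    K^2 in tau_c. ``K`` must lie strictly inside (0, 1); values outside the
    attainable range raise :class:`NoRootError`.
    """
    if T <= 0:
        raise ValueError("exposure T must be > 0")
    if not 0.0 < K < 1.0:
        raise NoRootError(
            f"contrast K={K} is outside the invertible range (0, 1) "
            f"of the n=0.5 model at exposure T={T}"
        )
    target = K * K

    def g(log_tc):
        return contrast_model_n05(T, np.exp(log_tc)) - target

    lo, hi = np.log(T) - 2.0, np.log(T) + 2.0
    for _ in range(60):
        if g(lo) < 0:
            break
        lo -= 2.0
    for _ in range(60):
        if g(hi) > 0:
            break
        hi += 2.0
    if not (g(lo) < 0 < g(hi)):
        raise NoRootError(f"failed to bracket tau_c for K={K}, T={T}")
    return float(np.exp(brentq(g, lo, hi, xtol=1e-15, rtol=1e-14)))


def rcbf_lsci(K_baseline, K_test):
    """Relative flow from the simplified contrast model: K_baseline / K_test.

    Equivalent to ``sqrt(BFI_test / BFI_baseline)`` of the 1/K^2 model.
    """
    kb = np.asarray(K_baseline, dtype=float)
    kt = np.asarray(K_test, dtype=float)
    if np.any(kb <= 0) or np.any(kt <= 0):
        raise ValueError("contrasts must be > 0")
    out = kb / kt
    return out if out.ndim else float(out)


def rcbf_lsci_n05(K_baseline: float, K_test: float, T: float) -> float:
    """Relative flow via the n = 0.5 model: ratio of inverted correlation
    times ``tau_c(K_baseline) / tau_c(K_test)``."""
    tb = invert_contrast_n05(K_baseline, T)
    tt = invert_contrast_n05(K_test, T)
    return tb / tt
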