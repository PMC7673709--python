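"""Synthetic speckle generation with known ground truth.

Produces single-pixel intensity time series and phantom image stacks whose
field autocorrelation is the stretched exponential ``exp(-(tau/tau_c)**n)``,
with a controllable static scattering fraction, speckle averaging (beta),
two-component dynamic mixtures and a simple camera model (shot noise, read
noise, quantization, black level). Every analysis stage of the package can
be exercised against exact ground truth with these generators.

Fields are stationary complex circular Gaussian processes synthesized by
circulant embedding of the target autocovariance: ``exp(-|tau/tau_c|**n)``
is the characteristic function of a symmetric alpha-stable law for
``0 < n <= 2`` and hence positive definite, so the embedding succeeds for
all supported exponents (the grid is doubled on numerical failure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import fft, ifft

from .correlation import AcquisitionMeta, FrameStack, IntensitySeries
from .models import DLSIParams, Regime, classify_regime, regime_for_pure_n

__all__ = [
    "SpeckleFieldSeries",
    "CameraModel",
    "PhantomRegion",
    "PhantomSpec",
    "gen_field",
    "mix_fields",
    "compose_intensity",
    "gen_phantom_stack",
    "gen_spatial_speckle_frames",
]

#: Refuse phantoms above this many samples (T*H*W); tile instead.
MAX_PHANTOM_SAMPLES = 2**28


@dataclass(frozen=True)
class SpeckleFieldSeries:
    """Complex field samples at frame-rate sampling with their target form.

    ``E`` is normalized so that mean |E|^2 = 1 in expectation; real and
    imaginary parts are zero-mean, equal-variance and uncorrelated
    (circular symmetry).
    """

    E: np.ndarray
    fs: float
    tau_c: float
    n: float
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "E", np.asarray(self.E, dtype=complex))


@dataclass(frozen=True)
class CameraModel:
    """Simple camera: counts = quantize(gain * Poisson(I/gain) + read + black).

    ``gain`` is counts per photoelectron; shot noise is Poisson on the
    photoelectron number, read noise is additive Gaussian in counts,
    quantization rounds to integer counts (clipped at zero, as an ADC does).
    """

    gain: float = 1.0
    read_noise_sd: float = 0.0
    black_level: float = 0.0
    quantization: bool = False
    shot_noise: bool = False

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")

    def apply(self, intensity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        counts = np.asarray(intensity, dtype=float)
        if self.shot_noise:
            counts = self.gain * rng.poisson(np.maximum(counts, 0.0) / self.gain)
        if self.read_noise_sd > 0:
            counts = counts + rng.normal(0.0, self.read_noise_sd, counts.shape)
        counts = counts + self.black_level
        if self.quantization:
            counts = np.clip(np.round(counts), 0, None)
        return counts


IDEAL_CAMERA = CameraModel()


def _circulant_eigs(n_samples: int, fs: float, tau_c: float, n: float) -> np.ndarray:
    """Eigenvalues of the circulant embedding of the target autocovariance."""
    m = 1
    while m < 2 * n_samples:
        m *= 2
    for _ in range(4):
        k = np.arange(m)
        lag = np.minimum(k, m - k) / fs
        r = np.exp(-((lag / tau_c) ** n))
        lam = fft(r).real
        if lam.min() > -1e-8 * lam.max():
            return np.maximum(lam, 0.0)
        m *= 2
    raise RuntimeError("circulant embedding failed to become positive definite")


def gen_field(
    n: float,
    tau_c: float,
    fs: float,
    duration: float,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> SpeckleFieldSeries:
    """Generate a complex Gaussian field with autocovariance exp(-(tau/tau_c)**n).

    Parameters
    ----------
    n : float
        Stretched-exponential exponent, 0 < n <= 2.
    tau_c : float
        Decorrelation time, seconds.
    fs : float
        Sampling rate, Hz.
    duration : float
        Record length, seconds (fs * duration >= 2 samples).
    seed
        Seed (int / SeedSequence / Generator). Identical seeds give
        bit-identical output.
    """
    if not 0 < n <= 2:
        raise ValueError("n must be in (0, 2]")
    if tau_c <= 0 or fs <= 0:
        raise ValueError("tau_c and fs must be > 0")
    n_samples = int(round(fs * duration))
    if n_samples < 2:
        raise ValueError("need at least two samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = _circulant_eigs(n_samples, fs, tau_c, n)
    m = len(lam)
    xi = (rng.standard_normal(m) + 1j * rng.standard_normal(m)) / np.sqrt(2.0)
    e = fft(xi * np.sqrt(lam / m))[:n_samples]
    return SpeckleFieldSeries(
        E=e, fs=fs, tau_c=tau_c, n=n, seed=seed if isinstance(seed, int) else None
    )


def mix_fields(
    field1: SpeckleFieldSeries, field2: SpeckleFieldSeries, d: float
) -> SpeckleFieldSeries:
    """Intensity-weighted superposition sqrt(d)*E1 + sqrt(1-d)*E2.

    The two fields must be independently generated; the resulting field
    autocorrelation is then the intensity-weighted average
    ``d*g1_1 + (1-d)*g1_2`` (the cross terms vanish).
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError("d must be in [0, 1]")
    if len(field1.E) != len(field2.E):
        raise ValueError("fields must have equal length")
    if field1.seed is not None and field1.seed == field2.seed:
        raise ValueError("component fields must come from independent seeds")
    e = np.sqrt(d) * field1.E + np.sqrt(1.0 - d) * field2.E
    return SpeckleFieldSeries(E=e, fs=field1.fs, tau_c=field1.tau_c, n=field1.n)


def compose_intensity(
    field_or_factory,
    rho: float,
    mean_counts: float,
    meta: AcquisitionMeta,
    camera: CameraModel = IDEAL_CAMERA,
    n_speckle_sum: int = 1,
    oversample: int = 1,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> IntensitySeries:
    """Compose a detected intensity series from dynamic and static fields.

    Per speckle the detected field is ``sqrt(rho)*E_dyn + sqrt(1-rho)*e^{i phi}``
    with a fixed random static phase ``phi``; ``n_speckle_sum`` independent
    speckles are averaged, which reduces the coherence factor to
    ``beta = 1/n_speckle_sum``. The result is scaled to ``mean_counts`` and
    passed through the camera model.

    ``field_or_factory`` is either a single :class:`SpeckleFieldSeries`
    (used when ``n_speckle_sum == 1``) or a callable ``f(rng) -> series``
    producing independent realizations for speckle summation.

    ``oversample > 1`` emulates in-exposure integration: the field must be
    sampled at ``oversample`` times the frame rate and intensity is
    box-averaged within each frame, which reproduces the temporal
    speckle-averaging loss of coherence (beta_t) at short tau_c.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be in [0, 1]")
    if mean_counts <= 0:
        raise ValueError("mean_counts must be > 0")
    if n_speckle_sum < 1:
        raise ValueError("n_speckle_sum must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if callable(field_or_factory):
        fields = [field_or_factory(rng) for _ in range(n_speckle_sum)]
    else:
        if n_speckle_sum != 1:
            raise ValueError("speckle summation needs a field factory for independence")
        fields = [field_or_factory]

    if oversample < 1:
        raise ValueError("oversample must be >= 1")
    total = np.zeros(len(fields[0].E), dtype=float)
    for f in fields:
        phi = rng.uniform(0.0, 2.0 * np.pi)
        e_tot = np.sqrt(rho) * f.E + np.sqrt(1.0 - rho) * np.exp(1j * phi)
        total += np.abs(e_tot) ** 2
    intensity = total / n_speckle_sum * mean_counts  # mean |E_tot|^2 = 1
    if oversample > 1:
        if len(intensity) != meta.n_frames * oversample:
            raise ValueError(
                "oversampled field length must be n_frames * oversample"
            )
        intensity = intensity.reshape(meta.n_frames, oversample).mean(axis=1)
    counts = camera.apply(intensity, rng)
    return IntensitySeries(values=counts, meta=meta)


@dataclass(frozen=True)
class PhantomRegion:
    """One phantom region: mask, ground-truth parameters and mean counts."""

    mask: np.ndarray
    params: DLSIParams
    mean_counts: float = 1000.0
    n: float = 1.0  # field exponent of the dominant component (d=0 side is n=1)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def regime(self) -> Regime:
        p = self.params
        if p.d == 0.0 and self.n in (0.5, 1.0, 2.0):
            return regime_for_pure_n(self.n)
        return classify_regime(p.X, p.d)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and ground truth of a synthetic image stack."""

    regions: tuple[PhantomRegion, ...]
    meta: AcquisitionMeta
    n_speckle_sum: int = 1
    camera: CameraModel = IDEAL_CAMERA

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        shapes = {r.mask.shape for r in self.regions}
        if len(shapes) != 1:
            raise ValueError("all region masks must share one shape")
        total = np.zeros(next(iter(shapes)), dtype=int)
        for r in self.regions:
            total += r.mask
        if np.any(total != 1):
            raise ValueError("region masks must partition the image")

    @property
    def shape(self):
        return self.regions[0].mask.shape


def _pixel_series(
    params: DLSIParams, n: float, meta: AcquisitionMeta, mean_counts: float,
    camera: CameraModel, n_speckle_sum: int, ss: np.random.SeedSequence,
) -> np.ndarray:
    rng = np.random.default_rng(ss)
    fs, dur = meta.frame_rate, meta.total_duration

    def factory(r: np.random.Generator) -> SpeckleFieldSeries:
        if params.d > 0.0:
            f2 = gen_field(params.X, params.tau_c, fs, dur, r)
            f1 = gen_field(1.0, params.tau_c, fs, dur, r)
            return mix_fields(f2, f1, params.d)
        return gen_field(n, params.tau_c, fs, dur, r)

    series = compose_intensity(
        factory, params.rho, mean_counts, meta, camera=camera,
        n_speckle_sum=n_speckle_sum, seed=rng,
    )
    return series.values


def gen_phantom_stack(spec: PhantomSpec, seed: int) -> tuple[FrameStack, dict]:
    """Generate a phantom stack plus exact ground-truth parameter maps.

    Each pixel receives an independent intensity series composed from its
    region's ground truth. Randomness derives from the master ``seed`` via
    ``numpy.random.SeedSequence(seed).spawn`` in raster order, so identical
    seeds give bit-identical stacks. Returns ``(stack, truth)`` with truth
    maps for tau_c, rho, beta, d, n, regime code and mean counts.
    """
    h, w = spec.shape
    t = spec.meta.n_frames
    if t * h * w > MAX_PHANTOM_SAMPLES:
        raise ValueError(
            f"phantom of {t * h * w} samples exceeds the cap "
            f"({MAX_PHANTOM_SAMPLES}); tile the field of view instead"
        )
    frames = np.empty((t, h, w), dtype=np.float32)
    truth = {
        name: np.zeros((h, w))
        for name in ("tau_c", "rho", "beta", "d", "n", "mean_counts")
    }
    truth["regime"] = np.full((h, w), int(Regime.INVALID), dtype=int)

    region_of = np.full((h, w), -1, dtype=int)
    for i, r in enumerate(spec.regions):
        region_of[r.mask] = i
        truth["tau_c"][r.mask] = r.params.tau_c
        truth["rho"][r.mask] = r.params.rho
        truth["beta"][r.mask] = 1.0 / spec.n_speckle_sum
        truth["d"][r.mask] = r.params.d
        truth["n"][r.mask] = r.n
        truth["mean_counts"][r.mask] = r.mean_counts
        truth["regime"][r.mask] = int(r.regime)

    children = np.random.SeedSequence(seed).spawn(h * w)
    for j in range(h * w):
        y, x = divmod(j, w)
        r = spec.regions[region_of[y, x]]
        frames[:, y, x] = _pixel_series(
            r.params, r.n, spec.meta, r.mean_counts, spec.camera,
            spec.n_speckle_sum, children[j],
        )
    return FrameStack(frames=frames, meta=spec.meta), truth


def gen_spatial_speckle_frames(
    h: int,
    w: int,
    n_frames: int,
    tau_c: float,
    n: float,
    fs: float,
    speckle_px_ratio: float = 2.0,
    static_fraction: float = 0.0,
    seed: int = 0,
) -> FrameStack:
    """Generate frames with *spatially* correlated, fully developed speckle.

    Per-pixel temporally correlated complex fields are low-pass filtered in
    space (Gaussian pupil) to a target speckle-to-pixel size ratio, giving
    realistic spatial statistics for spatial-contrast work. Optionally a
    frozen static speckle field of the given intensity fraction is added.
    Intensity is normalized to unit mean.
    """
    rng = np.random.default_rng(seed)
    lam = _circulant_eigs(n_frames, fs, tau_c, n)
    m = len(lam)
    xi = (rng.standard_normal((m, h, w)) + 1j * rng.standard_normal((m, h, w))) / np.sqrt(2)
    e = fft(xi * np.sqrt(lam / m)[:, None, None], axis=0)[:n_frames]

    # spatial low-pass: Gaussian pupil with 1/e^2 radius set by the speckle size
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    sigma_f = 1.0 / (2.0 * speckle_px_ratio)
    pupil = np.exp(-(fy**2 + fx**2) / (2 * sigma_f**2))
    e = np.fft.ifft2(np.fft.fft2(e, axes=(1, 2)) * pupil[None], axes=(1, 2))
    e /= np.sqrt(np.mean(np.abs(e) ** 2))

    if static_fraction > 0.0:
        es = rng.standard_normal((h, w)) + 1j * rng.standard_normal((h, w))
        es = np.fft.ifft2(np.fft.fft2(es) * pupil)
        es /= np.sqrt(np.mean(np.abs(es) ** 2))
        e = np.sqrt(1.0 - static_fraction) * e + np.sqrt(static_fraction) * es[None]

    intensity = np.abs(e) ** 2
    intensity /= intensity.mean()
    meta = AcquisitionMeta(
        frame_rate=fs, exposure=0.5 / fs, black_level=0.0, total_duration=n_frames / fs
    )
    return FrameStack(frames=intensity, meta=meta)
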