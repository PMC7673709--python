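"""End-to-end validation benchmarks on synthetic data.

These routines measure how well the full pipeline recovers known ground
truth under the standard study conditions (22,881 fps, 4 s records,
tau_c = 500 us unless stated): single-curve parameter recovery per dynamic
regime, F-test selection calibration, three-region phantom recovery, and
the directional model error of conventional LSCI under n = 0.5 dynamics.
They are deliberately deterministic given a master seed so that reported
numbers are reproducible.
"""

from __future__ import annotations

import numpy as np

from .correlation import AcquisitionMeta, compute_g2, compute_g2_stack
from .fitting import fit_curve, fit_image, select_model
from .lsci import emulate_exposure, invert_contrast_n05, temporal_contrast
from .models import DLSIParams, ModelLevel, ModelSpec
from .synthetic import (
    CameraModel,
    IntensitySeries,
    PhantomRegion,
    PhantomSpec,
    compose_intensity,
    gen_field,
    gen_phantom_stack,
    mix_fields,
)

__all__ = [
    "STUDY_FS",
    "STUDY_DURATION",
    "STUDY_TAU_C",
    "recovery_benchmark",
    "ftest_calibration",
    "phantom_benchmark",
    "lsci_directional_benchmark",
]

STUDY_FS = 22881.0
STUDY_DURATION = 4.0
STUDY_TAU_C = 500e-6
STUDY_MAX_LAG = 8.8e-3

#: Recovery conditions: pure regimes and two-component mixtures at rho=0.8.
RECOVERY_CONDITIONS = (
    {"label": "pure_n05", "n": 0.5, "d": 0.0, "X": 0.5},
    {"label": "pure_n1", "n": 1.0, "d": 0.0, "X": 0.5},
    {"label": "pure_n2", "n": 2.0, "d": 0.0, "X": 2.0},
    {"label": "mix_X05_d025", "n": 1.0, "d": 0.25, "X": 0.5},
    {"label": "mix_X05_d05", "n": 1.0, "d": 0.5, "X": 0.5},
    {"label": "mix_X05_d075", "n": 1.0, "d": 0.75, "X": 0.5},
    {"label": "mix_X2_d025", "n": 1.0, "d": 0.25, "X": 2.0},
    {"label": "mix_X2_d05", "n": 1.0, "d": 0.5, "X": 2.0},
    {"label": "mix_X2_d075", "n": 1.0, "d": 0.75, "X": 2.0},
)


def _study_meta() -> AcquisitionMeta:
    return AcquisitionMeta(
        frame_rate=STUDY_FS, exposure=0.5 / STUDY_FS, black_level=0.0,
        total_duration=STUDY_DURATION,
    )


def _study_series(n, d, X, rho, ss) -> IntensitySeries:
    rng = np.random.default_rng(ss)
    meta = _study_meta()
    if d > 0.0:
        f2 = gen_field(X, STUDY_TAU_C, STUDY_FS, STUDY_DURATION, rng)
        f1 = gen_field(1.0, STUDY_TAU_C, STUDY_FS, STUDY_DURATION, rng)
        field = mix_fields(f2, f1, d)
    else:
        field = gen_field(n, STUDY_TAU_C, STUDY_FS, STUDY_DURATION, rng)
    return compose_intensity(field, rho=rho, mean_counts=1000.0, meta=meta, seed=rng)


def recovery_benchmark(master_seed: int, n_seeds: int = 20, rho: float = 0.8) -> dict:
    """Median parameter-recovery errors per condition over ``n_seeds`` runs.

    Pure regimes are fitted with the static-level model at the true
    exponent; mixtures with the mixed-level model at the true X. Returns
    ``{label: {"tau_c_rel_err": ..., "rho_err": ..., "d_err": ...}}``
    (d_err is NaN for pure conditions).
    """
    out = {}
    for ci, cond in enumerate(RECOVERY_CONDITIONS):
        errs = {"tau_c_rel_err": [], "rho_err": [], "d_err": []}
        for seed in range(n_seeds):
            ss = np.random.SeedSequence((master_seed, ci, seed))
            s = _study_series(cond["n"], cond["d"], cond["X"], rho, ss)
            curve = compute_g2(s, STUDY_MAX_LAG)
            if cond["d"] > 0.0:
                spec = ModelSpec(level=ModelLevel.MIXED, X=cond["X"])
            else:
                spec = ModelSpec(level=ModelLevel.STATIC, n_fixed=cond["n"])
            res = fit_curve(curve, spec)
            errs["tau_c_rel_err"].append(res.params.tau_c / STUDY_TAU_C - 1.0)
            errs["rho_err"].append(res.params.rho - rho)
            errs["d_err"].append(
                res.params.d - cond["d"] if cond["d"] > 0.0 else np.nan
            )
        out[cond["label"]] = {k: float(np.median(v)) for k, v in errs.items()}
    return out


def ftest_calibration(master_seed: int, n_null: int = 100, n_power: int = 50,
                      alpha: float = 0.05) -> dict:
    """Selection rates of the mixed model under null and mixed truth.

    Null: curves whose truth is the Siegert+offset model (rho = 1, small
    noise-induced offset from a quantizing camera). Power: curves from the
    mixed model at d = 0.5 (X = 0.5) with static scattering rho = 0.8.
    """
    meta = _study_meta()
    cam = CameraModel(read_noise_sd=5.0, black_level=100.0, quantization=True)

    def null_curve(seed):
        rng = np.random.default_rng(np.random.SeedSequence((master_seed, 100, seed)))
        f = gen_field(1.0, STUDY_TAU_C, STUDY_FS, STUDY_DURATION, rng)
        s = compose_intensity(f, rho=1.0, mean_counts=1000.0, meta=meta,
                              camera=cam, seed=rng)
        vals = s.values - cam.black_level
        return compute_g2(IntensitySeries(values=vals, meta=meta), STUDY_MAX_LAG)

    def power_curve(seed):
        ss = np.random.SeedSequence((master_seed, 200, seed))
        s = _study_series(1.0, 0.5, 0.5, 0.8, ss)
        return compute_g2(s, STUDY_MAX_LAG)

    null_hits = sum(
        select_model(null_curve(s), alpha=alpha)[0].model.level == ModelLevel.MIXED
        for s in range(n_null)
    )
    power_hits = sum(
        select_model(power_curve(s), alpha=alpha)[0].model.level == ModelLevel.MIXED
        for s in range(n_power)
    )
    return {
        "null_mixed_rate": null_hits / n_null,
        "power_mixed_rate": power_hits / n_power,
        "n_null": n_null,
        "n_power": n_power,
    }


def three_region_phantom(duration: float = STUDY_DURATION) -> PhantomSpec:
    """32 x 32 phantom: parenchyma-like background (n=0.5, tau_c=1 ms,
    rho=0.8) with two vessel stripes (n=1, 200 us) and (n=2, 50 us)."""
    h = w = 32
    _, xx = np.mgrid[0:h, 0:w]
    vessel = (xx >= 20) & (xx < 26)
    large = (xx >= 8) & (xx < 14)
    paren = ~(vessel | large)
    meta = AcquisitionMeta(frame_rate=STUDY_FS, exposure=0.5 / STUDY_FS,
                           black_level=0.0, total_duration=duration)
    return PhantomSpec(
        regions=(
            PhantomRegion(mask=paren, params=DLSIParams(beta=1, rho=0.8, tau_c=1e-3),
                          n=0.5),
            PhantomRegion(mask=large, params=DLSIParams(beta=1, rho=1.0, tau_c=50e-6),
                          n=2.0),
            PhantomRegion(mask=vessel, params=DLSIParams(beta=1, rho=1.0, tau_c=200e-6),
                          n=1.0),
        ),
        meta=meta,
    )


def phantom_benchmark(master_seed: int) -> dict:
    """simulate -> g2 -> fit on the three-region phantom; regime accuracy
    and per-region median tau_c errors."""
    spec = three_region_phantom()
    stack, truth = gen_phantom_stack(spec, master_seed)
    lags, g2, degen = compute_g2_stack(stack, STUDY_MAX_LAG)
    maps = fit_image(lags, g2, degenerate=degen, model="auto")
    out = {
        "regime_accuracy": float(np.mean(maps.regime == truth["regime"])),
        "n_pixels": int(truth["regime"].size),
    }
    for name, region in zip(("parenchyma", "large_vessel", "vessel"), spec.regions):
        med = float(np.nanmedian(maps.tau_c[region.mask]))
        out[f"tau_c_rel_err_{name}"] = med / region.params.tau_c - 1.0
    return out


def lsci_directional_benchmark(master_seed: int, h: int = 8, w: int = 8,
                               n_avg: int = 114) -> dict:
    """Directional model error of LSCI under n = 0.5 dynamics.

    Simulates baseline (tau_c = 500 us) and 10x-slowed (tau_c = 5 ms)
    MU_n=0.5 stacks, emulates a ~5 ms exposure by frame averaging, computes
    temporal contrast, and compares relative flow from the conventional
    contrast-ratio model against the n = 0.5 inversion. Ground truth is 0.1.
    """
    meta = _study_meta()
    T = n_avg / STUDY_FS

    def mean_contrast(tau_c, tag):
        frames = np.empty((meta.n_frames, h, w), dtype=np.float32)
        children = np.random.SeedSequence((master_seed, tag)).spawn(h * w)
        for j in range(h * w):
            rng = np.random.default_rng(children[j])
            f = gen_field(0.5, tau_c, STUDY_FS, STUDY_DURATION, rng)
            s = compose_intensity(f, rho=1.0, mean_counts=1000.0, meta=meta, seed=rng)
            frames[:, j // w, j % w] = s.values
        from .correlation import FrameStack

        stack = FrameStack(frames=frames, meta=meta)
        avg = emulate_exposure(stack, n_avg)
        k = temporal_contrast(avg, block=25)
        return float(np.nanmean(k.K))

    kb = mean_contrast(STUDY_TAU_C, 301)
    ks = mean_contrast(10 * STUDY_TAU_C, 302)
    rcbf_conventional = kb / ks
    rcbf_n05 = invert_contrast_n05(kb, T) / invert_contrast_n05(ks, T)
    return {
        "true_rcbf": 0.1,
        "rcbf_lsci": rcbf_conventional,
        "rcbf_lsci_n05": rcbf_n05,
        "K_baseline": kb,
        "K_slowed": ks,
        "n_pixels": h * w,
    }
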