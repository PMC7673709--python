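"""Pipeline drivers tying the analysis stages together on disk.

Each driver reads its inputs, runs the corresponding library stage and
writes results plus a JSON manifest recording configuration, package
version and input checksums, so every artifact is reproducible from its
manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import tifffile

from .config import PipelineConfig
from .correlation import compute_g2_stack, subtract_black_level
from .fitting import fit_image
from .io import (
    read_g2_store,
    read_roi_mask,
    read_stack,
    roi_summary,
    write_g2_store,
    write_manifest,
    write_maps,
    write_stack,
)
from .lsci import (
    emulate_exposure,
    invert_contrast_n05,
    rcbf_lsci,
    spatial_contrast,
    temporal_contrast,
)
from .models import ModelLevel, ModelSpec
from .synthetic import PhantomSpec, gen_phantom_stack

__all__ = ["run_g2", "run_fit", "run_lsci", "run_simulate"]

log = logging.getLogger("dlsi")

_LEVELS = {
    "siegert": ModelLevel.SIEGERT,
    "siegert_offset": ModelLevel.SIEGERT_OFFSET,
    "static": ModelLevel.STATIC,
    "mixed": ModelLevel.MIXED,
}


def run_g2(config: PipelineConfig) -> Path:
    """Stack -> per-pixel g2 store (HDF5) + manifest."""
    if config.input is None:
        raise ValueError("run_g2 requires an input stack")
    stack = read_stack(config.input)
    if stack.meta.black_level > 0:
        stack = subtract_black_level(stack)
    lags, g2, degenerate = compute_g2_stack(stack, config.max_lag)
    out = Path(config.output_dir)
    store = out / "g2_store.h5"
    write_g2_store(store, lags, g2, degenerate, stack.meta)
    write_manifest(out / "g2_manifest.json", config.as_dict(), [config.input])
    log.info("g2 store written to %s (%d curves)", store, g2.shape[0] * g2.shape[1])
    return store


def run_fit(config: PipelineConfig, store: str | Path | None = None) -> Path:
    """g2 store -> parameter maps (TIFF) + ROI summary CSV + manifest."""
    out = Path(config.output_dir)
    store = Path(store) if store else out / "g2_store.h5"
    if not store.exists():
        raise FileNotFoundError(f"g2 store not found: {store}")
    lags, g2, flags, _meta = read_g2_store(store)
    model = "auto" if config.model == "auto" else ModelSpec(level=_LEVELS[config.model])
    maps = fit_image(
        lags, g2, degenerate=flags, model=model, alpha=config.alpha,
        adaptive_bounds=config.adaptive_bounds,
    )
    write_maps(out, maps)
    mask = None
    mask_path = out / "roi_mask.tif"
    if mask_path.exists():
        mask = read_roi_mask(mask_path)
    roi_summary(maps, mask).to_csv(out / "roi_summary.csv", index=False)
    write_manifest(out / "fit_manifest.json", config.as_dict(), [store])
    return out


def run_lsci(
    config: PipelineConfig, baseline: str | Path | None = None,
    test: str | Path | None = None, rcbf: bool = False,
) -> dict:
    """Stack(s) -> contrast / BFI maps, optionally rCBF between two stacks."""
    baseline = baseline or config.input
    if baseline is None:
        raise ValueError("run_lsci requires an input stack")
    if rcbf and test is None:
        raise ValueError("rCBF requires both a baseline and a test stack")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def contrast_of(path):
        stack = read_stack(path)
        if stack.meta.black_level > 0:
            stack = subtract_black_level(stack)
        stack = emulate_exposure(stack, config.n_avg)
        if config.lsci_kind == "spatial":
            return spatial_contrast(stack, size=config.spatial_window)
        return temporal_contrast(stack, block=config.temporal_block)

    kb = contrast_of(baseline)
    tifffile.imwrite(out / "contrast.tif", kb.K.astype(np.float32))
    with np.errstate(divide="ignore"):
        tifffile.imwrite(out / "bfi.tif", (1.0 / kb.K**2).astype(np.float32))
    results = {"contrast": kb}
    if rcbf:
        kt = contrast_of(test)
        rmap = np.where(
            (kb.K > 0) & (kt.K > 0), kb.K / np.where(kt.K > 0, kt.K, 1.0), np.nan
        )
        tifffile.imwrite(out / "rcbf_lsci.tif", rmap.astype(np.float32))
        results["rcbf"] = rmap
    write_manifest(
        out / "lsci_manifest.json", config.as_dict(),
        [p for p in (baseline, test) if p],
    )
    return results


def run_simulate(config: PipelineConfig, spec: PhantomSpec) -> Path:
    """Phantom spec -> HDF5 stack + truth TIFFs + manifest with the seed."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
        log.info("no seed supplied; generated seed %d", seed)
    stack, truth = gen_phantom_stack(spec, seed)
    stack_path = out / "phantom.h5"
    write_stack(stack_path, stack)
    for name, arr in truth.items():
        dtype = np.int16 if arr.dtype.kind in "iu" else np.float32
        tifffile.imwrite(out / f"truth_{name}.tif", arr.astype(dtype))
    write_manifest(
        out / "simulate_manifest.json", config.as_dict(), [],
        extra={"seed": seed, "shape": list(stack.frames.shape)},
    )
    return stack_path
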