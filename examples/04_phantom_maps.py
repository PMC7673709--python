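"""Two-region phantom: simulate, estimate g2 per pixel, fit parameter maps.

A 12x12 phantom with a parenchyma-like background (n = 0.5, tau_c = 1 ms,
20% static scattering) and a fast vessel stripe (n = 1, tau_c = 200 us) is
run through the per-pixel pipeline with automatic model selection.
"""

import numpy as np

from dlsi import (
    AcquisitionMeta,
    DLSIParams,
    PhantomRegion,
    PhantomSpec,
    compute_g2_stack,
    fit_image,
    gen_phantom_stack,
)
from dlsi.models import REGIME_NAMES, Regime

fs = 22881.0
meta = AcquisitionMeta(frame_rate=fs, exposure=0.5 / fs, black_level=0.0,
                       total_duration=1.0)
h = w = 12
_, xx = np.mgrid[0:h, 0:w]
vessel = (xx >= 8) & (xx < 11)
spec = PhantomSpec(regions=(
    PhantomRegion(mask=~vessel, params=DLSIParams(beta=1, rho=0.8, tau_c=1e-3), n=0.5),
    PhantomRegion(mask=vessel, params=DLSIParams(beta=1, rho=1.0, tau_c=200e-6), n=1.0),
), meta=meta)

stack, truth = gen_phantom_stack(spec, seed=5)
lags, g2, degen = compute_g2_stack(stack, max_lag=8.8e-3)
maps = fit_image(lags, g2, degenerate=degen, model="auto")

acc = np.mean(maps.regime == truth["regime"])
print(f"regime accuracy: {acc:.1%} of {h*w} pixels")
for name, mask, tc in (("background", ~vessel, 1e-3), ("vessel", vessel, 200e-6)):
    med = np.nanmedian(maps.tau_c[mask])
    print(f"{name}: median tau_c {med*1e6:.0f} us (truth {tc*1e6:.0f} us)")
labels = [REGIME_NAMES[Regime(v)] for v in np.unique(maps.regime)]
print("regimes present:", ", ".join(labels))
print("tau_c maps separate fast vessel pixels from slow background; the"
      " regime map recovers the imposed scattering regimes per pixel.")
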