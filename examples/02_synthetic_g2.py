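"""Simulate a speckle intensity record and estimate its autocorrelation.

Generates a complex Gaussian field with exponential correlation
(tau_c = 500 us) at 22,881 frames/s for 4 s, composes the detected
intensity, and compares the estimated g2(tau) with the Siegert prediction.
"""

import numpy as np

from dlsi import AcquisitionMeta, compose_intensity, compute_g2, gen_field

fs, duration, tau_c = 22881.0, 4.0, 500e-6
meta = AcquisitionMeta(frame_rate=fs, exposure=0.5 / fs, black_level=0.0,
                       total_duration=duration)

rng = np.random.default_rng(1)
field = gen_field(n=1.0, tau_c=tau_c, fs=fs, duration=duration, seed=rng)
series = compose_intensity(field, rho=1.0, mean_counts=1000.0, meta=meta, seed=rng)
curve = compute_g2(series, max_lag=4e-3)

print("lag (us)   g2 estimated   g2 Siegert")
for k in (0, 1, 5, 11, 23, 46):
    model = 1 + np.exp(-2 * curve.lags[k] / tau_c)
    print(f"{curve.lags[k]*1e6:8.1f}   {curve.values[k]:12.4f}   {model:10.4f}")

sel = (curve.lags > 0) & (curve.lags <= 4 * tau_c)
rms = np.sqrt(np.mean((curve.values[sel] - (1 + np.exp(-2 * curve.lags[sel] / tau_c))) ** 2))
print(f"\nRMS deviation from the Siegert model over lags <= 4 tau_c: {rms:.4f}")
print("The curve decays from ~2 to 1 with time constant tau_c/2 (field"
      " correlation squared); deviations reflect the finite 4 s record.")
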