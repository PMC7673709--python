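# dlsi — dynamic light scattering imaging analysis

`dlsi` analyzes high-frame-rate laser speckle recordings to map scatterer
dynamics — in practice, blood flow — pixel by pixel. It is aimed at
researchers doing laser speckle flowmetry (LSCI, LDF, MESI-style imaging)
who have time-resolved speckle stacks (tens of thousands of frames per
second) or per-pixel intensity autocorrelation curves and want quantitative
correlation times, static-scattering fractions and the dynamic light
scattering regime, rather than a relative blur index.

## The model

The measured intensity autocorrelation g₂(τ) = ⟨I(t)I(t+τ)⟩/⟨I⟩² is fitted
with a generalized Siegert relation

    g₂(τ) = 1 + βρ² m(τ)² + 2βρ(1−ρ) m(τ) + C
    m(τ)  = d·g₁⁽ⁿ⁼ˣ⁾(τ) + (1−d)·g₁⁽ⁿ⁼¹⁾(τ),   g₁⁽ⁿ⁾(τ) = exp(−(τ/τ_c)ⁿ)

where β is the coherence/speckle-averaging factor, 1−ρ the static
scattering fraction (adding the heterodyne term linear in g₁), C a constant
noise offset, and the field correlation is a stretched exponential whose
exponent n encodes the scattering regime: n = 0.5 for multiple scattering
from unordered motion (MU), n = 1 for single-unordered / multiple-ordered
(SU/MO), n = 2 for single-ordered (SO); d mixes a second component with
exponent X ∈ {0.5, 2}. Simpler models arise at parameter degeneracies
(C = 0, ρ = 1, d ∈ {0, 1}), and per pixel the complexity is chosen by a
forward chain of F tests (P ≤ 0.05). Relative flow is the correlation-time
ratio rCBF = τ_c,baseline/τ_c,test.

The package also implements speckle-contrast (LSCI) analysis: spatial (5×5)
and temporal (25-frame) contrast K = σ/⟨I⟩, exposure emulation by frame
averaging, the conventional BFI = 1/K² index, and the closed-form n = 0.5
contrast model K²(T, τ_c) with its inversion — which substantially reduces
the flow-change error of LSCI when the true dynamics are multiple-scattering
unordered.

A synthetic speckle generator (circulant embedding of the stretched-
exponential field covariance, static phasors, speckle summation, camera
noise) provides ground-truth data for every stage.

## Worked example

```
$ python examples/03_model_selection.py
level            form      RSS
SIEGERT          n=0.5    2.855e-03
SIEGERT_OFFSET   n=0.5    1.794e-03
STATIC           n=0.5    1.456e-03
MIXED            X=0.5    1.456e-03

accepted: STATIC (MU_N05)
tau_c = 972 us (truth 1000), rho = 0.65 (truth 0.70), beta = 1.00, C = -0.0044
```

A 4 s record at 22,881 frames/s was simulated with 30% static scattering
and n = 0.5 dynamics at τ_c = 1 ms. The chain accepts the static-scattering
model (adding the mixture is not significant), recovers the correlation
time within 3%, the dynamic fraction ρ within 0.05, and labels the pixel
MU (multiple scattering, unordered motion). The other examples show the
forward models (`01`), estimator convergence (`02`), per-pixel maps on a
phantom (`04`) and LSCI flow errors (`05`).

The same pipeline is scriptable from the shell:

```
dlsi simulate --output-dir run --seed 7 --size 16 --duration 0.5s
dlsi g2  --input run/phantom.h5 --output-dir run --max-lag 8.8ms
dlsi fit --output-dir run --model auto
dlsi lsci --input run/phantom.h5 --output-dir run --kind spatial
```

producing an HDF5 g₂ store, float32 TIFF parameter maps (τ_c, ρ, β, C, d,
regime, model level), a CSV ROI summary, and JSON manifests recording the
configuration, seed and input checksums.

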