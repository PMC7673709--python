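# Methods

## Scope and model

`dlsi` estimates, per pixel of a high-frame-rate speckle recording, the
temporal intensity autocorrelation

g₂(τ) = ⟨I(t)I(t+τ)⟩ / ⟨I⟩²

and fits it with a nested family of forward models built on a stretched-
exponential field correlation g₁(τ) = exp(−(τ/τ_c)ⁿ), n ∈ {0.5, 1, 2}:

1. **Siegert** (2 parameters): g₂ = 1 + β|g₁|². Assumes a fully dynamic,
   Gaussian-statistics field; β ∈ [0, 1] lumps source coherence with
   spatial and temporal speckle averaging (a composite of β_s and β_t —
   the two are not estimated separately).
2. **+ offset C** (3): a constant in [−1, 1] absorbing measurement-noise
   and finite-sampling effects on the long-lag level.
3. **+ static scattering** (4): with dynamic fraction ρ ∈ [0, 1],
   g₂ = 1 + βρ²|g₁|² + 2βρ(1−ρ)|g₁| + C. The linear (heterodyne) term comes
   from beating between the fluctuating field and the frozen field of
   non-moving scatterers.
4. **+ mixed dynamics** (5): |g₁| is replaced by
   d·g₁⁽ⁿ⁼ˣ⁾ + (1−d)·g₁⁽ⁿ⁼¹⁾ with X ∈ {0.5, 2}; the two component fields
   are uncorrelated so cross terms vanish and intensities add. Both mixture
   families (X = 0.5 and X = 2) are instances of one forward function with
   an X switch.

The fitted (X, d) map onto a five-way regime taxonomy: pure MU (n = 0.5),
pure SU/MO (n = 1), pure SO (n = 2), and the two mixed corridors. Purity
thresholds default to d ≤ 0.05 / d ≥ 0.95 (configurable); these are a
labelling convention for a continuous quantity, not physics.

Relative flow between two conditions is the correlation-time ratio
rCBF = τ_c,baseline / τ_c,test. No absolute flow calibration is attempted:
the mapping from τ_c to speed is deliberately out of scope.

## Correlation estimation

The estimator follows the ensemble definition with per-lag pair counting:
the numerator at lag k averages the N−k available products, the denominator
is the squared full-record mean. Computation uses a zero-padded real FFT;
a direct-sum path exists for verification and the two agree to ≤1e−10.
Lag 0 is computed raw (it is excluded from fitting anyway). The camera
black level is subtracted without clamping: clamping would truncate the
low-intensity tail of the speckle distribution and bias exactly the
statistics the offset term models. Default lag ranges are 0–8.8 ms, with
0–17.2 ms recommended for slow (e.g. ischemic) dynamics.

A deliberate consequence of this normalization, verified numerically: any
*stationary* additive camera effect (including ADC-clipped read noise,
whose conditional mean depends on intensity) shifts numerator and
denominator identically, so the long-lag limit of ĝ₂ stays at 1 and the
fitted C remains near zero for synthetic records. Real recordings acquire
nonzero offsets from insufficient sampling and nonstationary noise (laser
mode hopping, drifting dark level), which the generator intentionally does
not model; tests therefore assert that the long-lag distribution is centred
on 1 and narrows with record length, not that C becomes positive.

## Fitting

- **Window.** Lag 0 is always excluded. The tail is cut at the first lag
  where g₂−1 falls below 10% of its first-nonzero-lag value — the rule is
  applied to the correlation *amplitude*, since raw g₂ ideally never drops
  below 1. If fewer than 5 points survive, the first 5 nonzero lags are
  used; curves shorter than 6 lags are flagged short.
- **Initialization.** τ_c starts at the interpolated lag where g₂ crosses
  1 + (g₂(0)−1)/e²; for the ideal n = 1 Siegert curve this crossing is
  exactly τ_c. β starts at the first-lag amplitude (clipped to ≤1),
  ρ₀ = 0.9, d₀ = 0.5, C₀ = 0. On coarse grids the crossing interpolation
  carries an O((Δ/τ_c)²) bias (≈4% when τ_c spans only ~2 frames); it is an
  initializer, so this only seeds the optimizer.
- **Optimizer.** Bounded trust-region least squares (unweighted — no
  weighting scheme is assumed), tight tolerances (1e−12), with the τ_c
  coordinate scaled by its initializer. Bounds: β, ρ, d ∈ [0, 1],
  C ∈ [−1, 1], τ_c ∈ (0, max lag].
- **Model selection.** Forward chain Siegert → +C → +ρ → +d. Within each
  single-component level the best n is chosen by minimum RSS (the best
  form is re-identified at every complexity level); the mixed level picks
  X by minimum RSS. Each step advances only if
  F = (ΔRSS/1)/(RSS_complex/(N−p_complex)) is significant at α = 0.05, and
  the chain stops at the first non-significant step. Levels without
  residual degrees of freedom are skipped; a perfect complex fit (RSS = 0)
  is accepted outright. Each complex fit is additionally warm-started from
  the embedded simpler solution, which guarantees the nested-RSS
  monotonicity the F test presumes. When the mixed level selects the X that
  does not match the simpler level's n, nesting is still counted through
  d = 0 with Δp = 1 — a convention, since the strict nested structure is
  broken by the discrete n choice.
- **Image fitting.** Pixels are processed in descending order of the τ_c
  initializer (ties broken in raster order). After the first 30% of pixels,
  the β upper bound and ρ lower bound are set to mean + 2σ and mean − 2σ
  over a sliding window of the most recent ⌈0.3·n⌉ *converged* fits,
  recomputed for each pixel. This suppresses the characteristic artifacts
  of spuriously low β in slow pixels and spuriously low ρ in fast pixels.
  Degenerate pixels keep their positions with sentinel values. With
  adaptive bounds disabled the result is exactly the independent per-pixel
  fit.

## LSCI

Contrast is K = σ/⟨I⟩ with the population SD, over a centered 5×5 spatial
neighborhood per frame (edge pixels are flagged invalid rather than padded,
since padding biases K) or over non-overlapping 25-frame temporal blocks;
per-frame/per-block images are averaged as K (not K²). Longer exposures are
emulated by averaging non-overlapping blocks of n_avg frames (default 114,
≈5 ms at 22,881 fps; 91,544 frames → 803 emulated frames → 32 temporal
blocks). BFI = 1/K² and rCBF_LSCI = K_baseline/K_test.

For n = 0.5 dynamics the exposure-integrated contrast has the closed form
(x = 2√(T/τ_c), r = τ_c/T)

K² = r(1 + 2e⁻ˣ) + 3r^{3/2} e⁻ˣ + (3/2) r² (e⁻ˣ − 1),

which equals (2/T)∫₀ᵀ(1−τ/T)e^{−2√(τ/τ_c)}dτ; the implementation switches
to a Maclaurin series for x < 0.05 where the closed form cancels
catastrophically, and is validated against quadrature to ≤1e−8 over
T/τ_c ∈ [1e−3, 1e3]. The model assumes β = ρ = 1 (no static correction).
K² is strictly increasing in τ_c from 0 to 1, so inversion is a bracketed
root find on log τ_c; contrasts outside (0, 1) raise a no-root error.
Because temporal contrast divides by the per-pixel temporal mean, frozen
speckle makes it vary unphysically across a homogeneous medium; an option
substitutes a local spatial average of the mean.

## Synthetic data

Dynamic fields are stationary complex circular Gaussian processes with
autocovariance exp(−(τ/τ_c)ⁿ), synthesized by circulant embedding
(exp(−|τ|ⁿ) is a symmetric-stable characteristic function, hence positive
definite for 0 < n ≤ 2; the embedding grid is doubled on numerical
failure, and tiny negative eigenvalues are clipped). Mixtures are
√d·E₁ + √(1−d)·E₂ of independently seeded fields. Detected intensity per
speckle is |√ρ·E + √(1−ρ)e^{iφ}|² with a pixel-fixed random static phase;
averaging n independent speckles sets β = 1/n. A camera model adds optional
shot noise, Gaussian read noise, black level and integer quantization
(clipped at 0, as an ADC does). In-exposure integration can be emulated by
generating at an oversampling factor and box-averaging, which reproduces
the temporal-averaging loss of coherence. Spatially correlated frames for
contrast work are produced by low-pass filtering per-frame fields to a
speckle/pixel ratio of ~2. All randomness flows from one master seed via
`SeedSequence.spawn` in raster order, so outputs are bit-reproducible.

Default study conditions mirror the high-frame-rate protocol: 22,881
frames/s, 4 s records (≈91.5k frames), τ_c = 500 μs unless stated,
β = 1 (single speckle), mean 1000 counts. What the generator does *not*
emulate: photon-transport physics, vascular geometry, laser instability,
spatially varying β, or nonstationary noise — so passing tests demonstrate
estimator/fitting correctness under the stated statistical model, not
robustness to every artifact of real recordings.

## Validation results and known limitations

The benchmark suite (`dlsi.validation`, exercised by
`tests/test_acceptance.py` and `scripts/acceptance.py`) measures:

- Estimator-oracle and contrast-model agreement at numerical precision;
  initializer accuracy ≤0.01% on dense grids; LSCI bookkeeping counts.
- Parameter recovery at study conditions: pure regimes and X = 2 mixtures
  recover τ_c within a few percent, ρ within ~0.05 and d within ~0.01.
  **Limitation:** X = 0.5 mixtures show a systematic median τ_c bias
  (+12% at d = 0.25 rising to +36% at d = 0.75). The fitted RSS falls well
  below the RSS at the true parameters: with a slowly decaying n = 0.5
  component the sampling error of ĝ₂ is correlated over nearly the whole
  fit window, leaving ~1–3 independent noise modes for 5 parameters, and
  the free offset C trades off against the slow tail. This is an
  identifiability property of the model family at 4 s records, not an
  optimizer artifact (multi-start and symmetric normalization leave it
  unchanged). Clamping C or extending the window reduces the bias but
  departs from the stated fitting ranges and window rule, so it is not
  done.
- F-test calibration: the stepwise chain is *conservative* — the stepwise
  false-advance rate (offset → static under offset truth) is ≈8%,
  near-nominal, but falsely reaching the mixed level requires two
  consecutive false steps and was observed 0/100 times. Power is high:
  mixed truth at d = 0.5 selects the mixed model in ≈100% of trials.
  (A non-stopping variant that tests each level against the accepted model
  was evaluated and rejected: correlated residuals inflate its null mixed
  selection to ≈48%.)
- Three-region phantom (32×32, 4 s): regime accuracy 100%, vessel-region
  τ_c within ~1%. **Limitation:** the parenchyma-like region (n = 0.5,
  ρ = 0.8) carries a +25% median τ_c bias because the single F step lacks
  power to detect a 20% static fraction at per-pixel noise for ~half the
  pixels, and ρ = 1 fits of static-contaminated curves inflate τ_c. Pixels
  that do select the static level recover τ_c well; region-level averaging
  of curves before fitting, or priors on ρ, would mitigate this but are
  outside the per-pixel contract.
- Directional LSCI error: under a true 10× n = 0.5 slowdown the
  conventional contrast ratio returns ≈0.51 against a truth of 0.1, while
  the n = 0.5 inversion returns ≈0.15 — the error drops by roughly a
  factor of 8.

Problem sizes in tests and the acceptance script (20 seeds per recovery
condition, 100/50 F-test trials, one 32×32 phantom, 8×8 contrast stacks)
were chosen to give stable medians and rates while keeping a full run in
the minutes range on a single CPU.
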