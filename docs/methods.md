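# Methods

This note records the models, defaults and design choices behind the package,
and what the synthetic validation does and does not establish.

## Physical model

Energy expenditure is inferred purely from radiative heat loss. The chain is

1. **Radiative power.** $P = \varepsilon\sigma(T^4 - T_a^4)$ with temperatures
   in kelvin, applied to the *mean* bare-skin temperature (the per-pixel
   alternative — average the per-pixel $T^4$ fluxes — is available via
   `per_pixel_power=True`; by convexity it is never smaller, and on phantom
   scenes the Jensen gap is below 1 % of $P$). Defaults:
   $\varepsilon = 0.98$ (human skin, near-blackbody in LWIR) and
   $\sigma = 5.673\times10^{-8}$ W m⁻² K⁻⁴. The σ value is the rounded
   constant this model is conventionally quoted with; it differs from the
   CODATA value by ~0.05 % and is configurable in `PhysicsConstants`.
2. **Body surface area.** $A = (4W+7)/(W+90)$ m² from weight alone — the
   standard pediatric approximation. It is strictly increasing, equals
   1 m² at $W = 83/3$ kg and is bounded by 4 m².
3. **TEE.** $P$ integrated over 86 400 s, converted at 4184 J/kcal, and
   divided by the radiative fraction 0.75 (share of total heat loss carried
   by radiation in resting ill children). All three constants live in
   `PhysicsConstants`; changing the radiative fraction rescales TEE exactly
   inversely.

Temperatures are °C everywhere in I/O and the API; the kelvin shift happens
once, inside `energetics`.

### Occlusion correction

Covered skin reads low by the flux crossing the textile:
$T_{\mathrm{skin}} = T_{\mathrm{cloth}} + \varphi R_t$. The flux φ is not
observable per pixel; the package estimates it as the Stefan–Boltzmann flux
of the *bare-skin mean* against ambient — the only observable proxy — and
applies one material $R_t$ per frame (per-pixel material maps are out of
scope). An optional fixed-point refinement re-estimates φ from the pooled
corrected mean (≤ 5 iterations, 0.01 °C tolerance) but is off by default:
on phantoms the single pass is already exact by construction, and on real
data the refinement changes the correction by far less than the uncertainty
in $R_t$ itself.

Whether corrected covered pixels should enter the mean skin temperature is a
genuinely open modeling question; both modes exist
(`include_corrected=True/False`) and bare-only is the report default. The
phantom-truth TEE is defined over *all* patient pixels, so the recovery
tests run with the corrected pixels included.

### Bare-skin partition

Temperature is the sole clustering feature. In one dimension the optimal
k-means clusters are contiguous intervals of the sorted values, so
`kmeans_1d` computes the **exact** global optimum by divide-and-conquer
dynamic programming ($O(kn\log n)$) rather than Lloyd iterations: it is
deterministic, initialization-free, and satisfies the optimality invariant
the test suite checks against an independent naive DP. Default $k=2$ (bare
vs covered — the working hypothesis is binary). A guard merges the warmest
cluster downward when it holds < 5 % of patient pixels, so a few hot-spot
artifact pixels cannot hijack the bare-skin rule. Caveat: with $k=2$ on an
*unoccluded* patient the split falls inside the radial skin gradient; the
bare-only default is then harmless, but `include_corrected` would
over-correct the cooler half — one reason it is not the default.

## Segmentation

A compact UNet-style encoder–decoder implemented directly in NumPy (im2col
convolutions + BLAS, 2×2 max-pool, nearest-neighbour upsampling with skip
concatenation, 1×1 head). Defaults: depth 3, base width 16 (≈ 16/32/64
channels), per-frame standardized temperature input, per-pixel categorical
cross-entropy with inverse-frequency class weights, Adam (lr 10⁻³–3·10⁻³),
batch 8, seeded 80/20 train/validation split, early stopping on validation
mean IoU with patience 5. Augmentation samples flips (p = 0.5 each),
rotation ±15°, scale 0.9–1.1 (one joint affine; bilinear for the frame,
nearest for the mask), additive offset ±1 °C with contrast gain 0.9–1.1
about the frame mean (the thermal analogue of brightness/contrast), and
Gaussian noise up to 0.3 °C. The foreground decision threshold is selected
post hoc by maximizing mean IoU over a 0.05-step grid, ties toward the
smaller threshold. The network consumes the temperature matrix, not a
rendered 8-bit image — a deliberate choice: the radiometric signal is the
quantity the physics needs. Gradient correctness is verified against
numerical differentiation in float64.

## The phantom generator

Phantoms emulate what a PICU thermography frame contains: an elliptical
torso + head disc at 33–38 °C with a 1–2 °C centre-to-edge radial gradient,
background at the ambient temperature (21–26 °C), an optional blanket
polygon rendered through the *forward* resistance model
$T_{\mathrm{cloth}} = T_{\mathrm{skin}} - \varphi R_t$ (with φ computed
exactly as the analysis stage estimates it, so the inversion is consistent
to machine precision on noiseless frames), a ventilation tube at 28 °C, a
monitor screen at 30 °C, and i.i.d. Gaussian sensor noise (default
0.1 °C) added last. Default blanket $R_t = 0.15$ K·m²/W (fleece-like, ≈ 1
clo). Ground truth records the pre-noise state and the true TEE.

The cohort generator ties TEE to age: ages are right-skewed on [0, 17]
(gamma, shape 0.5, scale 4.6 — infants dominate a PICU census; mean ≈ 2.3 y),
TEE targets follow `intercept + slope·age + N(0, sd)` with defaults
1800 − 40·age ± 150 kcal/m²/day clipped to [500, 2500], weights rise with
age (≈ 3.4 + 2.75·age kg ± noise, clipped to [2, 60]), and each phantom's
core temperature is solved in closed form so its true TEE equals the drawn
target. The model is a mechanism for trend-recovery testing, not a
physiological growth model: real covariance of age, weight, posture and
skin temperature is far richer.

**What passing tests show** — that the algorithmic chain is self-consistent:
exact clustering, exact occlusion inversion, correct physics arithmetic,
a trainable segmenter, and statistics that recover a planted trend at the
correct false-positive rate. **What they cannot show** — accuracy on real
patients: phantoms have no anatomy, no pose variation, no motion, no
emissivity variation, no convective/evaporative physics, and their textile
model is the same equation the analysis inverts.

## Numerical choices and degenerate inputs

- Dead pixels (NaN, < 10 % of a frame) are filled by the 3×3 median of
  finite neighbours before any physics.
- Missing ambient temperature falls back to the median of the frame's
  1-pixel border ring, flagged `ambient-fallback` in the report.
- Negative radiative power (skin cooler than ambient) is reported, flagged,
  never clipped; a negative estimated flux is clipped to zero for the
  occlusion correction (there is no outward flux to invert) and flagged.
- k-means with fewer distinct values than $k$ reduces $k$ with a warning;
  a uniform-temperature patient is therefore entirely bare skin.
- Metabolic zones: |deviation| ≤ 10 % normal, ≤ 25 % monitor, beyond
  hyper/hypo, boundaries inclusive toward the milder zone. The default
  reference table is the single 1500 kcal/m²/day pediatric benchmark for
  all ages/sexes; richer age/sex tables load from file. These zone
  thresholds are package conventions, not clinical guidance.
- All randomness flows from explicit integer seeds; training, phantoms and
  pipeline runs are bit-reproducible.

## Problem sizes in the shipped checks

Test and acceptance runs use desk-scale sizes chosen as the package's own
defaults for a laptop-class single CPU: segmentation trains on 200 phantoms
at 48×64 for ≤ 25 epochs (held-out patient-class IoU ≥ 0.85), occlusion and
recovery checks use 96×128 scenes, and cohort analyses use the native
120×160 frames with n = 116 patients. Statistical calibration uses 2000
replicates of the n = 116 null cohort.

## Known limitations

- The thermal-resistance inversion assumes a single uniform textile layer
  with known $R_t$ and purely radiative flux; multi-layer bedding,
  conduction to the mattress and airflow are not modeled.
- The 75 % radiative fraction and constant emissivity are population-level
  assumptions that break under fever, sweating or circulatory compromise.
- One material per frame; no per-pixel material identification.
- The statistical battery treats patients as independent; longitudinal
  repeated measures need the monitor mode plus an appropriate model, which
  is out of scope here.
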