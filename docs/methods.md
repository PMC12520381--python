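# Methods

This note documents the models behind `taainv`: what is being simulated,
which equations close the reduced wall model, how the synthetic study is
assembled and trained, and where the reduced physics is known to differ
from a full finite-element treatment.

## 1. Reduced equilibrated wall model (`taainv.gr_membrane`)

### State and constituents

The vessel is a thin-walled cylinder of baseline inner radius `r0 = 1`
(all lengths scale with it). The wall is a constrained mixture of

* **elastin**, areal mass `m_e`, deposited with prestretch `G_e` and not
  replaced, with membrane fiber stress
  `σ_e(λ) = c_e ((G_e λ)² − (G_e λ)⁻²)`, and
* a lumped **collagen/smooth-muscle pool** that turns over continuously and
  is therefore always found at its deposition (prestress) stress `s_h`;
  when loaded elastically by a stretch `λ'` past deposition it carries
  `σ_c(λ') = s_h λ'² exp(k_c (λ'² − 1))`.

Intramural cells sense the mean circumferential Cauchy stress
`σ = P r / h` (thin-wall Laplace) against a homeostatic set-point `σ0`.
A mechanosensing defect `δ` scales the sensed deviation,

    Δσ = ((1 − δ) σ / σ0) − 1,

so growth and remodeling (G&R) equilibrates, Δσ = 0, at the erroneous
target `σ* = σ0 / (1 − δ)`.

### Insult application

`ϑ_δ` enters as δ above. `ϑ_ce` (loss of elastic fiber integrity) both
scales the elastin stress by `1 − ϑ_ce` and reduces the effective
prestretch to `G_e (1 − ϑ_ce)`, modeling fragmentation of the prestressed
lamellae. The prestretch loss is essential: with a pure stiffness scaling
the stress of surviving elastin regrows at least like `λ²` (a factor 2.25
between λ = 1 and λ = 1.5 for any prestretch), which one can show makes a
1.5-fold dilatation unreachable for any admissible parameter set once the
homeostatic identity and `s_h > σ0` are imposed. Physically, fibers that
lose their cross-links lose their stored tension, not only their modulus.

### Per-node equilibrium closure

At mechanobiological equilibrium three statements hold per node:

1. Laplace force balance at the grown state under the G&R pressure
   `P_gr` (systole): `σ = P_gr λ r0 / h`, with `h = M/ρ` the thickness and
   `M` the total areal mass;
2. satisfied (mis)sensing: `σ = σ*`, which pins the mass
   `M(λ) = P_gr λ r0 ρ / σ*`;
3. the constitutive split of the mixture stress with collagen at its
   deposition stress:

       R(λ) = φ_e(λ) σ_e,dam(λ) + (1 − φ_e(λ)) s_h − σ* = 0,

   where `φ_e = m_e / M` is the elastin mass fraction and `σ_e,dam` the
   damaged elastin stress.

`R` is solved by 64 bisection steps on λ ∈ [0.3, 12] (wide enough for
cap-saturating combined insults probed during calibration), vectorized over
all 1681 grid nodes at once. Axial growth is not modeled (unit axial
growth stretch). At `(ϑ_ce, ϑ_δ) = (0,0)` the homeostatic identity built
into `WallParams` makes λ = 1 the exact root.

### Elastic response over the cardiac cycle

About the grown state, a fast elastic stretch λ' obeys membrane
incompressibility (`h → h/λ'`) and the balance

    P λ λ'² r0 / h = φ_e σ_e,dam(λ λ') + (1 − φ_e) σ_c,grown(λ'),

solved for λ' at diastolic and systolic pressure by the same bisection
(bracket [0.3, 3]). `σ_c,grown` is `σ_c` with the stiffening exponent
scaled by `λ^1.5` — collagen deposited in a dilated wall is less undulated
and stiffens earlier. This growth-conditioned stiffening affects only the
cardiac-cycle response, never the grown geometry; without it the purely
local closure predicts *increased* distensibility for mechanosensing-driven
lesions (the wall equilibrates thinner relative to its radius), while every
mechanism of aneurysmal stiffening known from tissue data — load transfer
to collagen, collagen accumulation — points the other way. The exponent
1.5 was fixed at model-design time: it suppresses lesion distensibility for
all mixtures and orders elastic-dominated < mixed < mechanosensing-dominated,
with minimum distensibilities around 0.024–0.039 at matched 1.5-fold
dilatation (healthy baseline 0.05442).

A circumferential 3-node moving average (circular, configurable, 0
disables) is applied to the grown λ and h fields to mimic the membrane
continuity the per-node closure lacks; it preserves rotational
equivariance and the monotonicity of dilatation in insult magnitude.

Stress diagnostics at systole: `σ_θθ = P_sys r_sys / h'`,
`σ_zz = σ_θθ/2 + A·(M0/M)` with a baseline axial prestress `A = 0.25 σ0`,
and the intramural shear analog `(σ_θθ − σ_zz)/2`.

### Homeostatic calibration

Template constants (thickness/radius 0.1 at `P_sys = 120`, hence
`σ0 = 1200` in nondimensional stress units; elastin mass fraction 0.3;
`G_e = 1.4`; elastin load share 0.55·σ0 at λ = 1; `k_c` base 4.8;
`P_dia/P_sys = 80/120`) are scaled by a single stiffness factor κ applied
jointly to `c_e` and `k_c`, with `s_h` re-derived each trial from the
homeostatic identity. κ is found by Brent's method so the zero-insult
vessel's `(r_S − r_D)/r_D` equals the target 0.05442 to 1e−5. The
procedure is deterministic and idempotent. The template was chosen once so
that (i) `s_h > σ0` (solvability), (ii) each pure insult at its cap
(`ϑ_ce = 0.48` or `ϑ_δ = 0.28`) can dilate past 1.5-fold, which bounds the
elastin load share to roughly 0.45–0.73 of σ0 at this mass fraction, and
(iii) the calibrated κ sits near 1.

## 2. Synthetic study (`taainv.grf_insults`, `taainv.maps`)

* **Severity templates.** Stationary Gaussian random field on the cylinder
  with squared-exponential covariance; circumferential distances are
  chordal (`2 sin(Δθ/2)`), keeping the covariance periodic and positive
  semi-definite (Cholesky with escalating jitter). Defaults: variance 1,
  correlation lengths 1 rad (θ) and 0.25·L (z). Each draw is mapped
  affinely to [0,1], multiplied by an axial taper `sin(π ẑ)` so the
  template vanishes at the vessel ends (dilatation is normalized by the
  end radius, so the ends must stay unperturbed), then floored at 0.3 of
  range and rescaled (`max(0, (x − t0)/(1 − t0))`), which yields a
  compact-support lesion with maximum exactly 1.
* **Contributor mixtures.** `w ∈ {0, 0.25, 0.5, 0.75, 1}` spans pure
  mechanosensing to pure elastic-fiber dominance; the scale `s` obeys the
  caps (`s·w ≤ 1`, `s(1−w) ≤ 1`) and is calibrated per record by bisection
  until `max d` is within 0.01 of 1.5 (monotonicity of `max d` in `s` is
  asserted on the evaluated sequence). The default study is 100 templates
  × 5 mixtures = 500 records; templates whose calibration fails are
  resampled with a derived replacement seed (counter-based seed derivation
  from `(base_seed, template index, attempt)` makes the whole dataset a
  pure function of the base seed and the configuration).
* **Maps.** `d` from diastolic radii (end-row normalization, first+last
  axial row), `𝒟` pointwise. Grayscale encoding clips to the dataset-wide
  ranges d ∈ [0.9, 1.8] and 𝒟 ∈ [0, 0.08] and rounds half-away-from-zero
  to 8 bits; the ranges are recorded in the HDF5 container so decoding is
  self-describing. The 450/50 split is a seeded uniform permutation.

### What the generator emulates — and what it does not

The generator reproduces the study conditions: randomly shaped lesions,
five contributor mixtures at closely matched aneurysmal size, suppressed
distensibility inside the lesion with elastic-dominated lesions stiffest,
and higher wall stress (and shear analog) in mechanosensing-dominated
lesions. It does **not** emulate: aortic curvature or patient geometry;
axial/nonlocal growth coupling (the FE models it stands in for propagate
dilatation and distensibility changes to remote sites — here effects are
local up to a 3-node smoothing); unstable growth or dissection; or
measurement noise — maps are exact to quantization. Consequences for
interpretation: with matched apex dilatation the *dilatation maps are
nearly identical across mixtures* (max |Δd| ≈ 0.01, about 3 gray levels),
so dilatation-only inversion of the mixture is close to ill-posed here,
more so than in the nonlocal FE setting. Passing tests therefore
demonstrate correct mechanics and a learnable 2-channel inverse problem,
not clinical-grade identifiability from dilatation alone.

## 3. Operator architectures and training (`taainv.operators`, `taainv.nn`)

All four models share one contract: `(N, C, 41, 41)` map batches in
(C = 1: dilatation only; C = 2: dilatation + distensibility), normalized
to [0,1] (grayscale by the fixed 0–255 range, heat maps by their
train-set min/max), and `(N, 2, 41, 41)` contributor fields out, trained
against cap-normalized targets and reported in physical units. They run on
a package-internal reverse-mode autodiff engine over float32 numpy arrays
(im2col convolutions through BLAS; gradients of every op verified against
finite differences in the test-suite).

* **DeepONets.** Branch encodes the maps (3-conv CNN + dense, SiLU — or a
  2-hidden-layer FNN); trunk encodes output coordinates. Both heads share
  one parameter set by splitting the p-dimensional embedding in half, one
  half per contributor; the prediction at a node is the scaled dot product
  of branch and trunk half-embeddings plus a per-head bias. The trunk
  lifts `{θ̂, ẑ}` through a fixed sin/cos harmonic embedding (3 harmonics
  per axis) before its MLP: raw coordinates have a periodicity seam in θ
  and a small MLP cannot resolve localized lesions from them within a
  desk-scale budget (the 5-record capacity oracle plateaus at ~0.2
  relative ℒ2 with raw coordinates, < 0.05 with the lift).
* **UNet.** Reflect-pad 41→48, encoder/decoder with per-level double
  convolutions (GroupNorm + GELU), 2× max-pool / transposed-conv sampling,
  skip concatenations, 1×1 output head, crop back to 41. Full size: base
  width 32, depth 3 (~1.9M parameters); reduced: base 8, depth 2.
* **LNO.** Lift → Laplace layers → projection, sine activations. Each
  layer applies, separably along each spatial axis, an analytic
  pole-residue transfer function `K(s) = Σ_n β_n/(s − γ_n)` with learned
  channel-mixing residues and stable learned poles (`Re γ < 0` via
  softplus): the steady-state response scales the input's truncated
  Fourier modes (imaginary input poles `iω_ℓ`) by `K(iω_ℓ)`; the transient
  response excites decaying exponentials `e^{γ_n x}` with the analytic
  coefficients `Σ_ℓ α_ℓ/(γ_n − λ_ℓ)`. The original formulation of this operator family is 1-D;
  the separable per-axis extension (plus pointwise bypass) is this
  package's design choice for 2-D maps. Full size: 4 layers, width 32,
  8 modes.
* **Training tiers.** The `full` tier records the full-scale study budgets
  (2×10⁵ updates, Adam, constant 1e−3 for DeepONets with combined MSE
  loss; cosine-annealed 1e−4 for UNet; exponentially decayed 1e−3 with
  best-on-validation selection for LNO, relative-ℒ2 loss for both). The
  `reduced` tier — used by the test-suite and the reproduction scripts —
  scales both widths and budgets to desk size (UNet: base 8, 2000 updates,
  batch 8, cosine 2e−3; DeepONets: 2000 updates; LNO: width 16, 6 modes,
  3 layers, 1500 updates with a 10% validation carve-out). These sizes
  are the package's chosen study conditions for single-CPU runs.

## 4. Evaluation (`taainv.evaluate`)

Per record and contributor, `e = ‖ϑ̂ − ϑ‖₂/‖ϑ‖₂`; the test-set headline is
the mean of per-record errors (the pooled-norm variant is computed and
stored alongside). Records whose truth field is identically zero for a
head (pure mixtures: w = 0 has no elastic-fiber insult, w = 1 no
mechanosensing insult) are excluded from that head's mean. The filtered
variant restricts the norm to nodes with `ϑ* ≥ 0.5` (the lesion core).
Error maps are stored signed (`ϑ̂ − ϑ`). The condition table reports, per
architecture and encoding, both channel settings, their error ratio and
the 2-channel ranking.

At the reduced tier the 2-channel UNet reaches ~4–6% relative ℒ2 on both
contributors; dilatation-only errors saturate near 40% for the
identifiability reason above, so the 1-/2-channel ratio is far larger than
it would be under nonlocal growth physics. The directional conclusion —
distensibility is decisive for separating contributors — is reproduced
emphatically; its magnitude is a property of the reduced model.

## 5. Numerical choices and degenerate inputs

* Bisection everywhere a root is needed on a fixed bracket (64 iterations,
  bracket-width/2⁶⁴ resolution); sign-change violations raise with node
  indices. Brent for the scalar calibration of κ (xtol 1e−12).
* Degenerate severity fields (range below 1e−12 relative) normalize to
  the zero profile; a zero profile cannot be calibrated (no insult cannot
  dilate) and raises a calibration error.
* Grayscale rounding is half-away-from-zero; decode differs from the
  clipped input by at most half a quantization step, `(hi − lo)/510`.
* Mean-of-records vs pooled aggregation both stored; mean-of-records is
  the headline (the choice matters little here; both are reported).
* Determinism: dataset generation and evaluation are bit-reproducible
  given seeds; training is deterministic on fixed BLAS (single-threaded
  numpy), with the LNO additionally snapshotting best-on-validation.

## 6. Known limitations

* The wall model is a per-node membrane closure calibrated to two scalar
  targets (baseline distensibility, aneurysmal dilatation threshold); its
  parameters are nondimensional and not fitted to tissue data.
* No remote (opposite-wall) distensibility reduction: that effect requires
  structural coupling absent from a local model.
* Dilatation-only identifiability is weaker than under FE growth physics
  (see §2); 1-channel error levels and the 1-/2-channel ratio should be
  read accordingly.
* The LNO extension to 2-D is separable by design; a genuinely 2-D
  pole-residue transform is out of scope.
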