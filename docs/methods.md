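# Methods

## Scientific problem

Watson–Crick base pairs in duplex DNA open transiently. While a pair is
open, the guanine N1–H or thymine N3–H imino proton can exchange with water;
while it is closed, it cannot. Two NMR observables probe complementary sides
of this process:

* **CLEANEX-PM** measures the water→imino magnetization-transfer build-up
  versus mixing time, yielding the water–proton exchange rate `k1H`. In the
  EX2 limit (closing much faster than the open-state intrinsic exchange),
  `k1H = Kop · kint`, so `k1H` carries the opening *equilibrium constant*.
* **On-resonance imino ¹H R1ρ relaxation dispersion** measures the decay
  rate of spin-locked magnetization as a function of spin-lock field
  strength. Microsecond two-state exchange between the closed ground state
  and a sparsely populated open state produces an exchange contribution that
  is quenched at high field, yielding the *kinetic* rate `kex = kopen +
  kclose ≈ kclose` when the open population is very small.

Because the intrinsic open-state exchange of a G:C imino proton is
base-catalysed by the partner cytosine N3, `kint ∝ 10^(pKa(N3;C) −
pKa(N1;G))`, and cytosine modification shifts pKa(N3): 4.5 (C), 4.4 (5mC),
4.0 (5hmC), with guanine N1 at 9.4. Normalizing measured `k1H` by the
resulting factors (1.3 for a 5mC partner, 3.3 for a 5hmC partner, in the
two-significant-figure convention) puts opening equilibria of differently
modified duplexes on one common arbitrary scale. The analysis is
deliberately **semi-quantitative**: the proportionality constant in `kint`
is unknown, so the package reports only relative quantities — normalized
`k1H` (relative Kop), `kex` (≈ kclose), and their product as a relative
opening-rate index — never absolute `kopen`/`kclose`.

## Models fitted

**CLEANEX-PM build-up.** `I(τ)/I0 = k1H/(RA + k1H − RB) · [exp(−RB·τ) −
exp(−(RA + k1H)·τ)]`, where `RA` and `RB` are apparent imino and water
relaxation rates. This is the exact solution of the two-pool system in which
water is a large labeled reservoir decaying at `RB` feeding the imino pool
at `k1H`; back-transfer is neglected because the imino pool is vastly
smaller. The expression has a removable singularity at `RA + k1H = RB`; the
implementation evaluates it through `expm1`, which is exact in the limit, and
the suite checks continuity across the crossing. Parameters `{k1H, RA, RB}`
are fitted per site by weighted least squares (inverse-variance weights from
per-point errors), with bounds `k1H ∈ [0, 100]`, `RA ∈ [0.1, 200]`,
`RB ∈ [0.01, 5]` s⁻¹ and starts `k1H` from the initial slope, `RA` from the
inverse peak position, `RB = 0.5` s⁻¹. A site is reported *not detected*
(k1H = NaN, flag set) when the fitted peak amplitude is below 2× the median
ratio error — a baseline-noise detection limit, mirroring sites whose
exchange signal never rises out of the noise.

**R1ρ dispersion.** Effective rates come from the two-point relation
`R1ρ = −(1/T)·ln(I_SL/I0)` with errors propagated to first order from the
spectral baseline noise, `σ(R1ρ) = (1/T)·sqrt((σ/I_SL)² + (σ/I0)²)`.
Profiles are fitted to the two-state on-resonance expression

    R1ρ = R2⁰ + pA·pB·Δω²·kex / D
    D   = ωAe²ωBe²/ωe² + kex² − pA·pB·Δω²·(1 + 2kex²(pA·ωAe² + pB·ωBe²)
                                              /(ωAe²ωBe² + ωe²·kex²))
    ωAe² = ω1²,  ωBe² = Δω² + ω1²,  ωe² = ΩA² + ω1²,
    ΩA  = −pB·kex²·Δω/(kex² + Δω²)

with `ω1 = 2π·ν1`. The ΩA auxiliary is implemented exactly in this form even
though some published population-averaged offsets differ; the propagator
comparison below bounds the consequences (≤ 0.7% in the study regime), so
fidelity to the printed expression costs nothing measurable. In fast
exchange (`kex ≫ Δω`) only `Φex = pA·pB·Δω²` is identifiable, so the default
parameterization is `{R2⁰, kex, Φex}` with `pb` fixed (default 0.001,
config-overridable; the open population of a stable base pair is far too
small to separate) and `Δω` derived as `sqrt(Φex/((1−pb)·pb))`. A `full`
mode freeing `pb` and `Δω` exists but is degenerate in this regime and
flagged as such in its docstring. Fits start from `R2⁰ ≈ R1ρ` at the
strongest field, `kex ≈ 2π·ν1` at half-dispersion, `Φex ≈ Rex·kex`, with
`kex ∈ [10², 10⁷] s⁻¹`. A flat model (`R2⁰` only, the inverse-variance
weighted mean) is compared by corrected AIC; when flat wins the site is
reported `no_rex` with no exchange parameters.

Note the identifiability caveat that follows from the parameterization: the
assumed `pb` re-enters the model through the derived `Δω²  = Φex/(pA·pb)` in
the denominator, so the recovered `kex` is only insensitive to the `pb`
assumption when `Φex ≪ pb·kex²`. The suite asserts the <1% insensitivity
property in that regime; outside it, users fitting deep dispersions at
moderate `kex/Δω` should treat `kex` as conditional on the assumed `pb`.

**Uncertainties.** Default errors come from Monte-Carlo residual resampling
(200 seeded draws, refitting synthetic curves built from the best-fit model
plus Gaussian noise at the per-point errors); covariance-matrix errors are
available via `mc_draws=0` and are used in the large recovery studies for
speed — for these well-conditioned fits the two procedures agree closely
(asserted in the suite), and a 500-replicate calibration check confirms that
nominal 68% intervals cover truth at a binomially consistent rate.

**Melting curves.** Tm is the temperature of the maximum of dA/dT after
Savitzky–Golay smoothing (window 7, order 2 by default; both configurable
since no standard is universal), refined by quadratic vertex interpolation
through the three points around the discrete maximum so Tm is not quantized
to the 1 °C sampling. Uncertainty by residual bootstrap. Tm is invariant
under affine transforms of the absorbance, and noise-free recovery bias on
two-state sigmoids is below 0.1 °C (tested).

**Helical parameters.** Per-frame 3DNA-style tables (long format: frame,
position, parameter, value) are reduced to per-(position, parameter) means
and sample (n−1) SDs over raw frames — no block averaging — with an optional
difference table against a reference duplex. Missing cells are dropped,
never imputed.

## Numerical oracles

The synthetic module doubles as the independent check on every closed form:

* the CLEANEX build-up equation is validated against direct `DOP853`
  integration of the two-pool ODE (rtol 1e-12), agreeing to better than
  1e-8 relative everywhere tested including the degenerate point;
* the dispersion expression is validated against a 6-dimensional two-state
  Bloch–McConnell propagator (matrix exponential over the relaxation period,
  spin-lock along +x, ground state on resonance, equilibrium-populated
  starting magnetization, rate extracted by the same two-point log formula
  as the experiment so simulated and fitted quantities share one
  definition). An eigenvalue-based extraction is provided as a cross-check.
  Over the grid kex 5×10³–10⁵ s⁻¹, pb 10⁻⁴–10⁻², Δω/2π 0.1–3 kHz, R2⁰
  10–60 s⁻¹, the two agree within 2% (measured worst case ≈ 0.7%).
  Longitudinal relaxation defaults to R1 = 1.5 s⁻¹ for both states; with an
  on-resonance lock the extracted rate is insensitive to this choice
  (verified by ±50% variation).

**Cross-relaxation estimate.** ¹H–¹H cross-relaxation with nearby protons
could in principle contaminate imino R1ρ. The package estimates this with a
two-spin Solomon-type *reconstruction*: one passive neighbor spin under the
same lock at its own offset, coupled to the observed spin's transverse
components by a rotating-frame cross-relaxation rate σ, appended to the
Bloch–McConnell system. The reported quantity is the maximum relative R1ρ
perturbation over the spin-lock grid; at a typical σ = 1 s⁻¹ it is ≈ 3%,
below the documented 5% negligibility threshold. This is a reconstruction
built for order-of-magnitude screening, not an exact treatment of any
specific dipolar network.

## Synthetic study design

The generator emulates a six-duplex CpG-modification study — C/C, 5mC/C,
5mC/5mC, C/5mC, 5hmC/C, 5hmC/5mC; guanine imino sites at positions 6–9 with
the modified CpG at positions 7/8 — under the default acquisition: mixing
times {5, 10, 15, 20, 50, 100, 200} ms; twelve log-spaced spin-lock fields
0.5–15 kHz; relaxation period 20 ms. The duplex sequence itself is a config
annotation, not hard-coded, since only the site list enters the analysis.

Ground truths (chosen once, at the orders of magnitude the measurements
motivate): baseline `k1H` 0.3–1.2 s⁻¹ across positions; `RA = 25`,
`RB = 0.5` s⁻¹; `kex` 1.5×10⁴ s⁻¹ (unmodified) to 3.5×10⁴ s⁻¹ (modified —
modification speeds closing); `R2⁰` 31–34 s⁻¹; open population `pb = 0.001`,
matching the analysis default so the fast-exchange parameterization is
self-consistent; `Δω/2π = 2.8 kHz`. Additive Gaussian noise: sd 0.002 on
intensity ratios and baseline noise 0.005·I0 on spin-lock intensities
(≈ 0.5 s⁻¹ on R1ρ) — baseline-noise-limited, homoscedastic by default.
Three deliberate features mirror the qualitative structure of real data:
the hemi-methylated duplex carries a 4-fold opening-equilibrium increase at
the CpG guanines (3× at G6, 2× at G9); G6 of the unmodified duplex has no
exchange broadening (its profile is flat and must be flagged `no_rex`); and
guanines paired with 5hmC have `k1H` below the detection limit (their
build-up must be flagged not detected). All noise descends from one seed
via `SeedSequence.spawn`, so studies are byte-reproducible and means are
seed-independent.

What the generator does **not** emulate — and hence what passing recovery
tests cannot show about real data: peak overlap and deconvolution errors,
temperature or field drift, heteroscedastic or correlated noise (a
heteroscedastic option exists but is off by default), cross-relaxation
contamination (screened separately, not injected), three-state exchange,
and any systematic error in the two-state model itself.

## Recovery study sizes

The acceptance-level recovery study runs 100 noisy replicates of the full
six-duplex design (24 build-up + 24 dispersion fits each) with
covariance-matrix errors, checking per-site medians of `k1H` and `kex`
against truth within 10% and the built-in 4-fold Kop contrast within twice
its propagated uncertainty; smaller per-module Monte-Carlo checks use
50–500 replicates. These sizes make median estimates stable to a few
percent while keeping the default suite quick to run.

## Degenerate inputs and tie-breaks

* `cleanex_model` at `τ = 0` or `k1H = 0` returns exactly 0; the
  `RA + k1H = RB` crossing is continuous by construction.
* `dispersion_model` returns `R2⁰` exactly at `pb = 0` or `Δω = 0`;
  parameter sets driving the printed denominator non-positive raise a
  domain error naming the parameters rather than returning nonsense.
* The build-up maximum for `k1H = 0` is `(nan, 0)`; at the degenerate rate
  crossing the limit `τpeak = 1/RB` is used.
* Tm extraction raises a no-transition error for edge or constant-derivative
  maxima instead of reporting an edge temperature.
* Undetected CLEANEX sites and no-Rex dispersion sites propagate through
  normalization and combination as NaN fields with flags set — partial
  summaries are results, not errors.

## Known limitations

* Only on-resonance R1ρ is modeled; no off-resonance tilted-field geometry.
* Two-state exchange only; no three-site or WC↔Hoogsteen structural
  assignment of the excited state.
* Thymine sites pass through normalization unchanged (the pKa scheme is
  specific to cytosine-catalysed GC exchange); comparisons across AT sites
  assume equal `kint`.
* The `rounded_2sf` normalization convention reproduces the conventional
  printed factors exactly (1.3, 3.3) but inherits their rounding; the
  `full_precision` convention (10^0.1 ≈ 1.2589, 10^0.5 ≈ 3.1623) is
  recommended for new data. The two agree within 6%.
* Absolute opening/closing rates are out of reach by design; every reported
  rate is relative to the unmodified reference.
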