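# Methods

## The measurement and its model

A porous-chip peptide microarray reports, per spot, a fluorescence intensity
proportional to the amount of phosphorylated peptide, sampled at the imaged
pump cycles.  The progress curve of each spot is modelled as exponential
association,

    y(c) = y0 + ymax (1 − e^(−k c)),

with `c` the pump-cycle index, `ymax` the saturation plateau and `k` the
per-cycle rate constant.  The quantity carried forward is the initial
velocity

    v = ymax · k · e^(−k c*) · 2   [signal units / min],

the tangent of the fitted curve at the velocity-evaluation cycle `c*`,
converted from per-cycle to per-minute units (the pump runs 2 cycles/min).
`c*` defaults to cycle 4 — the second image of an every-second-cycle
acquisition, i.e. 2 minutes — and is configurable.  The signal 20 minutes
into the run (`s20`) is kept as a quality-control covariate and is the
statistic used by the substrate-calling stage.

### Fitting

The least-squares fit runs internally in the parametrisation
`(y0, m, k)` with `m = ymax·k` the initial per-cycle slope.  For weak
substrates the curve is nearly linear over the 30-minute window and `ymax`
and `k` are only jointly identified (their ridge is the linear limit
`y ≈ y0 + m c`), while `m` — the quantity `v` is built from — remains well
conditioned; fitting in `(y0, ymax, k)` directly stalls on that ridge.
Starting values come from a quadratic fit (`m` from the linear term, `k =
−2q/m` from the curvature `q`), bounds are `k ∈ (0, 10]`, `m ≥ 0`, `y0`
free, and standard errors come from the fit covariance (delta method for
`ymax = m/k`).  Fits that fail or return a non-positive `k` fall back to a
linear slope over the first five images, flagged `fallback`, so poor
substrates stay in the screen rather than disappearing.

## Synthetic assays

The generator inverts the analysis model so that every downstream stage has
a known answer.  The true initial velocity of a spot is

    v = E · (Vmax/Km)_pep · [S] · [ATP]/(Km_ATP + [ATP]) · u,

first order in enzyme amount `E` (pmol) and spotted peptide `[S]` (µM),
Michaelis-saturating in ATP with the construct's `Km_ATP`, and zero for all
negative controls, the kinase-dead construct, and peptides absent from the
efficiency map.  `u` is a signal-units scale (default 1).  An optional
peptide-level Michaelis constant replaces `[S]` by `[S]/(1 + [S]/Km_pep)`
for exercising the linear-range selector; by default the model is purely
first order in `[S]` (the Vmax/Km regime the efficiency analysis assumes).

Each spot's curve then follows the association model with plateau
proportional to the spotted amount (`ymax = 50 · [S]` signal units by
default — the plateau represents full conversion of the immobilised
peptide, far above the initial-phase signal).  The rate constant is chosen
so that the *pipeline's* velocity definition recovers `v` exactly: `k`
solves `2 ymax k e^(−k c*) = v` (Lambert-W; the `second_point` convention).
The closed form `k = v/(2 ymax)`, which instead matches the tangent at
cycle zero, is available as `initial_tangent`; the two differ by the factor
`e^(−k c*)`, which only matters for strongly curved spots.  Spots too fast
for the inversion (`v c*/(2 ymax) ≥ 1/e`), or reaching >99.9% of plateau
within two cycles, are flagged `saturated`.

Noise is additive plus proportional Gaussian on signals and a Gaussian
local background (reported background = the background actually added to
the signal, so background subtraction is exact in expectation).  The
defaults (σ_add = 5, σ_prop = 0.05, background 50 ± 10) produce technical-
replicate CVs in the 5–10% range suggested by the standard errors of the
published efficiency table; no noise model is published, so these are
labelled assumptions.  Per-run random streams derive from the master seed
by CRC-hashing the run key (construct, control, enzyme, ATP, replicate), so
replicates are independent and datasets reproduce bit for bit.

Assay geometry follows the published protocol: 60 cycles at 2 cycles/min
imaged every second cycle (30 images / 30 min); screening arrays with 144
peptides at 1000 µM (the 63 published substrates plus deterministic
tyrosine-centred decoys and the tyrosine-free / pre-phosphorylated antibody
controls); a 24-peptide custom chip with the
{100, 300, 400, 600, 750, 1000} µM series; enzyme titrations spanning 0 to
2× each construct's working amount (2 / 0.4 / 0.04 / 1.2 pmol for WT /
V617F / JH1 / JAK3-JH1 — the published 0–8 pmol range scaled per construct
so strong substrates stay out of plateau saturation inside the titration);
ATP from 0 to 400 µM.

What the generator does **not** emulate: antibody-binding kinetics (the
real assay is tuned so rates reflect enzymatic conversion), spatial array
artifacts, drift/bleaching, and replicate-to-replicate variance structure
beyond i.i.d. Gaussian noise.  Passing tests therefore demonstrate
correctness of the estimators under the stated forward model, not
robustness to every failure mode of real chips.

## Substrate calling

A peptide is called for a construct when all four hold at the 20-minute
image: (i) background-subtracted signal above `2 × SD(background)` at the
top titration condition; (ii) replicate-mean signal strictly increasing
across the enzyme titration with the top level exceeding the bottom by more
than the same threshold; (iii) likewise across the ATP titration; and (iv)
no above-threshold signal in any negative control.  The published criterion
is qualitative ("signals must increase with enzyme and ATP"); strict
monotonicity of replicate means plus a top-vs-bottom margin is this
package's operationalisation.  The background SD is pooled from the local
background channel and the tyrosine-free control spots, each centred on its
own mean; the comparison uses background-subtracted signal (an assumption —
the original estimator is unnamed).  Strict monotonicity over six ATP
levels is noise-fragile near ATP saturation (adjacent levels differ by only
a few percent), so perfect-recall demonstrations use a low-noise setting
(σ_add = 1, σ_prop = 0.01); under default noise, occasional single-peptide
misses at the top ATP steps are expected and are a property of the rule,
not of the implementation.

## Normalisation and the absolute scale

Rates are expressed as a percentage of the same construct's rate on the
reference spot (1000 µM STA5A_687_699) and per pmol of enzyme.  This
transform is invariant to any rescaling of the raw fluorescence units —
which also means the *absolute* relative-activity scale of the published
efficiency table is not identifiable from a ratio alone: it is fixed by a
calibration constant per construct.  `normalize_activity` therefore accepts
`reference_value` (default 100, the percent convention) either as a scalar
or per construct; the simulator's sidecar supplies the per-construct
constants (`eff_ref · 1000 µM · pmol`) that place recovered efficiencies on
the same scale as the packaged table, and zero-noise round trips then
reproduce every tabulated `Vmax/Km` to machine precision.  On real data the
constant would come from the instrument calibration; it scales columns
uniformly and cancels from the percent-of-total transform entirely.

## Kinetic estimation

* `Km(ATP)` and apparent `Vmax`: nonlinear least squares of
  `v = Vmax [ATP]/(Km + [ATP])` over ≥4 ATP levels (replicates averaged
  first), SEs from the covariance; a fitted `Km` beyond 4× the largest
  [ATP] is flagged `extrapolated` rather than trusted.
* `Vmax/Km` per peptide: ordinary least squares with a free intercept over
  the replicate-mean rates at the spotted concentrations, at 400 µM ATP.
  The free intercept matches the scattered sub-unity R² values of the
  published table; regression through the origin is available behind a
  flag.  By default all six levels enter (the published analysis appears to
  use them all); optional truncation repeatedly drops the top concentration
  while doing so raises R² by more than 0.05, guarding against saturation
  curvature.  A negative slope marks a non-substrate.  When the data
  saturate weakly (`Km_pep` finite), the OLS slope underestimates
  `Vmax/Km` by ≈ `2·mean([S])/Km_pep`; it converges to the true ratio as
  `Km_pep` grows.

## Comparison transforms and rounding

Fold change divides each construct's efficiency by the reference
construct's (reference ≡ 1); percent-of-total divides by the construct's
column sum (columns sum to exactly 100 before rounding).  Reporting columns
round half-up, which reproduces the published integers for cells that
recompute consistently from the printed efficiencies; the remaining printed
integers appear to derive from pre-rounding values and are not silently
"corrected" — raw values are always carried alongside.

## Motifs

Peptides align on the anchor tyrosine — the Tyr closest to the sequence
midpoint, ties broken toward the N-terminus (the published alignment does
not define the rule for multi-Tyr peptides; this is our choice) — over
positions −5..+5.  Per-position weighted residue frequencies use
percent-of-total `Vmax/Km` as weights, renormalised over non-gap weight at
each position; stack heights are the relative entropy against a uniform
1/20 background (a residue-frequency background is available),

    h(p) = log2 20 + Σ_r f_p(r) log2 f_p(r)  ∈ [0, log2 20 ≈ 4.32 bits].

The anchor column is always pure tyrosine and reaches the maximum height.
Motif pairs are compared by per-position Jensen–Shannon divergence (bits,
bounded by 1); on the packaged table the WT–V617F divergence is an order of
magnitude below WT–JAK3, the quantitative counterpart of the observation
that the V617F mutation raises activity without reshaping substrate
preference while a different kinase domain does.

## Problem sizes and determinism

The shipped demonstrations use the study's own dimensions: 144-spot screens
(three constructs, five enzyme levels, six ATP levels, triplicates, six
negative controls), the 24 × 6 custom chip in triplicate for four
constructs (1 728 spot fits), and seven-level ATP titrations in triplicate.
All randomness flows from a single master seed; simulated datasets, the
pipeline bundle, and the acceptance script are bit-reproducible given the
seed.

## Known limitations

* The screen's decoy peptides are synthetic; the identities of the 81
  non-substrate peptides on the real screening array are not public.
* Absolute relative-activity units require an external calibration (above);
  only ratios and percentages are identifiable from the data alone.
* The motif stage reproduces the stated weighting and entropy definitions;
  the original figures were produced by an external web tool whose gap and
  normalisation internals are unspecified, so rendered stack heights cannot
  be numerically adjudicated against the published figure.
* No correction for drift, bleaching, spatial artifacts, or antibody
  kinetics; no multiple-testing layer on substrate calls (the original
  analysis used a fixed threshold rule, reproduced as such).
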