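# Methods

## Model

`frapmc` models the mobility of a GFP-tagged nuclear protein as a
three-state continuous-time process observed through a strip-FRAP
experiment:

* **Free** molecules diffuse with coefficient `D` (µm²/s) inside an
  ellipsoidal nucleus with reflecting envelope.
* Two **bound** classes are immobile; class *i* holds an equilibrium
  fraction `f_i` of the pool and releases with rate `1/T_i`, where `T_i`
  (s) is the mean residence time (`T1 ≤ T2` by convention: class 1 is
  the short-lived, class 2 the long-lived interaction). Binding is
  position-independent — binding sites are assumed uniformly
  distributed, and the free fraction `f0 = 1 − f1 − f2` must be
  positive.

Time is discretized into substeps `dt` (default 1 ms, 21 per scan).
Per substep a free molecule takes an isotropic Gaussian step with
per-axis variance `2·D·dt` and binds to class *i* with probability
`p_on,i = (f_i/f0)·dt/T_i`; a bound molecule releases with probability
`p_off,i = dt/T_i`. This first-order closure has stationary occupancies
`(f0, f1, f2)` and mean bound dwells `T_i`; it requires
`dt ≤ min(T_i)/10`, which is enforced.

Steps that would exit the nucleus are reflected specularly at the exact
boundary crossing (about the local surface normal, iterated up to ten
times; a still-outside step is rejected). Specular reflection preserves
the uniform equilibrium density, which the no-bleach stationarity test
checks directly.

## Acquisition and bleaching

The simulated protocol mirrors the strip-FRAP assay: 1000 scans of
21 ms; after 100 scans a bleach pulse of three iterations; the ROI is a
strip 0.8 µm wide (10 pixels × 80 nm) through the nucleus centre,
spanning the other two axes. The readout is the count of fluorescent
particles inside the strip (unit detection efficiency inside, zero
outside — absolute efficiency cancels in normalization). Simulated
curves are normalized to the mean pre-bleach level; experimental-style
raw traces are background-subtracted and divided by the mean of the 50
scans immediately before the bleach.

The beam profile is a flat-top strip with Gaussian lateral shoulders:
relative intensity 1 inside the strip and `exp(−d²/2σ²)` at distance
`d` outside the edge, uniform along the strip and in depth. A
fluorophore at intensity `I` survives one bleach iteration with
probability `exp(−dose·I)`. Each iteration is a scanner pass occupying
one scan interval, with diffusion and exchange continuing in between,
so mobile molecules exchange into the beam and the effective bleached
pool exceeds the strip content. Bleached molecules keep diffusing and
binding; they only stop contributing signal.

**Calibration of the optical parameters.** The per-iteration peak dose
is 1.2 (cumulative ~97% destruction of molecules resident at the strip
centre across three iterations — a deep bleach). The shoulder width
defaults to `σ = 0.15 µm` (about two pixels). This value was fixed
against the free-GFP control: wider shoulders (e.g. 0.5 µm) bleach a
quarter to a third of the entire nuclear pool, which is inconsistent
with the observation that free GFP recovers to near pre-bleach levels;
0.15 µm keeps the collaterally bleached pool small while preserving the
deep in-strip bleach. Both parameters are configurable, and
`calibrate_dose` tunes the dose to any requested bleach depth.

## Nucleus geometry

Nuclear dimensions enter only through the ratio of strip to nucleus
volume (bleached-pool fraction) and the diffusion path length. Default
semi-axes are 6 × 4 × 2.5 µm, a typical cultured-fibroblast nucleus;
they are configurable and treated as a nuisance parameter, with
cell-to-cell size jitter in the synthetic-data generator.

## Simulation engines

`simulate_frap` has two engines producing statistically identical
curves. The `reference` engine composes the public single-step
operations (`step_diffusion`, `step_kinetics`, `apply_bleach`,
`measure_roi`) in Python, with per-substep Bernoulli transitions. The
`fast` engine (default) is a compiled kernel that samples the identical
event process via geometric dwell-time countdowns (the number of
substeps to the next transition), consumes pre-drawn bulk Gaussian
increments, and uses a multiply-only inclusion fast path with exact
specular reflection on the rare boundary crossings. Equivalence of the
two engines is asserted statistically in the test suite. All randomness
descends from one root seed via `numpy.random.SeedSequence` spawning
(one child per replicate, plus an explicit kernel seed), so identical
(seed, configuration) pairs give bit-identical curves.

## Grid fitting

Inference follows the brute-force recipe: enumerate a grid over
(D, f1, T1, f2, T2) within D ∈ [0.04, 25] µm²/s, f1 + f2 ≤ 0.9,
T ∈ [0.1, 300] s; simulate one reference curve per node under a common
configuration; pick the node minimizing the sum of squared residuals
over all post-bleach scans (the bleach-depth scan included, pre-bleach
scans excluded since both sides are 1 there by construction). Exact
ties break toward smaller total bound fraction, then smaller D. No
interpolation or gradient refinement is applied; an optional ranked
list of runners-up is reported. Unweighted OLS is used; scans are not
noise-weighted.

Label switching between the bound classes is eliminated by the
canonical ordering `T1 ≤ T2`; a single bound class is always encoded in
class 2, and grid nodes with `f_i = 0` collapse the then-meaningless
`T_i` axis to one placeholder value.

**Library noise suppression.** A library curve simulated with a finite
ensemble is a noisy estimate of the node's smooth model curve, and with
thousands of nodes the arg-min over raw Monte Carlo curves is dominated
by the library's own sampling error rather than by curve shape — the
between-family curve differences this fit must resolve are only 1–3% of
the signal. Four measures, all applied to the library only (the
measured curve is never altered), bring the library error well below
that:

1. *Expectation over bleach survival* (Rao–Blackwellization): the fast
   engine carries continuous fluorescence weights
   `w ← w·exp(−dose·I)` instead of Bernoulli bleaching. The mean curve
   is identical; the variance contributed by survival randomness of the
   few strip-resident molecules vanishes.
2. *Deterministic normalization*: library curves are divided by the
   analytic equilibrium ROI occupancy `N·p_slab` rather than the
   realized pre-bleach mean, removing a per-node coherent scale error
   of a few percent caused by slowly-relaxing pre-bleach occupancy
   fluctuations. (Simulated curves outside the library keep the
   pre-bleach normalization, matching the experimental procedure.)
3. *Temporal spline projection*: each curve is replaced by its
   least-squares cubic spline with 24 interior knots log-spaced in
   post-bleach time — full resolution across the fast early recovery,
   heavy averaging on the plateau — suppressing the white counting
   noise by roughly the scan-to-knot ratio. Disable with
   `smooth_knots=0`.
4. *Pooling across the fraction grid*: ROI occupancy fluctuates with a
   correlation time of seconds (set by transport and residence times),
   so each node retains a slowly-varying error component (~4% at 1000
   particles) that no temporal filter can remove. Within a family of
   nodes sharing (D, T1, T2) this error is independent across nodes
   while the true curve varies smoothly with (f1, f2); each scan's
   values are therefore regressed onto a degree-4 bivariate polynomial
   in the fractions over the ~190-node simplex (~12× variance
   reduction; boundary nodes average over the families they border).
   Disable with `f_smooth_degree=0`.

**Desk-scale library.** The default reduced grid keeps the full
5-percentage-point fraction resolution (the quantities of interest) and
structures the nuisance axes around identifiability. The two bound
classes are distinguishable only when their timescales separate, so the
short class offers residence times log-spaced over the sub-second to
seconds regime ({0.1, 0.55, 3} s) and the long class log-spaced from
there to the 300 s range limit ({3, 9.5, 30, 95, 300} s); a grid in
which both classes ranged over the full span would spend most of its
nodes on within-window-degenerate duplicates. D is pinned to the two
regimes the constructs occupy, 3 µm²/s (large fusion protein) and
20 µm²/s (free GFP): intermediate D values act as near-exact aliases of
fast-exchange binding (the `D_eff ≈ D·f0/(f0+f1)` degeneracy) and would
let the fitter trade the short-bound fraction against a slower
diffusion coefficient that no construct in the study has. The full
default grid (8 log-spaced D, 7 log-spaced T for both classes) remains
available for general use. Nodes are simulated with 1000 particles at a
7 ms substep (three per scan); the recovery plateau was measured to be
insensitive to the substep between 1 and 21 ms at these diffusion
coefficients. Library builds are resumable and cached to HDF5; per-node
seeds derive from the root seed and node index so a build is
reproducible node-by-node.

## Synthetic experiments

The generator emulates the study's acquisitions per cell: nucleus
semi-axes jittered by 10% (s.d., relative), particle count drawn
log-normally with 20% log-s.d. around 10000, the FRAP protocol simulated,
then counts converted to detector units as
`gain · Poisson(counts) + background + N(0, sd)`, with background 5%
and detector noise 2% of the pre-bleach signal. Per-cell curves are
normalized individually (expression levels differ) and averaged —
default 10 cells per experiment — before fitting. Ground truth and all
derived seeds are recorded in the manifest, and identical manifests
reproduce byte-identical files.

Construct presets carry the reported best-fit kinetics (free GFP; MN1
10%/11 s, +ATRA 10%/30 s; TEL 57%/0.63 s + 20%/59 s, +α-amanitin
released; MN1-TEL 20%/4 s + 60%/120 s, +α-amanitin 10%/235 s; the
non-DNA-binding DBD mutant free). The diffusion coefficient of the free
pool was never reported; presets assume 3 µm²/s for the large fusion
proteins and 20 µm²/s for free GFP, and this assumption is flagged
wherever presets are used.

What the generator does **not** emulate: aggregation at high expression,
nucleolar exclusion, monitor bleaching (available as an option, off by
default, since normalization is applied but no monitor-bleach model was
described), anomalous diffusion, spatially structured binding sites, or
vendor file formats. Passing recovery tests on these synthetics
therefore demonstrates the estimator's self-consistency under the
declared noise model, not robustness to every artefact of real
confocal data.

## Identifiability

With a ~19 s post-bleach window, residence times at or beyond the
window (59, 120, 235 s) are indistinguishable from permanent
immobilization: only "bound at least as long as the window" is
supported. `fraction_summary` and `score_recovery` flag such times as
non-identifiable instead of scoring them. Short-lived binding
(≲ 0.1 s) is near-degenerate with slowed effective diffusion
(`D_eff ≈ D·f0/(f0+f1)`), which is why the short-bound fraction is
recovered with coarser tolerance than the long-bound fraction.

## Numerical choices and degenerate inputs

* Substep validity: `dt ≤ min(T_i)/10` over classes with `f_i > 0`, and
  `p_on1 + p_on2 < 1`; violations raise `CoarseTimestepError`.
* Bleach-depth floor: a trace whose pre-bleach mean does not exceed the
  background raises `DegenerateCurveError`.
* Reflection: exact specular bounce, up to 10 iterations, then step
  rejection; the inward nudge of 1e−12 keeps boundary points strictly
  interior.
* Fits with mismatched time axes or empty windows are errors, never
  silently aligned.
* The bleach scan index is always declared, never inferred from the
  trace.

## Problem sizes

Default desk-scale sizes: 4772-node reduced library at 1000 particles
per node; synthetic experiments of 10 cells × 10000 particles; plateau
simulations at 1e5 particles with the full 1 ms substep. These sizes
were chosen so the complete analysis runs on a single CPU core at
around the Monte Carlo error the tolerances assume.
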