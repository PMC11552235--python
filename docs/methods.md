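# Methods

`sandplume` models how chemical cues leak out of prey buried in sand and
when a chemosensory predator probing the sand surface can detect them, and
implements the signal-processing pipeline that defines the sensory
threshold the physical prediction is compared against.  This note records
the model, the numerical choices, and the design decisions that were
genuinely open.

## Diffusion model

Inside water-logged sand, bulk flow is suppressed and transport of a
dissolved chemostimulant is diffusive with free-water diffusivity
`D = kT / (6 pi eta r)` (Stokes–Einstein; `k` is the Boltzmann constant at
its CODATA value).  For sub-nanometre molecules at room temperature this
gives `D ~ 1e-10 .. 1e-9 m^2/s`; amino-acid-like solutes sit near the top
of that range, and `D = 1e-9 m^2/s` is the package default.  The
characteristic distance travelled in time `t` is `sqrt(D t)` — about 1 mm
over a 30-minute trial at `D = 5e-10 m^2/s` — which is why only a thin
surface skin of sand ever carries signal from a buried source.

An instantaneous release of `dM` moles at `(xs, ys, zs)` produces

    dc = dM / (4 pi D t)^{3/2} * exp(-r^2 / (4 D t)),

the free-space heat kernel.  The sand/water interface sits at `z = 0`
(`z > 0` is sand, increasing downward).  Two bounding treatments of the
water column are implemented:

* **free interface** — perfectly still water: the interface is ignored;
* **Dirichlet** — fast flow dilutes everything instantly: `c = 0` is
  enforced at `z = 0` by subtracting a mirror source at `(xs, ys, -zs)`
  (method of images).

Reality lies between the two; both are carried through every downstream
stage and the Dirichlet field is everywhere bounded by the free one in the
sand half-space.

## Buried capsule

The source is a gel capsule shaped as a prolate ellipsoid with full axes
16 mm x 6.3 mm x 6.3 mm, lying flat (long axis horizontal) with its centre
at burial depth `depth_l`, releasing `M = c0 * V` moles uniformly over its
volume at `t = 0`.  Design decisions here:

* The stated axis dimensions are read as FULL axis lengths.  The resulting
  geometric volume (~0.33 mL) differs from the nominal capsule volume of
  1 mL; the configured `V` is authoritative for the released moles, so the
  uniform source density is `M / V_geom`.  When `V` is derived from the
  axes (`PhysicalParams.from_axes()`), density and `c0` coincide and the
  `t -> 0` limit at the capsule centre recovers `c0` exactly.
* The burial depth used for the published detectability statement is not
  printed; the default is `depth_l = 5 mm` (the shallowest round depth at
  which the 3.15 mm minor semi-axis keeps the capsule fully buried), and
  every sweep exposes it as a free parameter.
* The capsule centre anchors the depth coordinate.

### Quadrature

`c(x, y, z, t)` is the volume integral of the kernel over the ellipsoid,
computed with a Gauss–Legendre product rule in scaled ellipsoidal
coordinates: slices along the long axis, polar coordinates in each circular
cross-section (trapezoid in angle, which is spectrally accurate for
periodic integrands).  The order scales with the ratio of capsule size to
kernel width `sqrt(4 D t)` (about 4.5 nodes per kernel width, capped at
192 x 96 x 96), and convergence is verified against a 1.4x-refined rule on
a probe subset including the field maximum; failure escalates the order and
ultimately raises `QuadratureError` with diagnostics.  The convergence
criterion is `rtol = 1e-3` relative, with an absolute floor of 1e-4 of the
subset's peak value: many kernel widths into the Gaussian tail the field is
physically negligible and pointwise relative accuracy there is not a
meaningful target.

When `sqrt(4 D t)` falls below what the capped rule can resolve (very early
times), the field is evaluated instead as a Gaussian-smeared capsule
indicator using a 20-point Gauss–Hermite rule per axis: exact in the deep
interior (`-> c0`) and exterior (`-> 0`), percent-level inside the thin
transition shell.  At `t = 0` the initial condition is returned directly
(interior density inside, zero outside, half on the boundary).

### Surface statistic and detectability

A leg touching the sand is assumed to sample the topmost `layer_depth =
0.5 mm` of sand.  The surface statistic is the vertical *average* over that
layer (6-point Gauss–Legendre; a `max` option exists) and the horizontal
*maximum*, which by symmetry sits above the capsule centre.  The capsule is
detectable once this statistic exceeds the sensory threshold `c_star`;
the default is the permissive end of the 10–100 uM range, `c_star = 10 uM`.
Onset times are found by a log-spaced coarse scan over `(0, t_max]`
followed by bisection to 1 s.  The onset search runs the quadrature at a
lighter profile (`rtol = 5e-3`, ~3 nodes per kernel width) because
bracketing a threshold crossing needs percent-level, not 0.1%, accuracy.
The coarse scan (default 40 points) would miss a crossing briefer than its
spacing; with these parameters the surface concentration varies smoothly on
the scan's timescale.

With the defaults (`c0 = 100 mM`, `V = 1 mL`, `D = 1e-9`, depth 5 mm), the
surface layer is sub-threshold for the first minute or so (the *initial
transient*), crosses 10 uM on the order of a minute or two, and the onset
time decreases monotonically with `c0` — the model's explanation for why
concentrated capsules are found more efficiently.  The two boundary
scenarios give onset times well within a factor of two of each other here,
which is why the free-interface scenario is the reporting default.

## Brownian-walk oracle

An independent check on the quadrature: `n` particles start uniform in the
ellipsoid carrying `c0 V / n` moles each and take Gaussian steps of
per-axis variance `2 D dt`.  Under Dirichlet, particles found at `z < 0`
after a step are killed.  Discrete-step killing (rather than exact
first-passage) biases the absorbing boundary by ~`0.58 sqrt(2 D dt)`
(~0.03 mm at `dt = 1 s`), negligible against the 0.5 mm sampling layer;
tests that compare absorbed mass against the analytic half-space survival
`erf(zs / sqrt(4 D t))` use `dt = 10 ms` to push this bias below counting
noise.  Box concentration estimates carry binomial standard errors, and
quadrature-vs-walk agreement is asserted at 3 SE in 20 boxes for both
scenarios.

## Nerve-response quantification

Multi-unit suction-electrode recordings are quantified by rectifying the
signal, low-pass filtering with a Gaussian, subtracting the pre-stimulus
baseline, clipping at zero, and integrating over the response window.
Numerical conventions:

* The "25 Hz Gaussian low-pass" is parameterised by its -3 dB point:
  `sigma_t = sqrt(ln 2) / (2 pi * 25 Hz) ~= 5.30 ms`.  The filter has unity
  DC gain and a monotone frequency response; both are tested.
* The baseline is the mean envelope over a `pre_window` (default 10 s,
  at least 5 s required) before stimulus onset.
* The response window runs from onset to offset plus a `tail` of 30 s,
  chosen to capture slow sustained kinetics; blanks are integrated over the
  same window length.
* The clipped excess is integrated by the trapezoid rule (V·s).
* Peak, time-to-peak and decay fraction (excess at window end over peak)
  describe kinetics on second timescales, so they are read off the excess
  envelope after an extra 1 s Gaussian smoothing (on a ~100 Hz decimated
  copy); without it, individual spike bumps of a sparse multi-unit train
  masquerade as peaks.

Kinetics classes: `none` if the peak fails a 3x-baseline-SD noise floor;
`fast_transient` if the peak arrives within `tau_fast = 10 s` AND the
envelope decays to <= 0.3 of peak by window end; `slow_sustained`
otherwise.  The band between decay fractions 0.3 and 0.6 with an early peak
is deliberately classed slow — a response that has not largely decayed is
not transient.

Detection thresholds from a dose–response series use the lowest tested dose
whose mean response area exceeds `mean(blanks) + 3 SD(blanks)` — a
deterministic, scale-free rule chosen over a t-test because the published
design has only 4 replicate legs per dose.  The same integration serves
area-under-curve quantification of luminescence assays; no assay-specific
model is included.

Heatmaps of multi-compound screens normalise each leg to its own maximal
area before averaging across legs (legends reporting "relative responses"
imply per-leg, not global, normalisation; an all-zero leg is excluded with
a warning).

## Synthetic data

The generators produce data with the statistical structure the analysis
assumes, so every stage is testable without recordings.  What they emulate
and what they do not:

* **Traces** are spike-based: Gaussian instrument noise (20 uV RMS) plus an
  inhomogeneous-Poisson multi-unit train of biphasic 2 ms waveforms
  (amplitude `snr` x noise RMS, default 5, with 30% amplitude jitter), so
  the rectify/filter path is genuinely exercised.  The evoked rate is
  `100 Hz x gain(dose) x envelope(t)` on a 2 Hz spontaneous floor.  The
  dose gain is a Hill function of coefficient 4 half-activated at the
  species' threshold for the compound, times a mild `1 + 0.1 log10(1 +
  dose/K)` supra-threshold creep so response areas keep growing past
  saturation (as multi-unit recruitment does); without the creep the top
  doses are statistically exchangeable and rank-based monotonicity checks
  are meaningless.  Kinetics envelopes: fast transient
  `(1 - e^{-t/1s}) e^{-t/3s}`, slow sustained rise `1 - e^{-t/8s}` holding
  through the 20 s stimulus and decaying with a 100 s tail.  Real
  recordings have bursting units, electrode drift, and stimulus artefacts;
  none are modelled, so passing tests show the pipeline's correctness on
  its stated signal model, not robustness to every recording pathology.
* Each trace stores its own deterministic ground truth: the expected
  quantified area given the drawn spike times, via the folded-normal mean
  `E|s + n|` filtered by the same Gaussian, including the half-rectification
  bias `E max(X, 0)` of the envelope's residual noise (variance reduced by
  the filter's `sum g^2`).  The quantifier recovers it to a few percent.
* **Species profiles** place the L-amino-acid detection threshold at
  100 uM (digging) vs 10 mM (non-digging), betaine at 100 uM for both, and
  map tastants to fast, TRP agonists to slow kinetics.  The default
  dose–response design is 4 replicate legs over 7 log-spaced doses from
  10 uM to 10 mM — half-decade steps whose grid contains both species
  thresholds, so the estimator can land exactly on them and their ratio is
  100-fold.  The blank pool is larger than the per-dose replication
  (8 zero-dose traces): the detection rule keys entirely on SD(blanks),
  and a 4-sample SD is unstable enough to let blank-level dose means slip
  over the criterion in a few percent of series; blanks are cheap and an
  enlarged control pool is standard practice.
* **Behavioural trials** are Bernoulli: success probability
  `encounter_prob` (default 0.8, a free parameter — per-trial encounter
  statistics are not derivable from the data the model uses) when the
  condition's model result is detectable, else `false_rate` (default 0:
  control capsules are never excavated).  Summaries report per-condition
  rates with exact Clopper–Pearson 95% intervals.

All generators are bit-reproducible given a seed (NumPy `default_rng`;
dose–response designs spawn child seeds via `SeedSequence`).

## Problem sizes

The shipped tests and the acceptance script run at desk scale chosen for a
single CPU: mass-conservation audits on Simpson grids of ~1e4 probes,
oracle comparisons with 1e5 particles at `dt = 1 s` to `t = 60 s`,
dose–response pipelines of 32 traces per species at 10 kHz (2 kHz in unit
tests), and 200-trace kinetics-recovery experiments at 2 kHz.  These sizes
leave estimator noise far below every asserted tolerance.

## Known limitations

* No advection, sand tortuosity/porosity, or adsorption to grains: the
  model uses free-water diffusivity throughout, bracketing reality only
  via the two interface scenarios.
* Biological sources (live mussels) have unknown emission rates and are
  not modelled; only the controlled capsule is.
* The spike generator does not emulate spike-sorting difficulty, unit
  identities, or mechanical/thermal confounds.
* The onset search reports the earliest crossing at 1 s resolution of a
  40-point log scan; pathological parameter sets with sub-scan-width
  detectability windows would need a denser scan.
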