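# Methods

## The compartment model

The population is modelled as six well-mixed compartments: G0/G1, S and
G2/M cells, each either unlabelled (G, S, M) or carrying the thymidine
analogue (G′, S′, M′).  Transitions are first-order: `a_G` (per hour)
moves G0/G1 cells into S, `a_S` moves S cells into G2/M, and `a_M` takes
G2/M cells through division, each mitosis returning two daughters to
G0/G1.  Exit from the population (death, differentiation, export) is
first-order with rates `d_G`, `d_S`, `d_M`.  Label dynamics use two
parameters: `β`, the labelling rate of S-phase cells while label is
bioavailable, and `α`, the proportion of labelled mitoses whose daughters
shed the label.  Division of a labelled G2/M cell routes `2α` daughters to
unlabelled G0/G1 and `2(1−α)` to labelled G0/G1.

Working units are percent of the initial population (so compartments sum
to 100 at t = 0) and hours; rates are reported per day (×24) only at the
presentation boundary.

### Constraints used for fitting

The gated endpoint provides two independent numbers (three percentages
summing to 100), so the fit constrains the model to two free parameters:

* labelling neutrality: primed rates equal unprimed ones;
* instant labelling: β = ∞, represented as a sentinel "instant" mode, not
  a large finite rate — a finite-β mode is retained for generality;
* no shedding during the experiment: α = 0;
* steady state: constant total and phase occupancy.  Summing the equations
  shows this forces `d_G = a_G` once `d_S = d_M = 0` (divisions add
  exactly one cell per transit, which must be removed in G0/G1);
* no exit during S or G2/M: `d_S = d_M = 0`;
* a fixed S-phase duration of 6.5 h: `a_S = 1/6.5` per hour — a measured
  value for the lymphocyte populations this design targets, and the reason
  the remaining two parameters are identifiable at all.

Under these constraints the steady-state occupancy is closed-form and the
proliferation rate — the division flux `p = a_M M + a_M′ M′` — reduces to
`p = 200 a_M a_G / (2 a_M + 13 a_M a_G + 2 a_G)` %/h.  Both identities
are verified to 1e-10 relative in the test suite.  The inter-mitotic time
is reported as `100/p` with p in %/day, applied uniformly to every
population.  DNA content cannot separate G0 from G1 nor G2 from M, so the
reported G0/G1 and G2/M durations are occupancy-weighted averages; the
model makes no attempt to split them.

## Protocols

An injection keeps label bioavailable for `availability_h` hours
(default 1), modelled as a square window; overlapping windows merge and
everything truncates at sacrifice.  The default design — injections at 0,
1 and 16 h, sacrifice at 16.5 h — yields a 2-h pulse, 14-h chase and
30-min terminal pulse.  Windows use the half-open `[start, end)`
convention: instant-labelling transfers fire at pulse starts, and a
boundary instant belongs to the later window.

## Integration

Each window is a linear time-invariant system; the integrator is
classical fixed-step RK4 at dt = 0.01 h, with the per-window step
adjusted (n = round(length/dt)) so window boundaries land exactly on the
grid.  Instant labelling is a discrete event at each pulse start — all
unlabelled S cells move to S′ — plus rerouting of the `a_G G` influx into
S′ for the duration of the pulse.  This is exactly the infinite-β limit
and avoids integrating a stiff term.  A forward-Euler scheme is provided
as an independent cross-check; tests require RK4 at dt = 0.01 h to agree
with Euler at dt = 1e-4 h within 1e-4 per compartment, with an exact
matrix-exponential solution to 1e-9 on the objective, and step-halving to
move endpoint summaries by < 1e-5.  Compartments within −1e-9 of zero are
clipped; anything lower raises an error rather than being hidden.

## Fitting

The estimator minimises the Euclidean distance between the observed and
simulated triplets (all three components, as the redundancy is harmless
and matches how the readout is defined).  The search is a 60×60
log-spaced grid on (a_G, a_M) ∈ [1e-4, 1] per hour — grid endpoint
triplets are computed once per protocol by a vectorised batch integrator
numerically identical to the scalar path — followed by Nelder–Mead in
log-parameter space from the best node (xatol 1e-8 on log-rates, on the
squared distance).  Grid ties resolve to the lexicographically smallest
(a_G, a_M), biasing toward slower kinetics.  Noiseless round-trips
recover both parameters within 0.1% and leave distances below 1e-6, far
under the 0.05 percentage-point quality bound used to flag poor fits
(fits are flagged, never rejected).  Targets whose components miss 100 by
more than 0.5 are renormalised with a logged warning.  A sample with no
labelled cells pins a_G at the box floor (an upper bound) and sets a
boundary flag instead of failing.

### Confidence intervals

Viewing the gated triplet as one multinomial draw of `n_events` cells,
the weighted objective `Q(θ) = n Σᵢ (obsᵢ − μᵢ(θ))² / μᵢ(θ̂)` (proportion
scale, weights fixed at the optimum) is asymptotically the correct
quadratic form, because for residual vectors summing to zero
`n·diag(1/p)` is the generalised inverse of the multinomial covariance.
The parameter covariance is the inverse of the central-difference Hessian
of `Q/2` at the optimum (relative step 1e-3; at a zero-residual optimum
this equals the Gauss–Newton form exactly); 95% intervals are Wald, and
the interval for p uses the delta method with the analytic gradient of
the closed-form rate.  A non-positive-definite Hessian marks the sample
non-identifiable and widens the parameter intervals to the search box.
The construction is validated by simulation: over 200 multinomial
replicates at 10,000 events the 95% interval for p covers the truth
within the 88–99% band (observed ≈ 97%).

## Synthetic data generator

The generator emulates the study conditions the analysis assumes:

* **Designs**: strain × age × organ × population groups with true
  (a_G, a_M) signatures.  Preset rates span the reported range — ~32 %/day
  (young B6 whole thymus) to ~9 %/day (old FVB thymus), ~3 %/day rising
  to ~13 %/day in spleen with age, 45 %/day for mature CD8 thymocytes,
  down to ~0.4 %/day for naïve CD8 splenocytes — with G2/M durations from
  2 h to 63 h; 4 mice per group and 50,000 events per sample by default.
* **Counting noise**: a single multinomial draw over the triplet at the
  sample's event count.
* **Event level**: DNA content on a linear scale (1 ≈ 2N, 2 ≈ 4N) with
  Gaussian 5% CV around the G0/G1 and G2/M centres (a typical DNA-dye CV;
  draws saturate at the acquisition window edges), S-phase cells uniform
  between 1 and 2; EdU intensity as two log-normal modes (log₁₀ centres
  1.0 and 2.5, SD 0.2) with the gate threshold at the log-space midpoint.
  Live counts follow the simulated six-compartment proportions exactly
  (largest-remainder rounding), so all event-level noise is measurement
  noise.  Apoptotic events (sub-G0/G1, DNA 0.30–0.65) and engulfed events
  (>4N, DNA 4.3–5.5) are appended at per-design fractions (defaults 2%
  and 1%, matching the few-percent instantaneous death observed in
  thymus).  Dead cells never enter the kinetic fit; the EdU⁺/dead ratio
  is reported as an expansion performance index.
* **Gating**: G0/G1 at DNA 0.8–1.2, G2/M at 1.8–2.2, apoptotic < 0.7,
  engulfed > 4, DNA in (2.2, 4] discarded as aggregates (the synthetic
  stand-in for doublet exclusion); labelled = EdU above threshold
  regardless of DNA.  Unlabelled mid-DNA events stay in the live
  denominator but outside the triplet, as they would in a manual gate.
* **Reproducibility**: per-mouse generators derive from
  `default_rng([master_seed, group_index, mouse_index])`.

What the generator does **not** emulate: antibody-marker fluorescence and
spillover (populations are labels, not gated from markers), instrument
drift, pipetting/mouse-to-mouse variability beyond counting noise, real
manual-gate ambiguity, or death/differentiation fluxes coupling
populations.  Passing the end-to-end tests therefore shows the estimator
is correct under the model's own assumptions and realistic counting
noise — not that the biological assumptions hold for any given dataset.

## Calibration regression

Across populations, the fitted rate is nearly proportional to the
endpoint %EdU⁺ (the experiment is shorter than one cell cycle, so the
labelled fraction tracks the S-entry flux).  `rate_vs_edu_regression`
fits OLS of the rate in fraction/day on %EdU⁺ (0–100): those are the only
units consistent with the reference slope of 0.0119 (e.g. 38% EdU⁺ ↔
≈ 0.45/day).  On simulated sweeps spanning the presets' range the slope
reproduces within a few percent with r² > 0.99; the exact value depends
mildly on the mix of G2/M durations in the sweep, which is why the
acceptance check carries a generous tolerance.

## Problem sizes and numerical choices

The acceptance script fits a 10×10 noiseless grid (distance bound) and a
44-sample sweep (regression), a few minutes on one core; the coverage
study uses 200 replicates at 10,000 events.  Grid-cache reuse makes a
single fit ≈ 1 s.  Group-comparison hypothesis testing is intentionally
out of scope — summaries expose means and SDs per group for downstream
statistics.

## Known limitations

* Parameters are population averages; heterogeneous mixtures (e.g. whole
  thymus) are dominated by their most numerous subpopulation.
* Death, differentiation and migration are a single exit rate confined to
  G0/G1; dead cells are counted but not modelled dynamically.
* The 6.5-h S phase is an external constant; populations with different
  S-phase durations would bias both estimated rates.
* The calibration line is protocol-specific (16.5-h pulse-chase-pulse)
  and should be re-derived for any other schedule.
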