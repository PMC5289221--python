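# Methods

## The model

A single-copy DNA cassette in each cell is driven by two serine integrases,
intA and intB, induced by two chemical inputs a and b. The cassette has four
configurations:

* `S_o` — original state;
* `S_a` — after intA inverts its target region (`S_o -> S_a`, propensity α2);
* `S_b` — after intB excises the cassette from `S_o` (`S_o -> S_b`,
  propensity α1, a dead end);
* `S_ab` — after intB acts on `S_a` (`S_a -> S_ab`, propensity α3, the
  "a then b" record).

Serine integrases recombine attB/attP sites into attL/attR products they can
no longer act on, so `S_b` and `S_ab` are absorbing and there are no reverse
transitions. Each cell is a continuous-time Markov chain over
`(DNA state, IntA count, IntB count)`:

* production: IntA is born at `kprodA * u_a(t) + kleakA`, IntB at
  `kprodB * u_b(t) + kleakB`, where `u_*(t)` are the 0/1 induction
  indicators and leak is additive basal expression;
* degradation/dilution: each monomer dies at first-order rate `kdeg`
  (shared by both integrases);
* DNA flips: recombination requires a tetramer at the synapse with no
  binding cooperativity, giving the saturating propensity

      alpha(n) = kflip * n(n-1)(n-2)(n-3) /
                 (Kd^4 + Kd^3 n + Kd^2 n(n-1) + Kd n(n-1)(n-2) + n(n-1)(n-2)(n-3))

  which is exactly zero for n < 4, increasing, and bounded by `kflip`.
  α2 uses `(IntA, kflipA)`; α3 uses `(IntB, kflipB)`; the excision α1 uses
  `(IntB, kflipB_exc)`, which defaults to `kflipB` but can be set lower to
  model the empirically slower excision (the α1 < α2 = α3 variant).

Flips do not consume integrase monomers — all enzymatic detail is lumped in
`kflip`. Copy-number rates are molecules per hour in a fixed unit cell
volume (1 µm³), so counts are dimensionless integers. There is no explicit
cell division or lineage structure: dilution is folded into `kdeg`, and
growth differences between states are handled only as a reweighting in the
synthetic-data layer.

Two parameter presets are built in:

| preset    | kprodA/B | kdeg | kflipA | kflipB | kleakA | kleakB | KdA/B |
|-----------|----------|------|--------|--------|--------|--------|-------|
| `initial` | 50 h⁻¹   | 0.3  | 0.4    | 0.4    | 0      | 0      | 10    |
| `revised` | 50 h⁻¹   | 0.3  | 0.2    | 0.3    | 0.5 (1%) | 1.0 (2%) | 10 |

Induction schedules are piecewise-constant on/off intervals per channel.
`step_pair(dt)` turns a on at t=0 and b on at t=dt (both stay on);
`pulse_b(dt, pw_b)` keeps a on throughout and pulses b during
`[dt, dt+pw_b)`. The inducer separation time ∆t and the pulse width PW_b
are the two event parameters the package ultimately infers.

## Simulation

Sample paths are generated with the Gillespie direct method. Because the
induction profiles are piecewise constant, propensities are constant between
profile breakpoints; a sampled waiting time that overshoots the next
breakpoint is discarded and the clock resamples from the breakpoint, which
is exact by memorylessness. All trajectories start from `(S_o, 0, 0)`.

Two samplers share the reaction system: a plain-Python single-cell sampler
that records every event (the readable reference implementation), and a
numba-compiled population kernel that records per-cell DNA-flip events
(at most two per cell), final states, and integrase counts on an optional
time grid. Per-cell seeds are derived from the ensemble seed via
`numpy.random.SeedSequence`, so runs are reproducible bit for bit. A
10⁷-events-per-cell guard aborts runaway simulations.

Default horizons: step events run to 30 h (the end-point measurement time
for step experiments); pulse events run to `dt + pw_b + 24 h` (24 h of
outgrowth after the pulse). Both are overridable.

## Oracles

Three independent routes validate the SSA:

* **Truncated master equation.** The CME is integrated on
  `{S_o,S_a,S_b,S_ab} x {0..capA} x {0..capB}`, with births at the caps
  redirected into an absorbing overflow bucket whose probability is reported
  as the truncation mass defect (default warning threshold 10⁻³). The
  piecewise-constant generator is propagated with Krylov matrix exponentials
  (`expm_multiply`) segment by segment, so no ODE tolerance needs tuning.
  Oracle comparisons run in a reduced-production regime (kprod = 5 h⁻¹,
  caps = 40, mean copy number ~17) where truncation is tight and the SSA is
  cheap at n = 10⁴ — a validation regime, not a reproduction of the
  headline figures. Agreement is asserted per state within three binomial
  standard errors at single comparison times; a maximum over a dense grid
  of correlated time points exceeds 3 SE by chance (measured max |z| ≈ 3.5
  with no bias at n = 10⁵), so the CLI `validate` command uses 4 SE on the
  full grid and 3 SE at the end point.
* **Frozen-propensity closed form.** With constant α1, α2, α3 the DNA chain
  solves in closed form (two exponentials, with the degenerate case
  α1+α2 = α3 handled analytically as `a2 * t * exp(-a3 t)`). The CME with
  production and degradation zeroed and counts clamped at their initial
  values must reproduce it exactly; it does to 10⁻⁸.
* **Marginal-ODE self-consistency.** At the population level the DNA-state
  probabilities obey a linear ODE whose flip rates are conditional
  expectations of the propensities given the DNA state, e.g.
  `E_t[α2(IntA) | S_o]`. These are estimated from the ensemble's recorded
  counts, the ODE integrated forward, and the per-state maximum discrepancy
  compared against a tolerance of three Monte-Carlo standard errors. The
  error model combines the binomial error of the empirical fractions with
  the hazard-estimation noise accumulated through the integration
  (`∫ [(se_α1 + se_α2) P(S_o) + se_α3 P(S_a)] dt`); the binomial term alone
  understates the residual scale. A deliberately inconsistent ensemble
  (count time series reversed) fails the check by an order of magnitude.

One symmetry note: with fully symmetric parameters and simultaneous
induction, the correct exchange invariant is that the *branch totals* agree
at every time, `P(S_a) + P(S_ab) = P(S_b)` — not `P(S_ab) = P(S_b)`, which
holds only in the t → ∞ limit because `S_ab` requires two flips. The CME
verifies the branch identity to machine precision.

## Population analyses

`state_fractions` counts cells per DNA state over a grid (a cell's state at
t is its state after the last event ≤ t). `scan_dt` simulates step pairs in
either order over a ∆t grid and reports end-point fractions; each condition
runs to `dt + 24 h` so every population gets 24 h of joint induction.
"Final" fractions are fixed-time end points, not steady-state detections,
matching how end points are measured. `scan_matrix` does the same over a
(∆t, PW_b) pulse design — 11x11, 0–6 h in 0.5-h steps by default; 7x7 in
1-h steps for the experiment-scale design.

`dt90` reports the detection limit: the smallest ∆t at which the final
S_ab fraction reaches 90% of the population (absolute mode) or 90% of the
curve's own maximum (relative mode, the form used for measured data with a
switching ceiling). Crossings between grid points are linearly
interpolated; an absolute threshold never reached returns an infinite
sentinel, while the relative threshold is always reached at the argmax.

## Calibration (grid fit)

`grid_fit` reproduces the model-refinement procedure: leak rates pinned to
measured values (kleakA = 1% of kprodA, kleakB = 2% of kprodB), kflipA and
kflipB varied over 0.1–0.6 h⁻¹ (6x6 grid, 500 trajectories per candidate
condition by default), and the mean squared error computed between the
candidate's end-point S_ab curves (both inducer orders, mean over both
curves' points) and the observed curves. Ties break toward the smallest
kflipA, then kflipB, and are logged. `normalize_fractions` implements the
70%-maximum rescaling applied to measured fractions before fitting
(switched fractions divided by 0.70, clipped at 1, normalization recorded
on the table). Because no wet-lab data ship with the package, the
calibration is exercised as parameter recovery on synthetic curves
generated by the model itself; recovery of (0.2, 0.3) is clean with a
roughly tenfold MSE margin at the default sizes.

## Event inference

Given a calibration design, two inversion functions are fitted:

* **PW_b(R).** The a-first branch total depends only on the pulse width, so
  the RFP fraction R (S_a cells) is pooled over ∆t per PW_b. The pooled
  means must be monotone non-increasing within a tolerance (default
  isotonic adjustment ≤ 0.05, else the fit aborts advising more cells);
  after isotonic projection a monotone piecewise-cubic (PCHIP) interpolant
  maps R back to PW_b. The experimentally observed ∆t-dependent "slant" of
  R is a property of slower excision and is modeled, when wanted, through
  `kflipB_exc`, not absorbed into this fit.
* **∆t(G, PW_b).** A least-squares polynomial surface (quadratic by
  default, degree configurable) in the GFP fraction G and the pulse width,
  trained only on conditions with PW_b > 0. All PW_b = 0 conditions are
  physically identical — inducer b is never added — so their nominal ∆t
  labels carry no information; training on them drags the surface toward
  mid-range ∆t at the no-pulse anchor, where the correct behavior is to
  return a small ∆t at baseline (G, R). For the same reason, resolution
  summaries for ∆t are computed over pulsed conditions only.

`estimate_event(R, G)` first inverts R into a pulse-width estimate, then
evaluates the surface at (G, PW_b_hat). Both outputs are clamped to the
calibration design range (0–6 h) and flagged when clamping occurred;
extrapolation is refused rather than returned. `build_lookup` tabulates the
estimator over an (R, G) mesh for use as a reference table, and
`resolution_analysis` groups estimates by their true values, reporting
mean, sample standard deviation (ddof = 1) and count per group. On the
default synthetic 7x7 calibration the recovery SD is ~0.1 h at PW_b = 1 h,
grows with pulse width as the R curve saturates, and stays below 0.5 h for
∆t of 1–2 h.

## Synthetic data

The synthetic-data layer emulates what a wet lab would hand the analysis:

* **Sampling.** Observed state counts are drawn multinomially at
  `n_sampled_cells` (default 10⁶, the order measured per population on a
  cytometer); `None` gives the infinite-sample limit.
* **Replicate variability.** One log-normal factor per biological
  replicate, mean 1 with CV 10% by default, multiplies all three flipping
  rates (day-scale recombination efficiency). The CV is an assumption — no
  replicate noise model is measured — and is the dominant noise source in
  the default calibration (per-condition G standard deviation ~0.03,
  versus ~0.015 of pure Monte-Carlo error at 500 cells).
* **Growth bias.** Real populations cap below full switching because
  non-fluorescent states (S_o, S_b) grow slightly faster. This is emulated
  as a deterministic exponential reweighting of final fractions over the
  run duration (`w_s ∝ f_s exp(g_s T)`, renormalized), leaving the
  single-cell chain untouched. It reproduces the ~60% apparent ceiling
  qualitatively; it does not model lineage structure, division noise, or
  time-varying growth.
* **Cytometry events.** Per event a hidden state is drawn from the row's
  fractions and (RFP, GFP) intensities from per-state log-normals (defaults:
  10x separation between on/off channel means, CV 0.3, thresholds at the
  geometric midpoint — declared defaults, not measured values). S_ab events
  retain RFP with probability 0.03 by default, emulating the < 3%
  double-positive transition population from slow reporter dilution.
  `gate_quadrants` classifies events into Q1 (GFP only), Q2 (both), Q3
  (RFP only), Q4 (neither) and returns G = Q1+Q2, R = Q3.

What passing tests on these data do and do not show: they demonstrate that
the analysis pipeline is correct and well-calibrated *under the stated
noise model* (multinomial sampling + shared replicate factor + optional
growth reweighting). They do not certify performance against real
measurement artifacts — autofluorescence drift, gating misclassification
correlated with growth phase, day effects beyond a scalar efficiency — and
wet-lab resolution will differ to the extent those dominate.

## Numerical choices and edge cases

* SSA event guard 10⁷ events/cell; exceeded guards raise with the offending
  cell index.
* CME grid default: 121 points over the horizon; caps ≥ ~3x the stationary
  mean copy number keep the mass defect below 10⁻³.
* `dt90` requires ≥ 2 curve points; ties in the interpolation ordinate fall
  back to the right grid point.
* PCHIP knots: pooled R values tied after isotonic projection are collapsed
  (mean PW_b) so the interpolation abscissa is strictly increasing; a
  single surviving knot aborts the fit as degenerate.
* Grid-fit simulation failures mark the candidate pair invalid (infinite
  MSE) rather than dropping it silently.
* `estimate_event` validates R, G ∈ [0, 1]; the CLI flags out-of-range
  sample rows and continues.
* Floating-point determinism: identical inputs and seeds reproduce outputs
  bit for bit on a given platform; across platforms, libm differences may
  flip individual trajectories.

## Problem sizes

Default analysis sizes are chosen so every documented run completes on one
CPU core in minutes: ensembles of 3,000–5,000 cells for headline fractions
(binomial SE ≤ 0.9% at 50%), 500 cells per candidate condition in the 6x6
grid fit, and a 7x7 x 3-replicate calibration at 500 cells per condition
for the inversion stage. The test suite uses smaller ensembles with
Monte-Carlo margins stated inline (typically 3 SE).

## Known limitations

* No cell division, lineage correlation, or resource competition; growth
  bias is a population-level reweighting only.
* No mechanistic dimer/tetramer intermediates, attB/attP site-level
  modeling, or reversible recombination with RDF cofactors.
* The inversion surface refuses extrapolation outside the 0–6 h design box;
  events outside it are reported clamped, not estimated.
* ∆t is unidentifiable without a b pulse; estimates for PW_b = 0 samples
  are reported but carry no timing information (see Event inference).
* Inducer levels are binary (present/absent); graded induction would need a
  dose-dependent production model.
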