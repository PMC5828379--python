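# Methods

## Gating model

NaV1.7 is modeled with three independent first-order gates: activation
`m`, fast inactivation `h`, and slow inactivation `s`. Their steady-state
voltage dependences are

    m_inf(V) = 1 / (1 + exp((V½ₐ − V) / kₐ))
    h_inf(V) = 1 / (1 + exp((V − V½f) / kf))
    s_inf(V) = R_in + (1 − R_in) / (1 + exp((V − V½s) / ks))

and the membrane current is `I = g_max · m · h · s · (V − E_rev)` (nS · mV
= pA; inward negative). All gate exponents are 1 by design: the analysis
surface fits single Boltzmann curves to conductance–voltage and
availability data, so the model's equilibria must themselves be single
Boltzmanns for the pipeline to round-trip exactly. This is a deliberate
consistency choice, not a claim about microscopic gating; an m³h scheme
would make the fitted V½ a protocol-dependent effective parameter.

Gates relax exponentially: `dx/dt = (x_inf(V) − x) / τ_x(V)`.

* `τ_m = 0.1 ms`, voltage independent. Activation is much faster than
  inactivation on these protocols, so peak currents are near-maximal;
  only the ratio τ_m/τ_h matters for the small peak-attenuation effects
  the fits must absorb.
* `τ_h(V)` is anchored at two measured points — the recovery time constant
  at −100 mV (`tau_h_hyper`) and the macroscopic decay time constant at
  −25 mV (`tau_h_depol`) — and interpolated **log-linearly in V** between
  them, clamped to the anchor values outside [−100, −25] mV and floored at
  0.05 ms. The true voltage dependence between the anchors is not
  reported; log-linear is the one-parameter-free monotone rule that is
  exact at both measured points. Time constants in the clamped regions
  only set how fast the gates saturate, which the protocols are designed
  to make irrelevant (500-ms prepulses are ≥10 τ_h everywhere).
* `τ_s = 5000 ms`, voltage independent. This makes the 30-s conditioning
  prepulses of the slow-inactivation protocol ≥6 τ (equilibrated to
  <0.3%), while the 500-ms fast-inactivation prepulses move the slow gate
  by <10% of its gap — the residual drift is an affine distortion of the
  availability curve that the amplitude-bearing fits absorb without
  biasing V½ or k.

`R_in` (the resistant fraction, the lower asymptote of the slow curve) is
not published for any group; 0.2 is used for all three groups and is
configurable. `E_rev` defaults to the Nernst potential of the recording
solutions (140 mM Na⁺ out / 10 mM in, 21 °C): +66.9 mV. `g_max` defaults
to 100 nS per cell; every reported quantity is normalized, so g_max only
sets current scale.

Packaged parameter sets (from the published group means):

| group  | act V½/k     | fast V½/k   | slow V½/k    | τ_h −25/−100 ms |
|--------|--------------|-------------|--------------|------------------|
| WT     | −29.9 / 5.7  | −86.6 / 5.6 | −61.1 / 13.7 | 1.7 / 102.3      |
| M1852T | −27.6 / 6.3  | −72.5 / 9.1 | −67.5 / 12.9 | 3.4 / 106.3      |
| T1596I | −26.6 / 5.5  | −71.2 / 7.6 | −60.9 / 11.7 | 2.9 / 28.7       |

## Protocols and simulation

The five protocols share holding −100 mV, 10-s intersweep interval,
20-kHz sampling, 5-kHz filtering, and P/5 leak subtraction after the test
pulse:

* **step I-V** — 50-ms steps, −80…+40 mV in 5-mV increments (25 sweeps);
* **fast inactivation** — 500-ms prepulses, then 20 ms at −10 mV. The
  prepulse ladder (−130…−10 mV in 10-mV steps) is not published; it is
  chosen to bracket every group's V½ by ≥4 slope factors per side;
* **slow inactivation** — 30-s prepulses (−110…+10 mV by 10), then 500 ms
  at −120 mV to remove fast inactivation (duration chosen so h recovers
  ≥98% while the slow gate drifts <10% of its gap), then 20 ms at −10 mV;
* **recovery** — two 20-ms −10 mV pulses separated by an interpulse at
  −100 mV whose duration runs over a 12-point logarithmic ladder,
  1…3000 ms (snapped to the sampling grid);
* **ramp** — 0.2 mV/ms from −100 to 0 mV (500 ms, one sweep).

The 10-s intersweep interval exceeds every time constant (2 τ_s), so each
sweep starts from gate equilibrium at holding. Constant-voltage segments
are then solved **exactly** (`x(t) = x_inf + (x0 − x_inf)·e^(−t/τ)`);
ramps use exponential-Euler substeps at the 50-µs sampling interval with
the command voltage taken at the substep midpoint. Segment boundaries are
half-open: the sample on a boundary belongs to the later segment.

`navclamp.reference` provides an independent fixed-step RK4 integrator
(1-µs step, numba-compiled, sharing no integration code with the analytic
stepper). The test suite requires agreement within 0.1% of the per-protocol
peak current on all five protocols and all three groups; the slow protocol
is cross-checked on three of its thirteen sweeps (its 30-s sweeps cost
~4 s each at 1-µs resolution, and the per-sweep computation is identical).
Observed discrepancies are ≤0.008% (ramp) and ≈0 (steps, where the
analytic path is exact).

## Fitting pipeline

Peaks are the largest-magnitude extremum in the test segment after a
0.2-ms settle margin. The I-V relationship is fitted with the combined
Boltzmann–ohmic form `I = g_max(V − E_rev)/(1 + exp((V½ − V)/k))`;
conductance is `G = I/(V − E_rev)` (points within 1 mV of E_rev excluded;
negative conductances clipped to 0 and flagged, never dropped), normalized
to its maximum. Availability curves normalize test-pulse peaks to the
maximum across sweeps — the standard I/Imax convention — and the
normalized Boltzmann fits therefore carry a free amplitude so that
normalizing to a data point (rather than an asymptote) cannot bias V½ or
k. The slow-inactivation fit estimates R_in jointly.

Decay kinetics: single exponential with offset, fitted from 0.5 ms after
the peak (skipping the activation rise) to the segment end. Recovery:
R(Δt) = pulse2 peak / pulse1 peak, clipped to [0, 1.05], fitted with
`1 − A·exp(−Δt/τ)`; A is free rather than pinned to 1 (holding-state
availability is not exactly 1). Non-monotone recovery beyond 0.02 sets a
flag and a warning.

All fits use bounded nonlinear least squares (scipy `curve_fit`, numeric
Jacobians) with data-driven initializers (half-range crossings for V½,
zero-crossing extrapolation for E_rev, 1/e crossing for τ) and bounds
k ∈ (0.1, 50] mV, R_in ∈ [0, 1], τ ∈ (0.01, 10⁴] ms. Non-convergence and
flat traces return `converged=False` with diagnostics instead of raising.
A pure-ohmic I-V (no detectable gating) converges to a near-degenerate
Boltzmann (V½ below the data or k at its upper bound) — documented by
test, since k is then meaningless.

Window metrics integrate min(activation, fast-inactivation) on a 0.1-mV
grid over −100…+40 mV and report the peak of the product curve; ramp
metrics report the peak inward ramp current as a percentage of the
largest peak inward step current. Group-level values are means ± SEM of
per-cell fits, matching how the source data are reported — not pooled
fits.

Whether published activation V½ values come from the I-V fit or the
normalized G-V fit is ambiguous; both are computed, and on noiseless data
they agree within 0.5 mV (a tested invariant).

## Synthetic data

`navclamp.synth` emulates the recordings the pipeline was designed for:

* **cell variability** — each gating field is perturbed independently
  with a normal deviate whose SD is the published SEM × √n for that group
  and panel (e.g. WT fast V½: 1.4 × √18 ≈ 5.9 mV); draws violating the
  parameter invariants are rejected and resampled. Real cells surely have
  correlated parameters; independence is the simplest defensible model
  and is flagged as a limitation.
* **measurement model** — additive Gaussian current noise (default 10 pA),
  optional linear leak `g_leak·V`, a 4-sample moving average standing in
  for the 5-kHz low-pass at 20-kHz sampling, and P/5 leak subtraction
  implemented as five noisy 1/5-amplitude replica traces plus a holding
  baseline trace, subtracted so leak cancels in expectation (the
  corrected trace then carries √6 × the single-trace noise variance, as
  in real P/N subtraction).
* **group sizes** — 19 / 11 / 9 cells (WT / M1852T / T1596I) by default.

Not emulated: capacitance transients, series-resistance voltage errors,
rundown, seal instability. Passing tests on synthetic data therefore
demonstrate the internal consistency of simulation + fitting + statistics
under this measurement model, not robustness to every artifact of real
recordings.

Determinism: per-cell seeds are spawned from the master seed with
`numpy.random.SeedSequence` (kept below 2³¹) and recorded in the dataset
manifest; regeneration is byte-identical.

The cohort generator produces toy variant/participant tables with the
screen's structure — 111 painful vs 78 painless participants, 12 rare
variants in 10 carriers (all painful; one carrier holds four variants,
one variant is shared by two carriers), five literature-flagged variants,
two variants called pathogenic by all four predictors. MAFs and protein
changes are synthetic draws, not real annotations.

## Group statistics

One-way ANOVA (scipy) across the three groups, then Dunnett's
many-to-one comparison against WT with unequal-n contrast variances. The
family-wise adjustment is Monte-Carlo: the joint null of the comparison
t statistics is the correlated multivariate t with λ_i = √(n_i/(n_i+n₀)),
sampled directly (default 10⁵ draws, seed recorded); the adjusted p is
the `(count+1)/(n_mc+1)` tail estimate, clipped to be ≥ the unadjusted
two-sided p. Monte-Carlo was chosen over quadrature because it is a few
lines, seedable, and verifiable by calibration; the test suite checks
agreement with scipy's quadrature-based Dunnett to 0.01 and a type-I
error of 0.05 ± 0.01 over 2000 simulated null families. Zero pooled
variance is flagged as degenerate rather than producing p = 0.

## Variant screen

The triage rule keeps a variant unless it is **both** above 1% MAF **and**
unreported in the pain literature — a literature report overrides
frequency. With several databases, "common" defaults to above-threshold
in *every* database where the variant was observed (the conservative,
keep-more reading; `db_mode="any"` selects the alternative, since the
source description is ambiguous between the two). Consensus pathogenicity
counts pathogenic calls among Align-GVGD, SIFT, MutationTaster and
PolyPhen-2 (unknown/missing counts as not pathogenic). Carrier counting
is participant-level: a participant with several qualifying variants is
one carrier. The carrier association uses Fisher's exact test
(hypergeometric, two-sided by the minimum-likelihood rule; one-sided for
enrichment in the painful group) with a Haldane–Anscombe 0.5 correction
on the odds ratio when a cell is zero. For the study-shaped table
(10/111 vs 0/78) the one-sided p is ≈0.004.

## Problem sizes and numerical notes

Acceptance-grade round trips use one noiseless cell per group — the
fitted values are deterministic, and cell averaging would only add
sampling noise around the same means. The noisy-dataset statistics test
uses the full 19/11/9 design. The slow-inactivation protocol dominates
runtime (13 × 30-s sweeps, ~8 × 10⁵ samples each) and is simulated
analytically in a few seconds; its RK4 cross-check runs on a three-sweep
subset as noted above. Tolerances asserted for exact-curve fits (≤10⁻⁶
relative) reflect optimizer termination, not model error.

## Known limitations

* Single-Boltzmann gates with unit exponents reproduce fitted equilibria,
  not microscopic gating or β-subunit effects (the published parameters
  already absorb β1/β2 co-expression).
* τ_h between the anchors and R_in are conventions, not measured values;
  quantities that depend on them only through protocol saturation are
  insensitive to the choice, and the fitted slow-inactivation V½/k are
  invariant to affine availability distortions.
* The prepulse/interpulse ladders are plausible reconstructions; the
  published values do not specify them.
* No series-resistance or capacitance artifacts; no persistent-current or
  two-exponential decay analysis.
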