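# Methods

This note documents what the package models, the choices that were
genuinely open, and what the synthetic benchmarks do and do not show.

## Kinetic schemes as linear rate systems

Both schemes are simulated under pseudo-first-order conditions
(nucleotide ≥ 10× protein, enforced with an explicit error naming the
offending ligand) as occupancy dynamics `dp/dt = Q p` over a handful of
states. Columns of `Q` sum to zero (mass conservation, checked to
1e-10 s⁻¹ at construction) and off-diagonal entries are non-negative.
The observable is a yield-weighted sum of occupancies, so noiseless
signals are exact sums of exponentials; simulation uses the
eigen-decomposition, with a matrix-exponential propagator kept as the
brute-force cross-check (agreement to 1e-6 relative is tested, as is
occupancy conservation to 1e-9).

**S1 + ATP (Scheme 1).** States M~M·T (rapid-equilibrium pool), M*·T,
M**·D·Pi, plus one lumped product-release exit. ATP binding is collapsed
into the effective isomerisation rate `k₊₂·K₁[T]/(1+K₁[T])`; an explicit
two-step binding mode (on-rate `K₁·k₋₁`, off-rate `k₋₁ = 10⁴ s⁻¹`)
exists to validate the collapse (fast-phase rates agree within 2% in the
test). The reverse isomerisation `k₋₂` defaults to 0 — step 2 is
treated as irreversible for muscle myosin II; the type rejects
`k₋₂ > 0.1·k₊₂`. Product release is lumped at `k_release = 0.05 s⁻¹`
(typical basal turnover; irrelevant on the 0–5 s observation window and
constrained to be slower than the hydrolysis step).

**Acto·S1 + ATP/ADP (Scheme 2).** States A·M′, A·M, A·M·D, A·M′·D and
the dissociated complex. ATP binding to A·M is rapid-equilibrium
collapsed as above (`K′₁`, `k′₊₂`); the conformer exchange
(`k₊α`, `k₋α`) and its ADP-bound counterpart (`k₊αD`, `k₋αD`) are
explicit. The ADP branch is explicit kinetics, not a rapid-equilibrium
pool: the association rate is `k₋AD/K_AD·[ADP]`, implied by the stored
affinity and release rate. This matters: the competitive-inhibition
form for k_obs([ADP]) is exact only in the rapid-exchange limit, and the
simulated chain carries the finite-exchange lag a real record would.

### Fluorescence yields are calibration, not physics

The source measurements report phase amplitudes, not per-state quantum
yields, so the `ObservableMap` defaults are reverse-engineered from the
printed amplitude structure: tryptophan yields 1.00/1.17/1.18 for
M~M·T / M*·T / M**·D·Pi (17% fast + 1% slow rise for the mutant), and
pyrene yields 1.0 for every actin-bound state vs 1.34 for free
pyrene-actin (≈34% total dequenching). The product-release exit shares
the post-hydrolysis yield, so release contributes no signal. Because the
pre-mix level is normalised to 1, fitted amplitudes are percentages of
pre-mix fluorescence, signed (rise positive), and extrapolate through
the instrument dead time to the mixing instant — which is why the
calibrated amplitudes are recovered even when a fast phase partly decays
within the dead time.

## Exponential fitting

The transient model is `y(t) = y∞ + Σ bⱼ exp(−kⱼ t)` with 1 or 2 phases,
fitted by unweighted least squares (instrument noise is treated as
homoscedastic additive Gaussian, matching the generator). Rates are
optimised on a log scale with amplitudes projected out at every
iteration (variable projection), which removes amplitude initialisation
entirely. Rate initialisation is reproducible without user input:
fast = 3/t₁₀ (time to 10% of total change), slow = fast/20, with five
log-spaced multi-start perturbations (×0.1…×10) before a fit is flagged
non-convergent — flagged results are still returned, never silently
dropped. Standard errors come from the local quadratic (Gauss–Newton)
covariance of the full parameter vector; they scale linearly with the
noise SD over 0.1–2% (tested within 20%). Rates are clamped to
[1e-6, 1e8] s⁻¹, beyond any stopped-flow time base.

Phase-count selection (1 vs 2) uses the extra-sum-of-squares F-test at
α = 0.01, with ties and machine-level residuals resolved in favour of
fewer phases, and a degenerate two-phase fit (coincident rates or a
vanishing amplitude) rejected. The selection criterion used by the
original analysis software is not stated anywhere; the F-test is this
package's choice. When a record's two rates are within ~1.5×, the
two-phase fit is ill-conditioned; the tests document that regime
(huge standard errors or collapse to one phase) rather than hiding it.

Phase labelling follows bench practice: the dominant-amplitude phase of
a record is the principal ("fast") phase. At saturating ATP this is the
large fast rise; at deeply sub-saturating ATP, where the physical fast
eigenvalue carries almost no amplitude, it is the dissociation-limited
phase an experimentalist would actually read off the record.

## Secondary analyses

* **Hyperbolic ATP dependence** `k_obs = k_max·c/(c+K_half)`; the
  initial slope is reported as the derived ratio `k_max/K_half` (delta-
  method SE), never as a third free parameter. A fitted `K_half` above
  max(c)/0.3 raises "saturation not reached"; a flat series raises.
* **Low-concentration linear fit** (through the origin by default,
  points ≤ 0.2·K_half). The through-origin slope of hyperbolic data is
  systematically attenuated by ≈ (3/4)·c_max/K_half — about 15% at the
  0.2·K_half cutoff, under 10% only for points within 0.1·K_half. The
  hyperbola's derived slope is the preferred estimator; this one exists
  for sparse low-concentration designs.
* **ADP competition** `k_obs = k₀/(1+[ADP]/K_AD)` with k₀ estimated
  jointly rather than pinned to the zero-ADP point (reduces bias from a
  single operating point). A series whose k_obs rises with ADP raises a
  model-violation error.
* **Amplitude ratios** `K_α = A_fast/A_slow`, `k₋α = k₊α/K_α`; a
  vanishing slow amplitude returns the fast-myosin sentinel (K_α = ∞),
  where only a single phase is observable.
* **Overall ADP affinity of acto·S1.** The exact algebraic combination
  of the A·M site constant with the bound-state conformer equilibrium is
  not recoverable from the source (figure-only equation), so both
  candidate forms sit behind a convention switch. Default "partition":
  `K_AD = K_ADP/(1+1/K_αD)` — partitioning bound nucleotide into the
  extra A·M′·D conformer increases total binding and tightens the
  overall affinity. The reciprocal form is available, and the inverse
  operation round-trips under either convention.
* **Quadratic tight-binding titration.** Amplitude ∝ bound complex;
  the fitted root is the physical one (bound fraction in
  [0, min(A₀, M)/A₀], the smaller root). Recovery is exact to <1%
  across 1 nM–1 μM at A₀ = 30 nM on noiseless grids; a fitted K_D below
  A₀/50 triggers a tight-binding warning (upper bound only).
* **Phase-assignment diagnostic.** For a fast phase with plateau k_max
  and measured second-order constant K₁k₊₂, the half-max concentration
  is k_max/K₁k₊₂ under binding control but k_max/(2·K₁k₊₂) under
  hydrolysis control (binding irreversible). The operation returns both
  predictions, the diagnosis by proximity of the observed half-max on a
  log scale ("indeterminate" below a 10% margin), and flags the case
  where the supplied slope equals k_max/K_half to printed precision —
  the predictions then coincide with the observation by construction.
* **Construct comparison.** Welch's two-sample t-test on per-preparation
  means at α = 0.05 (the summary SDs are visibly unequal between
  constructs); a single replicate yields a ratio only. A seeded
  Monte-Carlo helper estimates detection power for a given parameter
  shift at n preparations.

## Synthetic experiments

Five designs mirror the study's experiments at their post-mix
concentration ranges: tryptophan ATP titration (0.2 μM S1, ATP grid
0.05–4 × 1/K₁), pyrene ATP-induced dissociation (50 nM acto·S1, same
relative grid on 1/K′₁), ADP competition (20 μM ATP, 0–100 μM ADP),
ADP displacement (premixed 50 μM ADP vs 2 mM ATP), and actin titrations
(30 nM actin; S1 to 160 nM without ADP, to 1.6 μM with 100 μM ADP at
500 μM ATP). Defaults chosen where the study is silent: 8-point
relative ATP grids; instrument dead time 1.5 ms (handled by discarding,
not convolution); additive iid Gaussian noise at 0.5% of the pre-mix
level (no shot-noise model — this matches the unweighted fitting
assumption; the actual instrument noise is unreported).

Records that contain well-separated phases (the two titration-by-ATP
designs and the displacement design) are sampled log-spaced over
dead-time → 20/(slowest resolvable rate), emulating a split time base;
single-exponential designs (competition, actin titrations) use the
ordinary linear time base. This distinction is not cosmetic: log
sampling overweights the first milliseconds, where the explicit ADP
branch is still pre-equilibrating, and drags the recovered competition
affinity upward by ~9%; the linear base keeps it within the printed
uncertainty.

Determinism: one master seed; every trace's noise stream is spawned from
it via `SeedSequence.spawn`, so identical seeds are bit-identical and
replicate streams are independent. Synthetic traces carry their
generating truth in metadata for recovery scoring; text export strips
it. Inter-preparation variability in the battery is lognormal and
multiplicative, with per-parameter CVs taken from the summary table's
SD/mean (10% where no SD is printed).

### Bundled parameter sets

The bundled `S1_*`/`ACTO_S1_*` sets store the printed operational
constants. Where the printed trio (plateau, half-saturation, slope) is
arithmetically inconsistent — the mutant tryptophan figure prints 88 s⁻¹,
93 μM and 1.08 μM⁻¹s⁻¹, but 88/93 = 0.946 — the preset keeps the
(slope, plateau) pair and derives the half-saturation (81.5 μM), so
simulate-and-refit returns the printed slope and plateau. The mutant
hydrolysis plateau uses 4 s⁻¹ (the summary table lists a 0.6–3.8 range;
the derived detached lifetime of ~250 ms corresponds to 4), split 3.2/0.8
between forward and reverse — only the sum is observable. The acto·S1
mutant set takes its ATP-binding pair from the dissociation-figure fit
(1357 s⁻¹, 891 μM) and its conformer branch from the replicate-mean
table (k₊α = 69 s⁻¹, K_α = 11).

## What the benchmarks show — and what they do not

The recovery benchmarks are *in-family*: data generated by the same
model class the fits assume, with iid Gaussian noise. Passing them shows
the chain is unbiased and correctly propagates uncertainty under those
conditions; it says nothing about mixing artifacts, photobleaching,
inner-filter effects, baseline drift or heteroscedastic photon noise,
none of which are modelled.

Two deliberate emulation choices:

* The acto·S1 ATP-binding recovery benchmark runs in the single-phase
  limit (K_α → ∞). With the conformer branch active, the fast
  eigenvalue is `k_diss` plus a coupling term of order k₋α, and the
  hyperbolic refit of the fast phase recovers the half-saturation only
  to ~2–3%; that full-scheme chain is tested separately at a 5%
  tolerance. The limit isolates the two-step binding model the
  hyperbola actually describes.
* The ADP-displacement design recovers the release rate ~10% low:
  post-mix ADP (25 μM) rebinds A·M in competition with dissociation
  even at 2 mM ATP. This is faithful physics, documented rather than
  patched; the conformer-phase rate and amplitude-ratio equilibrium are
  recovered cleanly.

Numerical conventions: degenerate (near-defective) rate matrices get a
1e-9 s⁻¹ diagonal jitter with a logged warning; complex eigenvalue pairs
(impossible for the reversible schemes built here, possible for
hand-built matrices) fall back to their real parts with a warning;
fitted rates are clamped to [1e-6, 1e8] s⁻¹; all fits are deterministic
given identical inputs.

## Report conventions

The comparison report mirrors the summary-table row set with ASCII
transliteration of the symbols (K′₁ → `K1_prime`, k₊α → `k_plus_alpha`,
α → `alpha`); each row records the design that measured it, the ratio
column is exactly the quotient of the two mean columns, and every number
is recomputable from the persisted per-preparation fit records.
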