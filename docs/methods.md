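# Methods

## Lateral-inhibition circuit model

Two (or three) cells are coupled by the dimensionless equations

    dN_i/dt = D̄_i^r / (K_N^r + D̄_i^r) − N_i
    dD_i/dt = v · ( 1 / (1 + (N_i/K_D)^h) − D_i )

where `N_i` is activated Notch, `D_i` Delta, `D̄_i` the Delta input from cell
i's neighbors, `K_N` the threshold for Notch activation by neighbor Delta,
`K_D` the threshold for Delta repression by same-cell Notch, `v` the
Notch/Delta degradation-rate ratio (default 1), and `r = h = 2` Hill
coefficients capturing cooperativity. All state variables live in [0, 1];
time is in units of the Notch degradation timescale. A transcriptional
reporter is computed as `R_i(t) = β ∫₀ᵗ N_i dt` with β = 1 (the
production-dominated early phase); the full first-order form
`dR/dt = βN − αR` is available as `reporter_mode="ode"` and reduces to the
integral as α → 0 (checked to 1e-4 for α ≤ 1e-6).

Defaults mirror the biology being modeled: both cells start with high Delta
(D = 1, the steady state of the unrepressed Delta equation) and low Notch,
with a 10% relative head start for one cell (N = 0.010 vs 0.011) to break
symmetry. Two reference points organize the analysis: `K_N=0.5, K_D=0.25`
(healthy-like, intact repression — the fitted wild-type K_D range is
0.2–0.3) and `K_N=0.5, K_D=1` (injury-like, weakened repression). Scalar
metrics are evaluated at t=10: *steady-state Delta* is the Delta of the
high-Notch cell (argmax of Notch at t_end, ties to the lowest index), and
*signaling speed* is `(R(10) − R(4)) / 6` with β=1, linearly interpolated on
the dense output grid. Phase maps sweep K_N log-spaced over [0.1, 10] and
K_D linearly over [0.1, 2] by default.

**Integration.** Adaptive Runge–Kutta (scipy `solve_ivp`, RK45) with
rtol=1e-8, atol=1e-10, output every dt=0.01. Tests verify trajectories
against an independent fixed-step RK4 integrator (dt=1e-4) to 1e-5 sup-norm.

**Triplet coupling.** For more than one neighbor the Delta input is the
arithmetic mean of the neighbors' Delta, keeping `D̄` on the same [0, 1]
scale and making the pair the exact one-neighbor special case
(`neighbor_input="sum"` is available for additive ligand pooling; the
topology itself is configurable). Averaging halves the effective coupling
gain of the all-mutual triplet's asymmetric mode, which matters below.

### Timescale of symmetry breaking (and a deliberate red test)

At the healthy-like point the symmetric state (N≈0.335, D≈0.36) is only
weakly unstable: the antisymmetric mode grows at λ = −1 + √(f′·|g′|) ≈ 0.31,
so the 0.001 initial asymmetry needs t ≈ 30–40 to resolve into the opposing
states (N ≈ 0.80/0.03, D ≈ 0.09/0.98); at t=10 the pair still sits near the
symmetric state. Moreover, with h=2 the repression term is bounded below by
`1/(1+(1/K_D)²)`, i.e. Delta can never fall below 0.059 at K_D=0.25. One
acceptance test asserts Delta(t=10) < 0.05 at this point; both the
resolution timescale and the Hill-function floor make that bound
unattainable under these equations, and the test is intentionally left
failing rather than weakened. All comparative claims are unaffected: the
low-K_D regime shows markedly lower Delta and roughly half the signaling
speed of the high-K_D regime at t=10, speed is non-decreasing in K_D at
every K_N on the default grids, and the high-K_D regime reproduces the
high-Notch/high-Delta state. For the all-mutual triplet with mean coupling
the asymmetric mode is stable at K_D=0.25 (coupling eigenvalue −1/2), so no
winner emerges there; documentation of this regime lives in the circuit
tests.

## Mixture classification of reporter intensities

Single-cell mean nuclear reporter intensities are fitted with a
two-component Gaussian mixture **on log10 intensity** — the bimodality and
near-Gaussian component shapes appear on the log scale (a linear-scale fit
is available via `scale="linear"`). Fitting uses EM (scikit-learn
`GaussianMixture`) with k-means initialization, 20 restarts keeping the best
log-likelihood, a component-variance floor of 1e-4 (log10 units)², a
20-sample minimum, and a fixed seed; identical data and seed give
bit-identical fits. Components are ordered by mean (component 0 = NRE^low).

The NRE^low/NRE^hi threshold is the equal-posterior point: the root of
`w₀·φ(x; μ₀, σ₀) = w₁·φ(x; μ₁, σ₁)` located by bisection on [μ₀, μ₁] to
1e-8. Severely overlapping components with no crossing between the means
raise a boundary-undefined error; degenerate fits (collapsed variance,
vanishing weight) are returned flagged with a warning. Cells strictly above
the boundary are NRE^hi; a cell exactly at the boundary is NRE^low. Any fit
can be applied to any record set, so marker subsets (e.g. mitotic PH3+
cells) or other genotypes are scored against their reference condition's
mixture. Cross-tabs report exact integer counts alongside proportions, and
a zero denominator yields an undefined (NaN) proportion, never 0.

Histograms use bins uniform in log10 space with width 0.04 or 0.05 decades,
edges at integer multiples of the width so samples share a common grid.
Distribution comparisons use the two-sample Kolmogorov–Smirnov test
(asymptotic p-value); rate comparisons use the unpaired two-sided
Mann–Whitney test.

## Timer-trace pipeline

Input is a long table of per-frame dGFP/RFP mean intensities per tracked
cell, sampled every 7.5 min. Steps, in order:

1. **Normalization** — each channel divided by its movie-wide maximum
   (per movie, per channel), mapping intensities to [0, 1]; idempotent.
2. **Smoothing** — robust local-linear regression ('rlowess') with a 5-point
   span: tricube distance weights over the 5 nearest frames, two bisquare
   robustness iterations with residual scale 6×MAD (falling back to the mean
   absolute residual when the MAD degenerates to 0, e.g. a flat baseline
   with isolated spikes). Local linear fits reproduce constants and exact
   lines unchanged. statsmodels' lowess was not used: at 5-point spans it
   interpolates isolated spikes at odd robustness-iteration counts instead
   of suppressing them. A plain centered moving average is provided for
   sensitivity analysis.
3. **QC** — first matching rule wins: fewer than 8 points → `excluded_short`;
   whole-track GFP < 0.1 with mean RFP ≥ 0.1 → `notch_off` (recently
   deactivated cells, excluded from slope analysis as their own category);
   mean GFP over the first ⌈n/2⌉ points < 0.1 → `excluded_low_signal`;
   residual noise score SD(raw − smoothed)/(max − min of smoothed) > 0.15 →
   `excluded_noisy`; else `included`. The noise score is a scale-free,
   reproducible stand-in for a manual "too noisy to analyze" judgment. The
   Notch-OFF rule is checked before the low-signal rule because every
   Notch-OFF track also has a dim first half; the reverse order would make
   the category unreachable.
4. **Split and fit** — each included track is split at the maximum of the
   smoothed series (earliest index on ties; the maximum belongs to both
   segments), and an ordinary least-squares line `y = mx + b` is fitted to
   each segment with ≥3 points, x being the frame offset within the track.
   Slopes are therefore in normalized intensity per frame; multiply by 8
   (`PER_HOUR_FACTOR`) for per-hour units. Noiseless piecewise-linear
   fixtures are recovered to 1e-10.
5. **Pattern classification** — `up_down` requires a qualifying rising and a
   qualifying falling segment; a segment qualifies if its slope clears the
   floor (default 0.002/frame) *and* it traverses ≥0.1 normalized units
   (|m| × span). The amplitude requirement exists because noise makes the
   argmax wander across plateaus and track edges, creating short spurious
   segments that can be steeper than genuine slow phases; real signaling
   phases sweep a large fraction of the track's range. Tracks with no
   qualifying segment are `indeterminate`.
6. **Summaries** — per (condition, direction): n, median slope, and the
   fraction of rapid cells (|m| > 0.025/frame, sign-appropriate; the
   deactivation threshold is assumed symmetric to the printed activation
   threshold and is configurable), plus Mann–Whitney p-values between
   conditions.

## Synthetic data

**Populations.** Cells are drawn from a two-component log10-normal mixture
(defaults: means 1.0 and 2.5, SDs 0.2, high-mode weight 0.3 healthy / 0.5
injured); Delta+ and PH3+ flags are Bernoulli with component-conditional
probabilities (healthy: P(Delta+|low)=0.84, P(Delta+|high)=0.10; injured
raises P(Delta+|high) to 0.62, emulating feedback loss). True component
labels are retained, so classification accuracy and marker cross-tabs have
closed-form expectations.

**Timer forward model.** Each fluorophore follows a linear two-compartment
system, immature I and mature M:

    dI/dt = A(t) − (k_m + k_d)·I,     dM/dt = k_m·I − k_d·M

with k = ln2/t applied to the reported half-times (maturation times are
treated as half-times too — an approximation, flagged as such): dGFP
maturation 0.1 h and half-life 2 h, RFP 1.5 h and 20 h. Promoter activity
A(t) ∈ [0, 1] is piecewise linear (patterns up_only, down_only, up_down,
sustained, with onset, rise rate, plateau, fall rate); a circuit-model Notch
trajectory can be used as A(t) directly (`activity_from_trajectory`),
linking the ODE module to trace generation. Integration starts at the
steady state of A(0), so cells already signaling before the movie opens at
their plateau. The constant-activity steady state `a·k_m/((k_m+k_d)·k_d)`
and the zero-state step response are matched analytically to 1e-6, and a
pulse yields an RFP peak strictly after the dGFP peak — the timer's
temporal-separation signature.

**Movies.** A movie draws per-cell activity profiles from a condition
preset — healthy: rise 0.22/h, fall 0.18/h; injured: rise 0.55/h, fall
0.42/h (≈2.5× faster), each jittered by a lognormal factor (σ=0.2), onsets
uniform on 0.5–3 h and plateaus on 0.5–2 h. Default per-pattern cell counts
reproduce the observed phase-pattern mixes: healthy 13/11/8
(up/down/up_down) of 32 cells, injured 18/22/53 of 93. Traces are scaled to
arbitrary units with a ±10% per-cell gain, windowed to the frames where
dGFP clears a visibility floor of 10% of the movie maximum (±2 frames) —
cells are tracked from first appearance until signal loss, and the GFP-dark
tail after complete downregulation is the recently-Notch-OFF state, not an
analyzable GFP trace — then randomly trimmed by up to 6 frames per side
(cells entering/leaving the field) and perturbed with additive Gaussian
noise, σ=0.02 on the normalized scale. All generators are deterministic
under a fixed seed.

**What the generator does not emulate.** Photobleaching, focus/z drift,
segmentation error, multiplicative or correlated noise, cell divisions or
movements, and any pixel-level process; intensities are idealized mature-
fluorophore levels. Passing round-trip tests therefore demonstrates that
the pipeline recovers the generative truth under clean additive noise, not
that it is robust to every artifact of real microscopy.

## Numerical choices and degenerate inputs

- Circuit solver tolerances rtol=1e-8/atol=1e-10; oracle agreement 1e-5.
- Mixture bisection tolerance 1e-8; variance floor 1e-4 (log10 units)².
- Argmax ties: earliest index. "First half" = first ⌈n/2⌉ points.
- Noise-score denominator of 0 (constant smoothed track): score 0 if the
  residuals are also 0, else infinite (hence `excluded_noisy`).
- Non-positive intensities are rejected per record (log-transform
  precondition) and reported, never silently classified.
- Proportions with zero denominators are NaN, with integer counts retained.

## Observed-window effects on rate summaries

Split-at-maximum slopes are diluted by whatever plateau or decay tail falls
inside a segment, so measured medians compress the generative rate
difference between conditions: upregulation medians preserve the
injured > healthy ordering clearly, while downregulation medians — fitted
over plateau + fall within the dGFP-visible window — come out nearly equal
between presets. This is a property of the windowed split-and-fit
procedure, not of the generator's rates, and it is why reported medians
should be read alongside the rapid-fraction and pattern-proportion metrics.

## Problem sizes

Test and acceptance runs use the sizes natural to the analysis: 5000-cell
populations for mixture recovery (10000 for closed-form marker checks),
32/93-cell movies at 165 frames, 100-replicate noise studies, 5×5 grids for
monotonicity sweeps and ~180-point grids for the full phase maps.
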