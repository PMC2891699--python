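# Methods

## Model

The simulator implements a mean-field flip-flop model of the sleep–wake
switch.  Two neuronal populations — wake-active monoaminergic brainstem
nuclei (MA) and the sleep-active ventrolateral preoptic area (VLPO) — are
each described by a mean cell-body potential `V` (mV relative to resting)
mapped to a population firing rate by the sigmoid
`Q(V) = Q_max/(1 + exp(-(V-θ)/σ'))`.  Mutual inhibition (`ν_mv, ν_vm < 0`)
creates bistability: for intermediate VLPO drive the frozen (V_m, V_v)
subsystem has two stable fixed points (wake-like: MA active; sleep-like:
VLPO active) separated by a saddle, which `core_model.flip_flop_fixed_points`
locates by bracketed root-finding on the scalar fixed-point equation.

Transitions are driven by two slow inputs to the VLPO: a somnogen
concentration `H` (nM) that relaxes toward `μ·Q_m` with time constant `χ`
(production ∝ MA firing, clearance ∝ concentration), and an entrained
sinusoidal circadian drive `ν_vc C(t)` with 24 h period.  The MA group
receives a constant cholinergic/orexinergic drive `A`, held at its average
level so ultradian REM/NREM alternation is deliberately absent; the model
scores only binary wake/sleep.  Light entrainment of the circadian
oscillator is not modeled (the drive is assumed well entrained); nocturnal
species are represented by a 12 h phase shift (`φ = π`).

## Parameters and units

Time is in hours at every API surface.  The neuromodulator decay times
`τ_m = τ_v = 10 s` are stored in seconds (their natural scale) and
converted once, in `SwitchParams.tau_*_h`; this conversion is covered by a
dedicated unit test because mixing seconds and hours is the likeliest bug
in this model class.  Weight × firing-rate products need no conversion
(mV·s × s⁻¹ = mV).

Calibrated defaults (human): `Q_max = 100 s⁻¹`, `θ = 10 mV`, `σ' = 3 mV`,
`ν_mv = -1.8 mV·s` (VLPO→MA), `ν_vm = -2.1 mV·s` (MA→VLPO),
`ν_vh = 1.0 mV·nM⁻¹`, `μ = 4.4 nM·s`, `A = 1.3 mV`, `χ = 45 h`,
mean circadian drive `ν_vc c₀ = -13.05 mV` with delivered oscillatory
amplitude `-2.9 mV` (the circadian coupling is negative: SCN output
promotes wake).  This parameterization is the model's established
calibration lineage and reproduces, with no further adjustment, ~8.5 h of
consolidated monophasic human sleep, rapid (~8–9 min) transitions, and a
monophasic→polyphasic boundary at χ ≈ 16 h — the three behaviors used as
end-to-end checks.  We expose the *delivered* oscillatory amplitude
`circ_amp` directly rather than a separate (coupling × unit-cosine)
factorization; with `circ_amp < 0` and `φ = 0`, wake propensity peaks at
t = 0 mod 24 h.  The mean drive is negative in all physiological presets,
but non-negative values are accepted: the no-wake extreme of the parameter
map (lesion-like loss of the wake-promoting drive) is only reachable when
the mean drive crosses zero, because with any negative mean drive the
homeostatic feedback always eventually restores wake.

All parameters serialize to a flat YAML mapping; `human_nominal` is the
calibrated preset.  The `rodent_like` (χ = 0.5 h, -8.0 mV),
`elephant_like` (χ = 8 h, -14.5 mV), `seal_like` (χ = 6 h, -10.0 mV) and
`opossum_like` (χ = 1 h, -7.0 mV, φ = π) presets are representatives of
the corresponding regions of the (drive, χ) map chosen from sweep probes
(rodent: ~7-min bouts; elephant: ~3.8 h/day in ~1 h bouts; seal: ~7.5 h/day
polyphasic), not literature-pinned values.

## Integration

Deterministic runs use classical RK4; stochastic runs use Euler–Maruyama
(higher order is pointless against additive noise).  Both share one
right-hand side.  Default step `dt = 10 s`, comparable to τ; a convergence
test checks that halving it leaves attractor metrics unchanged.  Noise
terms are independent standard normals added to the two potential
equations with amplitude `σ_noise/√Δt`, making the variance contributed
over a fixed physical interval independent of the step (asserted by a
drift-free random-walk test).  `σ_noise` defaults to 0; 1 mV·h^1/2 is a
documented exemplar for irregular-pattern demonstrations.  `H` is clamped
non-negative after each step (negativity can only arise from noise or
discretization).  One `numpy` generator per simulation; the resolved seed
is recorded in the result for provenance.  Simulations integrate
`duration` hours and discard the first `transient_discard` (default 5
days, several circadian cycles) so metrics are computed on the attractor;
the standard protocol scores 10 days after that transient.  A non-finite
state aborts with an error naming the step.

## Scoring and metrics

Wake is scored where `Q_m > 1 s⁻¹` (strict), between the ~5 s⁻¹ wake
plateau and ~0 s⁻¹ sleep level; the threshold is configurable.  Episodes
are maximal constant-state runs with boundaries at sample midpoints; the
first and last episodes are flagged truncated and excluded from
bout-length statistics.  Daily sleep is the sleep fraction × 24 h; episode
rate counts sleep onsets per recorded day.  Zones: NO_WAKE / NO_SLEEP when
the minority state is below 1% of the record, MONOPHASIC when there is
exactly one sleep episode per cycle, else POLYPHASIC.  An optional
minimum-bout filter (off by default) merges sub-threshold flickers for
noisy runs.

Transition durations: the wake and sleep plateaus drift slowly for hours
around each flip as `H` creeps, so crossing times of fixed fractions of
the global wake plateau conflate that creep with the switch itself (they
measure ~100 min at human nominal).  The implementation therefore isolates
the rapid segment: within ±2 h of each threshold flip, the maximal
contiguous interval where `|dQ_m/dt|` exceeds 2% of its per-flip peak, and
reports the time spent between `frac_lo` and `frac_hi` (default 5–95%) of
that segment's span.  At human nominal this yields a mean of ~8.5 min.
Both fractions, the slope fraction, and the window are arguments.

## Parameter map and species inversion

`sweep_map` simulates every (mean drive, χ) cell independently with an
identical configuration (results are evaluation-order independent; a
failed cell is recorded, not fatal) and default grid spans drive
-17…-9 mV × χ 0.1…100 h (log-spaced), bracketing the calibrated human
drive.  Daily sleep is monotone non-increasing in inhibitory drive
magnitude and episode rate monotone non-increasing in χ (coarse-grained;
plateaus allowed) — both asserted as properties.  `monophasic_boundary`
bisects χ between polyphasic and monophasic attractors at fixed drive.
Species regions are axis-aligned preimages of the reported metric
intervals (no smoothing), optionally clipped at a χ upper bound for
monophasic primates (72 h, the human sleep-deprivation-derived bound).
The bundled species table ships placeholder metric values only, flagged
as such and skipped by the loader.

## Unihemispheric sleep

Two identical hemispheres, each with its own `H` driven by its own MA
firing, couple through `ν_inh Q(V_v')` (≤ 0) added to each VLPO equation.
Perfectly symmetric deterministic initial conditions stay synchronized
forever, so default initial somnogen levels differ by 5% to seed
alternation; the desynchronization mechanism is a modeling choice (noise
is the alternative) and is not itself a prediction.  Four-state scoring
(BW/BS/LUS/RUS) derives deterministically from the two hypnograms;
unihemispheric (and bihemispheric-sleep) episodes must last ≥ 5 min to
count, guarding against transition skew between hemispheres.

`find_thresholds` locates (a) the weakest coupling giving ≥ 1
unihemispheric episode per day and (b) the weakest eliminating all
bihemispheric-sleep episodes, by a 13-point coarse scan over |ν_inh| ∈
[0, 3] mV·s (monotonicity of both indicators is verified before bisecting;
a non-monotone scan raises with the scan table).  At the seal-like preset
the ratio (b)/(a) is ≈ 19 — eliminating bihemispheric sleep requires far
more than the 2.4-fold strengthening that bounds it from below.  The
onset threshold (a) is small at these parameters: with deterministic
asymmetric initial conditions, weakly-circadian-gated polyphasic sleep
sustains anti-phase alternation at very weak coupling, so (a) is limited
by the bisection tolerance (1% of the scan range).  Base-parameter choice
matters: at χ ≈ 2 h an intermediate-coupling "mutual veto" window appears
in which neither VLPO can activate (total insomnia), violating the
monotonicity precondition; the seal preset (χ = 6 h) avoids it.

`furseal_protocol` ramps the coupling linearly from 0 to a supra-threshold
value (default -0.4 mV·s, ~2.7× the elimination threshold) across a
configurable window (default days 2–4).  The protocol runs with no
pre-transient so the initial homeostatic asymmetry survives to the ramp: a
ν = 0 transient resynchronizes the hemispheres, and ramping coupling onto
an exactly symmetric state produces the mutual-veto insomnia artifact
instead of alternation.  Output: polyphasic bihemispheric sleep before the
ramp, alternating left/right unihemispheric sleep after it, with
per-hemisphere daily sleep staying in a physiological band throughout.

## Allometric scaling

`theoretical_chi_exponent` returns `b(1-k)` — clearance per unit volume
scales as brain mass^(k-1), so χ scales as its inverse — and
`mu_scaling_exponent` returns `metabolic_volume_exponent + b(1-k)`,
≈ +0.09 under the defaults (b = 0.7, k = 2/3, metabolic exponent -0.14),
which justifies holding μ fixed while χ varies across species.  The two
satisfy the identity `mu_exp - metabolic_exp = chi_exp` (μ ∝ power × χ).

`fit_power_law` fits log10 χ against log10 mass by least squares, using
geometric-midpoints of the per-species χ intervals for the point estimate
(the species inversion yields regions, not points).  Uncertainty comes
from 10,000 bootstrap replicates that resample species with replacement
and draw one χ per species uniformly in log space within its interval;
this scheme is a design choice, validated by parameter recovery on
synthetic species (true exponent recovered within 2 bootstrap SD).
Empirical cross-species exponents are not reproduced here because the
per-species body masses and fitted χ ranges are not bundled; the fixture
table is a template for users to populate.

## Synthetic hypnogram generator

`generate_hypnogram_fixture` emulates behavioral/EEG scoring records:
alternating bouts on a 1-min grid with exponentially distributed
sleep-bout lengths (the distribution reported for mammalian sleep
episodes; default mean 6 min is rat-like), wake bouts set by the
episode-rate budget with a sinusoidal 24 h modulation of sleep propensity.
It does not emulate sleep-stage structure, scorer disagreement, or
autocorrelated artifacts, so tests passing on fixtures validate the
scoring pipeline's arithmetic, not its robustness to real polysomnography.
Ground truth (including the realized per-record bout statistics) is
returned with the record.

## Numerical choices and limitations

- Bisection tolerances: 0.25 h for the monophasic boundary, 1% of the
  coupling scan range for thresholds; both arguments.
- Boundary convention: a sample exactly at the wake threshold scores SLEEP.
- Problem sizes: the standard scored record is 10 days after a 5-day
  transient at dt = 10 s, which keeps every per-cell simulation at ~0.5 s
  and gives stable episode counts for χ up to the monophasic boundary.
- No adaptive stepping, no delay terms, no REM/NREM differentiation, no
  light-driven entrainment, no torpor/hibernation states.
- The parameter map's zone boundaries depend mildly on the 1% no-state
  threshold and the episode-count rounding; both are documented defaults
  rather than tuned values.
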