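# sleepswitch

A quantitative simulator of the mammalian sleep–wake switch, for
computational sleep researchers and comparative physiologists who want to
relate behavioral sleep metrics (daily sleep duration, bout length,
episode counts, unihemispheric sleep) to the underlying neuronal circuit.

## The model

Wake is maintained by the monoaminergic brainstem nuclei (MA); sleep by the
ventrolateral preoptic area (VLPO).  Each population has a mean cell-body
potential `V_j` (mV, relative to resting) and a sigmoidal firing rate

    Q(V) = Q_max / (1 + exp(-(V - θ)/σ'))

Mutual inhibition makes the pair a bistable flip-flop:

    τ_m dV_m/dt = -V_m + ν_mv Q(V_v) + A
    τ_v dV_v/dt = -V_v + ν_vm Q(V_m) + D_v(H, t)
    χ   dH/dt   = -H + μ Q(V_m)

The VLPO drive `D_v = ν_vh H + ν_vc C(t)` combines a homeostatic somnogen
concentration `H` (nM; accumulates with wake-level MA firing, clears with
time constant `χ`) and an entrained 24 h sinusoidal circadian drive
`C(t)`.  Two parameters capture interspecies diversity: the **mean VLPO
drive** (sets daily sleep duration) and the **homeostatic time constant χ**
(sets the cycling rate: ~45 h in humans gives consolidated monophasic
sleep; minutes-to-hours gives rodent-like polyphasic sleep).  Coupling two
hemispheres with an inhibitory contralateral VLPO–VLPO connection
(`ν_inh Q(V_v')` added to each VLPO equation) generates unihemispheric
sleep.  A production/clearance argument (production ∝ brain metabolic
power, clearance ∝ working surface area ∝ brain mass^k) predicts
`χ ∝ M^(b(1-k))` for body mass `M`, i.e. exponent 0.23 for simple-solid
geometry (k = 2/3) and brain-mass allometry b = 0.7.

Modules: `core_model` (parameters, vector field, fixed points),
`integrator` (RK4 / Euler–Maruyama), `metrics` (hypnograms, bouts, zones,
transitions), `mapping` (parameter-plane sweeps, species regions),
`unihemispheric` (coupled hemispheres, coupling thresholds, fur-seal
protocol), `allometry` (scaling exponents, bootstrap power-law fits),
`fixtures` (synthetic hypnograms with known ground truth).

## Worked example

```sh
$ sleepswitch simulate --preset human_nominal -o out
total_daily_sleep = 8.52 h, zone = MONOPHASIC
```

`out/metrics.json` then contains

```json
{
  "total_daily_sleep": 8.516075272550518,
  "mean_bout_length": 511.00000000000045,
  "bouts_per_day": 1.0,
  "mean_transition_duration": 8.49999999999227,
  "n_episodes_per_cycle": 1,
  "zone": "MONOPHASIC"
}
```

i.e. the calibrated human parameter set (χ = 45 h), integrated for 10 days
after a 5-day transient, sleeps 8.5 h/day in a single ~8.5-hour bout, with
rapid (~8.5 min) wake↔sleep transitions — consolidated monophasic sleep.
Lowering χ below ~16 h fragments sleep into multiple daily episodes
(`sleepswitch map` sweeps the whole plane); the same library call is
available as `sleepswitch.monophasic_boundary`.  The analogous
one-liners for the other subsystems:

```python
import sleepswitch as ss
from sleepswitch.unihemispheric import CoupledParams

# coupling thresholds for unihemispheric sleep at the seal-like preset
p = CoupledParams(hemi=ss.get_preset("seal_like"))
cfg = ss.SimConfig(duration=360, transient_discard=120)
nu_t1, nu_t2 = ss.find_thresholds(p, cfg)   # onset / BS-elimination weights

# theoretical allometric exponent of the homeostatic time constant
ss.theoretical_chi_exponent(ss.ScalingParams(b=0.7, k=2/3))   # 0.2333...
```

## Data

`src/sleepswitch/data/species_fixture.csv` is an editable template for the
species-metrics table (17 species names, body masses, metric ranges).  All
metric values it ships with are placeholders flagged in the `placeholder`
column and are skipped by the loader; transcribe real ranges from the
primary literature before using it for species-region fits.
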