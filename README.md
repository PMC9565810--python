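# fenestra

Chloride permeation pathway analysis for pentameric ligand-gated ion
channels (pLGICs), built around the observation that ions reach the
channel's extracellular vestibule not only through the apical entrance on
the pore axis but predominantly through **lateral fenestrations** — tunnels
through the side wall of the extracellular domain. The package provides the
complete desk-scale analysis chain:

- **Event detection** (`fenestra.events`): a compartment state machine with
  hysteresis that turns ion coordinate tracks into classified permeation
  events — transmembrane (pore), lateral (fenestration) and apical
  crossings, each inward or outward.
- **Currents and I–V statistics** (`fenestra.currents`): constant-field
  voltage (V_m = E_z·L_z), event-counting currents I = N·e/T with Poisson
  error σ = I/√N, conductances, pathway fractions, lateral permeability
  ratios, per-branch slope fits and rectification indices.
- **Kinetic model** (`fenestra.kinetics`): a three-compartment model of
  vestibular rectification (extracellular bath ⇌ vestibule ⇌ intracellular
  bath) with a closed-form steady state and an exact Gillespie stochastic
  simulator as an independent oracle.
- **Synthetic trajectories** (`fenestra.synth`): a generator that renders
  Poisson-scheduled crossings through the correct gate geometry with known
  ground truth, so the detector can be validated event by event.
- **Patch-clamp simulation and fitting** (`fenestra.patch`): two-state
  single-channel traces, all-points-histogram two-Gaussian amplitude fits,
  branch-wise slope conductances, rectification reports and Hill
  dose-response fits.

Real molecular-dynamics trajectories enter through `fenestra.tracks`
(TSV-based `IonTrack` contract; XTC/TRR/DCD ingestion via the optional
MDAnalysis extra).

## Worked example

### 1. Synthetic trajectories → events → pathway statistics

```python
from fenestra import (
    GeneratorConfig, PathwayRates, RegionModel, generate_tracks,
    detect_events_all, pathway_fractions, recovery_report,
)

geometry = RegionModel()          # template pLGIC-like compartment geometry
config = GeneratorConfig(
    rates=PathwayRates(tm_inward=0.08, tm_outward=0.08,
                       lat_inward=0.25, lat_outward=0.25,
                       api_inward=0.02, api_outward=0.02),   # events/ns
    duration=80.0, n_ions=30, n_vest_init=4, seed=2024,
)
tracks, truth = generate_tracks(config)
log = detect_events_all(tracks, geometry)
report = recovery_report(log, truth)
print(f"{len(log.events)} events detected, {report.n_truth} rendered "
      f"({report.missed} missed, {report.spurious} spurious, "
      f"{report.misclassified} misclassified)")
frac = pathway_fractions(log)
print(f"lateral {frac.lateral_rate:.3f}/ns, apical {frac.apical_rate:.3f}/ns, "
      f"transmembrane {frac.tm_rate:.3f}/ns; apical fraction {frac.apical_fraction:.1f}%")
```

```
62 events detected, 62 rendered (0 missed, 0 spurious, 0 misclassified)
lateral 0.450/ns, apical 0.050/ns, transmembrane 0.275/ns; apical fraction 10.0%
```

### 2. Kinetic model of vestibular rectification

```python
import numpy as np
from fenestra import (KineticParams, model_iv, rectification_index_model,
                      gillespie_simulate, steady_state)

params = KineticParams()          # k_l = k_-l = 0.5, k_a = k_-a = 0.025, k_t = k_-t = 0.1
grid = np.arange(-250, 251, 50)
for scale, name in [(1.0, "WT"), (0.01, "k_l/100")]:
    iv = model_iv(params, grid, lateral_scale=scale)
    idx = rectification_index_model(iv, 250.0)
    print(f"{name}: J(+250) = {iv.query('V_mV == 250')['J_net'].iloc[0]:.4f}, "
          f"J(-250) = {iv.query('V_mV == -250')['J_net'].iloc[0]:.4f}, "
          f"rectification index {idx:.2f}")
res = gillespie_simulate(params, 150.0, n_A=200, horizon=200.0, seed=11)
ss = steady_state(150.0, params)
print(f"Gillespie occupancy {res.occupancy_mean:.1f} vs analytic {ss.B_ratio * 200:.1f}; "
      f"flux {res.flux_net:.2f} vs {ss.J_net * 200:.2f}")
```

```
WT: J(+250) = 0.2797, J(-250) = -0.5986, rectification index 2.14
k_l/100: J(+250) = 0.0285, J(-250) = -0.5862, rectification index 20.54
Gillespie occupancy 113.8 vs analytic 114.6; flux 44.63 vs 44.84
```

Hindering the lateral pathway (scaling k_l, k_-l down 100-fold) collapses
the outward branch to its supply-limited plateau (k_l + k_a)·A0 while barely
touching the inward branch — inward rectification from vestibule access
alone.

### 3. Single-channel traces → amplitude fits → rectification report

```python
from fenestra import (GatingModel, PATCH_VOLTAGES, simulate_trace, fit_amplitude,
                      build_iv, fit_two_slopes, rectification_report)

model = GatingModel(gamma_in=85.16, gamma_out=60.47)   # wild-type-like
amps = {}
for V in PATCH_VOLTAGES:                                # -100..+100 mV, 20 mV steps
    if V == 0:
        continue
    vals = []
    for patch in range(3):
        trace = simulate_trace(model, float(V), 0.4, seed=abs(1000 + 17 * V) + patch)
        vals.append(fit_amplitude(trace).amplitude)
    amps[float(V)] = vals
fit = fit_two_slopes(build_iv(amps, label="WT"))
print(f"inward slope {fit.inward_slope:.2f} pS, outward slope {fit.outward_slope:.2f} pS, "
      f"rectification index {fit.index:.2f}")

report = rectification_report(
    {"WT": (85.16, 60.47), "K104E": (64.78, 20.19)}, reference="WT"
)
print(f"indices: {report.indices}")
print(f"outward reduction: {report.outward_reduction_pct['K104E']}%")
```

```
inward slope 85.30 pS, outward slope 60.46 pS, rectification index 1.41
indices: {'WT': 1.41, 'K104E': 3.21}
outward reduction: 67%
```

## Command-line interface

Every stage is also available as a `fenestra` subcommand operating on TSV /
YAML / JSON files:

```sh
fenestra simulate-tracks --config gen.yaml --out tracks.tsv --truth truth.tsv
fenestra detect-events   --tracks tracks.tsv --voltage -150 --out events.tsv
fenestra iv              --events run1.tsv --events run2.tsv --out iv.tsv
fenestra perm-ratio      --mutant mut.tsv --wt wt.tsv
fenestra kinetics        --scenario kl100 --out model_iv.tsv
fenestra kinetics-sim    --voltage 150 --seed 4
fenestra simulate-patch  --voltage -100 --seed 3 --out trace.tsv
fenestra fit-amplitude   --trace trace.tsv
fenestra rectification-report --slopes slopes.json --reference WT
```

See `fenestra <command> --help` and the YAML schemas in
`fenestra/config.py`.

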