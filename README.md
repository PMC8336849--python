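# ageflux

Demand-gated, age-structured simulation of mRNA (and protein) level
fluctuations, plus exhaustive-search estimation of RNA metabolic
parameters — transcription rates, degradation rates, lifespans and
demands — from single-cell time-series abundance data.

## Who this is for

Transcriptomics researchers who observe fluctuating RNA levels in
time-course experiments and want mechanistic quantities that abundance
snapshots alone do not give: how much was transcribed and degraded over the
experiment, how long the transcripts live, and what level of demand the
cell was tracking. The same machinery applies to any biomolecule whose
production is pulsed and whose degradation depends on molecular age.

## The model

A cell's pool of molecules is partitioned by *age* x — the number of
discrete time steps since transcription. Each step, cohorts age with
per-age survival fractions d_x, and a production pulse of fixed size B0
enters at age 0 whenever total activity falls short of the demand for
activity:

```
B[x,t] = B[x-1,t-1] · d[x-1]                    (aging with survival)
B[0,t] = B0   if TA[t-1] < DA[t], else 0        (demand-gated pulse)
TB[t]  = Σ_x B[x,t]                             (total abundance)
TA[t]  = Σ_x a[x] · B[x,t]                      (total activity)
```

with a_x the per-age activity coefficients and DA[t] the demand schedule
(constant, square-wave rotation, logistic ramp, or arbitrary series).
Despite its simplicity the model produces limit cycles whose period and
amplitude depend on demand, aliasing artefacts under sparse sampling,
stable levels under unregulated or unattainable-demand transcription, and
— in the coupled RNA→protein variant, where the unmet demand for protein
activity becomes the demand driving transcription — the characteristic
looseness of protein/mRNA ratios next to the stability of the
translation-rate/transcription-rate ratio.

The inverse problem is solved exactly as an exhaustive grid search:
every candidate (lifespan, survival rates, pulse level, demand, initial
age distribution) is simulated and the minimum-SSE candidate selected,
with R² and the median absolute percentage error (MdAPE) as diagnostics.

## Worked example

Simulate a gene under constant demand 50 with decreasing (type-B) survival
and unit activity, and measure its oscillation:

```python
import ageflux as af

profile = af.make_profile("B", "A")           # 11 ages, survival ladder
traj = af.simulate(profile, af.PulsePolicy(100.0),
                   af.ConstantDemand(50.0), horizon=100)
report = af.detect_cycles(traj)
print(report.period, report.amplitude)        # -> 5 84.0
print(traj.tb[-5:])                           # -> [115. 96. 72. 50. 31.]
```

The pool cycles every 5 ages: one pulse of 100 decays down the survival
ladder until total activity drops below 50, which triggers the next pulse.

Fit a synthetic "experiment" (14 observations, 5 minutes apart) generated
by the model itself and recover its parameters:

```python
import numpy as np
from ageflux.fitting import FitSpec

series, truth = af.generate_series(af.SyntheticSeriesSpec(
    survival=np.array([0.9, 0.9, 0.5, 0.0]), pulse_level=1.4,
    demand=2.0, horizon=14, step_length=5.0))
fit = af.fit_exhaustive(series, FitSpec(
    lifespans=[10.0, 20.0, 30.0], survival_grids=[[0.3, 0.5, 0.9]] * 3,
    pulse_grid=[0.7, 1.4, 2.1], demand_grid=[1.0, 2.0, 3.0],
    initial_patterns=np.zeros((1, 5)), refine_pulse=False))
print(fit.lifespan, fit.pulse_level, fit.survival_rates, fit.demand)
# -> 20.0 1.4 (0.9, 0.9, 0.5) 2.0
print(fit.accumulated_transcription, fit.accumulated_degradation)
# -> 11.2 8.54
```

The fit recovers the generating lifespan (20 min), pulse level, per-age
survival rates and demand exactly (SSE 0), and reports the accumulated
transcription/degradation over the experiment; dividing by the 70-minute
duration gives the net rates (0.16 and 0.122 units/min here, via
`af.metabolic_report`).

The same operations are available from the shell:

```
ageflux simulate --config sim.yaml --out traj.csv
ageflux analyze  --traj traj.csv
ageflux fit      --series series.csv --organism yeast --out fit
ageflux label    --config label.yaml --out groups.csv
ageflux generate --spec gen.yaml --out series.csv
ageflux simulate-coupled --config coupled.yaml --out-prefix run
```

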