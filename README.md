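# adaptkit

Inference of time-varying parameter trajectories in kinetic metabolic
models from sparse phenotype-snapshot data (the ADAPT approach: Analysis
of Dynamic Adaptations in Parameter Trajectories).

## The problem

In preclinical and clinical studies a progressive disease or a therapeutic
intervention is phenotyped at a handful of stages — say, a fasting
metabolic profile once per day — while the underlying regulation by the
transcriptome and proteome changes slowly over days and is not measured.
A kinetic model of the metabolic network,

```
dx/dt = N f(x, θ, u),      y = C x,
```

with stoichiometric matrix `N`, rate laws `f`, parameters `θ`, input
fluxes `u` and observation map `C`, captures the fast (seconds-scale)
biochemistry but treats `θ` as constant. ADAPT links the snapshot stages
by letting the parameters evolve, `θ = θ(t)`, and inferring trajectories
`θ̂(t)` that carry the model from one phenotype to the next. The parameter
trajectories act as coarse-grained stand-ins for the unmodelled slow
regulation.

The estimator advances on a grid with step `δt`, simulating the model over
each step with candidate parameters held constant and solving

```
θ̂(t+δt) = argmin  X_d + λ_r X_r
X_d = (1/N) Σ_n ((y_n − d_n(t+δt)) / σ_n(t+δt))²
X_r = (1/M) Σ_m ((θ_m(t+δt) − θ_m(t)) / (θ_ref,m δt))²
```

where `d(t)` is a continuous description of the data — a cubic smoothing
spline through a parametric-bootstrap replicate of the snapshot means —
and `σ(t)` its interpolated uncertainty. The squared-derivative penalty
`X_r` (weight `λ_r`) suppresses unphysiological parameter fluctuation.
Repeating the whole procedure `nr` times with fresh bootstrap interpolants
and log-uniform random initial parameter draws (Monte-Carlo multiple
minimization) gives a trajectory ensemble; replicates whose cumulative SSE
exceeds `sseThres` are discarded. The result is a distribution of
parameter, state and flux trajectories reflecting measurement uncertainty
and model error.

The package ships a fully executable case study: a five-state toy system
(metabolites S1–S4 plus a regulator mRNA R1) whose first reaction is
inhibited by the product of an S4-activated gene. A staged decline of the
transcription rate constant `k6` creates five phenotypes; three analyses
of increasing sophistication (re-estimate `k6` per stage; per-stage
Monte-Carlo estimates of a lumped `k1`; the full time-varying `k1(t)`
trajectory) can be run and compared against the generator's ground truth.

## Worked example

```python
import numpy as np
from adaptkit import AdaptConfig, NoiseConfig, generate_snapshots
from adaptkit import case_study

system = case_study.build_true_system()
schedule = case_study.intervention_schedule()      # k6: 0.01 ... 0.000625
dataset, truth = generate_snapshots(system, schedule,
                                    NoiseConfig(max_rel_sd=0.0), rng=1)

ensemble = case_study.run_case3(dataset, AdaptConfig(nr=50, seed=101))
print(f"accepted {len(ensemble.accepted)}/{len(ensemble)}")

k1_true = np.array([case_study.lumped_k1(v) for v in schedule.values])
k1_med = np.median(ensemble.parameter_matrix("k1"), axis=0)
cols = [int(round(t / ensemble.config.dt)) for t in dataset.stage_times]
for t, est, tru in zip(dataset.stage_times, k1_med[cols], k1_true):
    print(f"day {t:.0f}:  k1_hat = {est:.5f}   k1_true = {tru:.5f}")
```

prints

```
accepted 50/50
day 0:  k1_hat = 0.00371   k1_true = 0.00386
day 1:  k1_hat = 0.00682   k1_true = 0.00674
day 2:  k1_hat = 0.01155   k1_true = 0.01144
day 3:  k1_hat = 0.01920   k1_true = 0.01906
day 4:  k1_hat = 0.03112   k1_true = 0.03152
```

All 50 replicates are accepted and the ensemble median of the lumped
rate constant `k1(t)` tracks the truth-implied value (Vmax scaled by the
stage's inhibition level) within a few percent at every stage time; the
residual offset at day 0 is the smoothing bias of the data interpolant.

The same pipeline is available from the shell:

```
adaptkit generate --noise 0.1 --seed 3 --out data/
adaptkit run --case 3 --dataset data/dataset.csv --nr 100 --out run/
adaptkit sweep --dataset data/dataset.csv --lambdas 0,0.1,100,1e6
adaptkit pulse
```

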