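# sddetwin

Stochastic delay differential equation (SDDE) simulation of inflammatory
biomarker cascades, for exploring how *delayed* physiological responses
structure cardiovascular risk in virtual cohorts.

Inflammatory responses are neither instantaneous nor deterministic: a
stressor activates neutrophils within hours, C-reactive protein (CRP)
rises with an intermediate lag, and albumin — a negative acute-phase
protein — falls and recovers on a slower time scale. `sddetwin` models
this cascade as a four-variable SDDE and uses it as a conceptual digital
twin: many virtual subjects experience the identical stressor, and the
interplay of lags and multiplicative noise alone generates heterogeneous
latent risk trajectories.

## Model

State variables: neutrophils B1, CRP B2, albumin B3 and a latent
cardio-inflammatory output Y, driven by a rectangular stressor pulse S(t):

    dB1 = [α₁ S(t−τ₁) − α₂ B1(t−τ₂)] dt + σ₁ B1(t−τ₂) dW₁
    dB2 = [γ₁ B1(t−τ₃) − γ₂ B2(t−τ₄)] dt + σ₂ B2(t−τ₄) dW₂
    dB3 = [θ₁ − θ₂ B2(t−τ₅) − θ₃ B3(t−τ₆)] dt + σ₃ B3(t−τ₆) dW₃
    dY  = [β₁ B2(t−τ₇) − β₂ B3(t−τ₈) − β₃ Y(t−τ₉)] dt + σ₄ Y(t−τ₉) dW₄

Noise is multiplicative in a *delayed* state (fluctuations carry a memory
of where the system was), integrated with an Euler–Maruyama scheme using
discrete-index delayed lookups and a constant pre-history. Time is in
abstract units. For each subject the package records max Y, the time Y
first peaks (`time_to_peak_y`), and a binary cardiovascular event label
`event_cv` defined by threshold exceedance of max Y, with the threshold
calibrated empirically so that exactly 20% of a cohort are events
(nominal cutoff 1.5 on the normalized Y scale).

Also included: the two-variable stimulus→biomarker→output SDDE, the three
robustness analyses (event prevalence 15/20/30%, Gaussian outcome noise
at the event-definition stage, 10%-CV interindividual parameter
heterogeneity), rank-sum / ROC / separation diagnostics, Kaplan–Meier and
log-rank survival machinery with tertile stratification, and the
cross-sectional delay-proxy ratios

    τ_composite = CRP / (neutrophils + 1),   Δratio = CRP / albumin

for single-timepoint biomarker tables.

## Worked example

```python
import numpy as np
from sddetwin import build_cohort, default_parameters, mann_whitney_u, roc_auc

params = default_parameters("reference")          # version-pinned preset
cohort = build_cohort(params, n_subjects=100, prevalence=0.20, master_seed=0)

tpk = np.array([m.time_to_peak_y for m in cohort.metrics])
ev = np.array([m.event_cv for m in cohort.metrics])
print(f"events: {cohort.n_events}, raw threshold: {cohort.threshold:.2f}")
print(f"mean time-to-peak  events: {tpk[ev == 1].mean():.1f}")
print(f"mean time-to-peak  others: {tpk[ev == 0].mean():.1f}")
print(f"rank-sum p: {mann_whitney_u(tpk[ev==1], tpk[ev==0]).p_value:.2e}")
print(f"AUC of time-to-peak: {roc_auc(tpk, ev):.3f}")
```

prints

```
events: 20, raw threshold: 3.00
mean time-to-peak  events: 33.1
mean time-to-peak  others: 30.0
rank-sum p: 5.93e-12
AUC of time-to-peak: 0.999
```

Twenty virtual subjects cross the calibrated event threshold; they peak
systematically later than event-free subjects, the rank-sum test
separates the groups decisively, and within this idealized cohort the
delay feature is an almost perfect discriminator — the hallmark
(near-complete stratification) that disappears once outcome noise and
parameter heterogeneity are switched on (see `run_sensitivity_suite`).

A command-line interface mirrors the library:

```bash
sddetwin simulate --seed 42 --out run/          # metrics.csv + provenance
sddetwin sensitivity --seed 42 --out run/       # three robustness analyses
sddetwin km --input run/metrics.csv --out run/  # tertile survival curves
sddetwin proxies --input panel.csv --output panel_ratios.csv
```

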