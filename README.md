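# latkin

Kinetic analysis of single-molecule pMHC:TCR binding events and the LAT
condensates they trigger.

T cells discriminate antigen by the binding kinetics of peptide-MHC (pMHC) to
the T cell receptor (TCR). At low antigen density, each binding event is a
spatially isolated single-molecule experiment: the complex dwells for an
exponentially distributed time τ, and with some probability nucleates a
discrete LAT condensate — a self-limiting, two-dimensional cluster of
hundreds of LAT scaffold molecules — after a long stochastic delay. `latkin`
implements the analysis chain that turns tables of such events into
quantitative antigen-discrimination kinetics:

* **Photobleach-corrected dwell kinetics.** Observed dwells end by unbinding
  or by dye bleaching, so the observed marginal is exponential with rate
  k_obs = k_off + k_bleach. The bleach rate is fit from immobilized-spot
  survival series and subtracted to recover the true off-rate; the chance a
  disappearance was a bleach is k_bleach/(k_bleach + k_off). A pseudo
  per-cell on-rate k_on^cell = N / (σ_L (1 − e^{−k_b t})/k_b) converts event
  counts into a binding frequency per unit ligand density.
* **The single-TCR discrimination function.** Events are binned by dwell
  (linearly widening bins), the productive fraction per bin gives
  P(τ) — the probability that a binding event of dwell τ produced a
  condensate — and a weighted fit of
  `P(t) = A · P_reg(N, λt)` (amplitude × regularized lower incomplete gamma)
  summarizes it by its plateau A, effective step number N, step rate λ, and
  half-maximum time.
* **Nucleation propensity and kinetic proofreading.** The hazard
  `k_c(t) = Ṗ(t) / (1 − P(t))` is the momentary nucleation rate of a
  still-engaged, still-silent receptor. Its early rise is compared with
  N-step proofreading chains, whose equal-rate hazard is
  `λ^N t^{N−1} e^{−λt} / (Γ(N) − Γ_N(λt))`; the late decline seen in data is
  *not* producible by any simple chain and is excluded from the fit window.
* **Ligand potency.** Mixing P(t) over a ligand's dwell density gives the
  a-priori success probability `p(k_off) = ∫ k_off e^{−k_off t} P(t) dt =
  A (λ/(λ+k_off))^N`; an exact Gillespie simulation of the cell–bilayer
  contact (binding, rebinding, occupancy sequestration, diffusive
  replenishment) predicts binding-event counts, and the empirical surplus
  ratio compares observed condensate counts against events × p.
* **Copy-number calibration.** Cluster intensities are converted to LAT
  molecule counts via single-fluorophore intensities with acquisition-factor
  normalization, the endogenous/exogenous expression ratio, and a
  zero-intercept expression–size regression; plus detection-limit arithmetic,
  FRAP recovery fits, and NFAT translocation timing.
* **Synthetic data.** A first-class generator produces event tables, bleach
  series, LAT pulse traces, and FRAP/NFAT fixtures with exactly the
  statistical structure above, so the whole chain is testable end to end.

## Worked example

```python
import numpy as np
from latkin import (EventGenConfig, SuccessModel, SuccessProbabilityModel,
                    apriori_success, extract_propensity, fit_kpr,
                    fit_observed_dwell, generate_event_table)

# ground truth: 0.25 plateau, 2 effective steps, 24 s half-max
truth = SuccessModel.from_half_max(0.25, 2.0, 24.0)
cfg = EventGenConfig(k_off=1/23.8, k_bleach=0.0, plat_model=truth,
                     n_events=1071, t_resolution=2.0, seed=0)
events = generate_event_table(cfg)

print(fit_observed_dwell(events).summary())
fit = SuccessProbabilityModel.from_events(events).fit()
print(fit.summary())
kpr = fit_kpr(extract_propensity(fit.model, np.arange(0.0, 60.0, 0.5)))
print(kpr.summary())
print(f"a-priori success of a 6 s ligand: {apriori_success(1/6, fit.model):.3f}")
```

prints

```
Exponential dwell fit
----------------------------------------
events                1071  (0 right-censored)
rate (1/s)         0.03695  +/- 0.00113
mean dwell (s)       27.06  +/- 0.83

Success-probability fit: P(t) = A * P_reg(N, lambda t)
------------------------------------------------------
bins used                 12
events                  1071
amplitude             0.2714  +/- 0.0788
shape                 2.3091  +/- 0.9442
rate                  0.0639  +/- 0.0479
t_half_max (s)         31.10  +/- 10.36

Kinetic-proofreading fit: k_c(t) on [0, 13.0] s
------------------------------------------------
steps N            2.021  +/- 0.018
rate (1/s)        0.0238  +/- 0.0005
points                27
resid norm     0.0004516

a-priori success of a 6 s ligand: 0.014
```

The observed mean dwell (27.1 s) sits above the generative 23.8 s because the
2-s frame interval rounds dwells up and drops sub-frame events (use
`t_resolution=0` for continuous dwells). The discrimination-function
parameters recover the truth within their standard errors — which are large:
at ~1000 events only ~100 are productive, and the plateau, step number and
rate trade off strongly (see `docs/methods.md`). The proofreading fit then
summarizes the early rise of the fitted hazard, and the a-priori success of a
6 s-dwell ligand comes out near the 0.022 obtained from the reference curve.

A shell interface wraps the same stages:

```sh
latkin simulate-events --seed 1 --out events.csv
latkin fit-dwell events.csv
latkin success-curve events.csv --out curve.csv
latkin propensity curve.csv --out kc.csv
latkin kpr-fit kc.csv
latkin report --seed 1 --out run/          # full pipeline + report.md
```

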