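# Methods

This note records the models implemented in `latkin`, their assumptions, the
defaults and why, the numerical choices, and what the synthetic-data tests do
and do not demonstrate about real microscopy data.

## Dwell-time model

Each tracked pMHC:TCR complex is assumed to unbind at a constant rate
`k_off` while its dye bleaches independently at `k_bleach`; the observed
dwell is the minimum of the two exponentials, so the observed marginal is
exponential with `k_obs = k_off + k_bleach` and the probability that a given
disappearance was a bleach is `k_bleach / (k_bleach + k_off)`.

* The default dwell estimator is the censored-exponential MLE
  (`rate = uncensored events / total observed time`): tracks cut by the end
  of an acquisition enter as right-censored lower bounds rather than being
  discarded, which removes the downward bias that dropping them introduces.
  A `drop_censored` flag reproduces a fully-observed-tracks-only analysis,
  and a binned log-linear least-squares fit (Poisson-weighted so sparse tail
  bins do not dominate) is available as `fit(method="binned")`.
* The reported standard error of the mean dwell is `mean/√n`, the exact SE of
  an exponential sample mean.
* Bleach rates are fit by log-linear least squares on the nonzero
  surviving-spot counts of at most the first 150 frames; decay dynamics
  drift at longer times (uneven illumination), and typical acquisitions are
  no longer anyway. The per-path OLS standard error is conditional on the
  realized thinning path and understates across-realization scatter — the
  tests therefore validate recovery with an across-realization SEM.
* `correct_dwell` refuses to subtract when `k_obs ≤ k_bleach`: in that regime
  essentially every disappearance is a bleach and the off-rate is not
  identifiable from the data.
* The pseudo per-cell on-rate uses the effective exposure
  `σ_L (1 − e^{−k_b t})/k_b`, evaluated with `expm1` so the `k_b → 0` limit
  `N/(σ_L t)` is reached continuously (relative error < 1e−6 at
  `k_b = 1e−9`).

## The discrimination function P(τ) and its hazard

`P(τ)` is the probability that a binding event of dwell `τ` nucleates a LAT
condensate at any point during its observed lifetime. Because each event
contributes a Bernoulli outcome conditioned on its own dwell, the binned
estimate `p̂ = n_productive/n_total` is a calibrated probability regardless
of how the dwell marginal samples the bins.

* **Bins.** Widths grow linearly (default 4 s first width, +2 s increments)
  so rare long-dwelling events still land in usable bins. The geometry is
  configurable; the defaults roughly match a 2-s-resolved acquisition with
  ~10^3 events. Empty bins are flagged (`p̂ = NaN`) and excluded from fits,
  never imputed.
* **Parametric form.** `P(t) = A · P_reg(N, λt)` with plateau `0 < A ≤ 1`,
  shape `N ≥ 1` (real-valued) and rate `λ > 0`. The half-maximum time is
  `gammaincinv(N, 1/2)/λ` (for N = 2, `1.6783/λ`).
* **Fitting.** Weighted least squares against binomial SEs. Bins with
  `p̂ ∈ {0, 1}` have a zero plug-in SE, so *fit weights* use the shrunk
  estimate `p̃ = (k + 1/2)/(n + 1)`; reported curve SEs remain the plain
  `√(p̂(1−p̂)/n)`. The plateau is initialized at the last populated bin, the
  shape at 2 (the value the proofreading comparison favors), and the rate
  from the first bin exceeding half the initial plateau. The half-max SE is
  a delta-method propagation over (N, λ).
* **Identifiability.** At ~1000 events with a 24 s half-max and ~0.04 s⁻¹
  observed dwell rate, only ~10% of events are productive and (A, N, λ) are
  strongly correlated. The binomial Cramér–Rao bound at this design gives
  relative SEs of roughly 20% (A), 32% (N), 58% (λ) and 26% (t_half); the
  implemented estimator attains approximately this bound. Per-parameter
  precisions much better than these at this ensemble size are not supported
  by the information content of the data, whatever the fitting procedure.
* **Hazard.** `k_c(t) = Ṗ/(1−P)` is computed analytically for the parametric
  model (in log space when A = 1, where it coincides with the gamma hazard).
  For empirical curves the derivative of a noisy binned `p̂` is hopeless by
  finite differences, so a cubic smoothing spline with inverse-SE weights is
  used, its smoothing factor chosen by leave-one-out cross-validation over a
  coarse grid around the nominal `s ≈ n_bins`; the curve is anchored at
  `P(0) = 0` and the derivative clipped at zero. The probability↔hazard
  round trip `P = 1 − exp(−∫k_c)` is evaluated with per-segment adaptive
  quadrature and closes to better than 1e−6 on [0, 120] s.
* **A-priori ligand success.** `p(k_off) = ∫ k_off e^{−k_off t} P(t) dt`,
  computed after substituting `u = k_off·t` so the integrand is O(1) at any
  off-rate; the closed form `A (λ/(λ+k_off))^N` (the gamma moment-generating
  function, valid for real N) serves as a 1e−8 cross-check.

## Kinetic proofreading

An N-step chain of irreversible first-order transitions has a delay density
equal to the convolution of per-step exponentials; with equal rates this is
the gamma density and its hazard has the closed form
`λ^N t^{N−1} e^{−λt} / (Γ(N) − Γ_N(λt))`.

* The convolution is evaluated on a uniform grid by FFT with trapezoid
  end-point correction and per-step renormalization (each factor has unit
  mass); the grid must resolve the fastest step (`dt ≤ 0.1/max λ`) and
  contain the decayed tail.
* The closed-form hazard is computed as `exp(log pdf − log sf)` and returns
  the asymptote λ where the survival function underflows. It approaches λ
  like `1/(λt)`, which matters when asserting asymptotics.
* The gamma form admits non-integer N; the convolution machinery requires an
  explicit integer chain. Both agree to 1e−6 where both apply.
* Fits restrict to an early window (default first 13 s) because measured
  nucleation propensities decline at later times — a feature no simple chain
  reproduces — and use inverse-variance weights when the empirical curve
  carries SEs, uniform weights otherwise. N is fit as a real parameter.

## Contact-zone Gillespie simulation

The simulation estimates how many binding events occur at a cell–bilayer
contact over an acquisition, accounting for rebinding, occupancy
sequestration, and diffusive replenishment.

* Geometry: a disk of 80 μm² (a typical T-cell footprint; configurable).
  The local free-ligand pool (initially `σ_L × area`) exchanges with an
  infinite bulk at `k_ex = 4D/r²` — the diffusive relaxation rate of the
  disk — implemented as constant influx `k_ex σ_L A` and per-molecule efflux
  `k_ex`. With `D = 0.55 μm²/s` and 80 μm², `k_ex ≈ 0.086 s⁻¹`.
* Reactions: binding at `k_on_cell × (free/area)`, unbinding at `k_off × bound`
  (the ligand returns to the local pool; rebinding allowed), influx, efflux.
  Exact direct-method SSA; event counts are small, so tau-leaping would gain
  nothing. `D = ∞` short-circuits to the Poisson limit
  `k_on_cell σ_L T` (the 380-event no-depletion baseline at
  `k_on = 3.8 μm²/s, σ_L = 0.5 μm⁻², T = 200 s`).
* Depletion is transient: while occupancy builds toward its steady state the
  free pool dips below bulk, so slow-off ligands (44 s dwell) accumulate a
  few percent fewer events than fast-off ones (10.8 s). Mean-field ODE
  values are ≈337 and ≈369 events; the reference values (355/375) sit
  within the ±10% band that the choice of replenishment scheme implies.
  The exchange constant was fixed a priori from the disk geometry, not
  adjusted to the targets.
* Bleaching is tracked as a per-event visibility label drawn with
  probability `k_off/(k_off + k_bleach)` (the chance the dye outlives the
  dwell), unconditionally, so turning bleaching on never perturbs the
  binding trajectory at a fixed seed. Condensate-based counts use all
  events; a visible-only count supports dye-channel comparisons.

## Quantitative fluorescence

* Cluster intensity is the midpoint `½(C_total + C_net)` of the
  annulus-corrected net and total intensities, bracketing the unknown
  background participation; copy number divides by the single-fluorophore
  intensity after normalizing both by gain × power × exposure. Linearity of
  those factors is an assumption of the instrument, stated as a
  precondition. Total copy number scales by `(1 + α)` with α the
  endogenous/exogenous expression ratio (default 0.60).
* Relative size expresses a cluster in μm²-equivalents of local background;
  multiplying by a physiological membrane density (default 601 μm⁻²) gives
  an expression-independent molecule count (0.43 × 601 ≈ 258).
* The detection-limit chain (SNR defined over an annulus from the spot
  radius to twice the spot radius) reports background equivalents,
  detectable excess, the fluorescent bound, and the total bound
  `(1 + endo/exo)` — for the reference inputs: 5, 7, 12 and 24. The last is
  conventionally quoted as "≈20"; the exact value is returned.
* FRAP recovery is fit as a single exponential toward a plateau under a
  reaction-limited assumption, making the rate a lower bound on the off-rate
  within the structure; a plateau below full recovery reports the immobile
  fraction, and traces spanning fewer than three recovery half-lives or
  showing no recovery are rejected.
* NFAT translocation time is the first sample where the mean nuclear
  intensity strictly exceeds the cytosolic one; `None` if never.

## Synthetic-data generator

The generator inverts the analysis' own model: dwells are competing
exponentials; condensation is drawn by thinning the model hazard on a 0.1 s
grid with exact-to-grid step probabilities
`(P(t_{k+1}) − P(t_k))/(1 − P(t_k))`, only while the complex is observably
bound — so a nucleation that would occur after a bleach-censored end is
recorded as non-productive, exactly as it would be unobservable in imaging.
Frame discretization (default 2 s) rounds dwells up to the next frame and
drops sub-frame events, mirroring time-lapse sampling; `t_resolution = 0`
yields continuous dwells for distributional tests (a discretized marginal
cannot and should not pass a continuous-exponential KS test). LAT pulses are
amplitude-normalized gamma shapes; the defaults (shape 3, scale 4.65 s, peak
258 molecules) put the peak 9.3 s after onset with a ~30–40 s footprint —
the rise time and copy number are measured quantities, the gamma shape
itself is illustrative. Bleach series are per-frame binomial thinnings.

What passing tests on these fixtures shows: the estimators are consistent
against their own generative assumptions at realistic ensemble sizes
(1071 events, ~10² delays, 10²–10³ spots). What they do not show: robustness
to tracking errors, non-exponential dwell mixtures, spatial heterogeneity,
drift in imaging conditions, or condensate mis-assignment — none of which
the generator emulates.

## Problem sizes and determinism

Default analysis scales are the ones above: 1071-event ensembles, 250
Gillespie replicates over 200 s, 200-replicate recovery studies; all complete
in seconds on one CPU. Every stochastic component takes a seed or a
`numpy.random.Generator`; the pipeline spawns per-stage child seeds from a
single configured seed, and reruns are byte-identical.
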