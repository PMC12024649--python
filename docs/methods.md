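# Methods

This note documents the models, estimators and generators implemented in
`gcswitch`: their assumptions, the parameters that matter, the numerical
choices, and what the synthetic-data tests do and do not establish.

## Growth-coupled switch models

All four switch models are deterministic ODE systems in which protein
production is a Hill function of a regulator and every species is diluted
at the specific growth rate λ (1/h), plus an optional first-order molecular
decay δ. Units are hours, µM, and doublings/hour = λ/ln 2 for reporting.
Each model reduces to one scalar balance by placing fast processes
(phospho-transfer, dimerization, inducer import) at quasi-steady state:

* **Autoactivator** — `dx/dt = b + β x^n/(K^n + x^n) − (λ+δ) x`. With
  negligible basal production the loop is a pure growth-rate sensor: off at
  fast growth, bistable at intermediate doubling times, locked on at slow
  growth. The preset (b = 1.75·10⁻⁴, β = 0.28 µM/h, K = 1 µM, n = 2) was
  calibrated so the bistable window spans doubling times of roughly 5–50 h;
  the window's width is set by b/β and its position by β.
* **Protease-coupled switch** — same loop, but total decay is
  `λ + δ + δ_p/(1 + (s/s₀)^h_p)`: the external signal represses a protease.
  At intermediate signal the switch stays bistable out to growth arrest
  because the residual protease activity replaces dilution.
* **Two-component switch** — the operon expresses the TF X and a membrane
  kinase at ratio ρ. Signal activity a(s) = s/(s + k_act) drives
  phosphorylation; the phosphorylated fraction is
  p = a·k_phos·kin/(a·k_phos·kin + k_deph) with kin = ρX, and the promoter
  input is the dimer D = (pX)²/K_D. Because both X and the kinase dilute as
  1/(λ+δ), the bistability-onset signal scales as (λ+δ)² in the unsaturated
  regime. The preset additionally sits in a regime of mild phospho-transfer
  saturation at fast growth (a·k_phos·ρX/k_deph ≈ 0.5 at a 1 h doubling
  time), where the onset drops a full factor ~100 per decade of doubling
  time even with a finite (48 h) molecular half-life; at doubling times
  below ~0.5 h the preset is bistable for arbitrarily strong signal.
* **lac switch** — the scalar state is the transporter (LacY) concentration
  Y. The intracellular inducer is at quasi-steady state,
  `τ = α_imp·Y·c_ext/(λ + δ + k_hyd·Y)` (k_hyd = 0 for gratuitous inducers
  such as TMG), and production is
  `y_prod(λ)·(leak + (1−leak)·τ^n_τ/(τ^n_τ + K_τ^n_τ))`.

### Full-induction regulation modes

`y_prod(λ)` encodes how the operon's maximal output depends on growth rate:

* **constant** — a growth-rate-independent production *rate* y₀ (µM/h); the
  simplest scenario, giving the quadratic critical-inducer law.
* **c_line** — the catabolic growth law: the full-induction steady-state
  *concentration* decreases linearly, y_h(λ) = y₀(1 − λ/λ*) (µM), so the
  production rate is (λ+δ)·y_h(λ). This is the natural reading of the
  measured law (the linear fit of concentration versus growth rate), and it
  is what makes inverse-Monod tracking possible (below).
* **r_line** — translation-inhibition regulation: the full-induction
  concentration rises proportionally to λ (y_h = κλ), production
  (λ+δ)·κλ.

An exponent θ for K_τ ∝ λ^θ is exposed but defaults to 0 in every mode:
under the concentration reading of the growth laws no K_τ rescaling is
needed for either the C-line tracking result or the translation-mode
invariance.

### Exact scaling of the lac threshold

For k_hyd = 0 the reduced steady state depends on the external inducer only
through the dimensionless group `α_imp·y_prod·c / ((λ+δ)²·K_τ)`, so every
saddle-node boundary obeys `c = γ·K_τ·(λ+δ)²/(α_imp·y_prod(λ))` exactly,
with γ depending only on (leak, n_τ). `lac_threshold_relation` computes γ
from the dimensionless balance (cached per (leak, n_τ)) and serves as an
independent cross-check of the numerical boundary scan. Consequences:

* constant production → c* ∝ (λ+δ)²: slope −2 in log c vs log T for
  T ≪ 1/δ, flattening to a δ² plateau for T ≳ 48 h. Over the window
  T ∈ [0.7, 6] h with δ = ln2/48 h⁻¹ the exact exponent is −1.90 (the −2
  limit requires δ → 0).
* c_line → c* ∝ (λ+δ)/(1 − λ/λ*), which for δ → 0 and λ* = λ_max is
  proportional to the inverse Monod curve K_s λ/(λ_max − λ) exactly.
* r_line → c* ∝ (1 + δ/λ)², within a few percent growth-rate independent.

### Numerics

Fixed points are found by a sign-change scan on a 2000-point log grid over
the invariant interval [p_min/decay, p_max/decay] (production is bounded by
the basal and maximal rates, so all roots live there), refined by Brent's
method; stability is the direction of the sign change; roots closer than
10⁻⁶ of the concentration scale are merged as saddle-node points. The ODE
oracle integrates the un-reduced systems (kinase or inducer as a second
dynamical variable; their steady states coincide with the reduced algebra
exactly) with LSODA at rtol 10⁻⁸. Bistability boundaries are located by a
400-point log scan over ±6 decades around the model's natural signal scale
and bisection in log signal to a relative tolerance of 10⁻⁴. The off/on
discriminator for monostable points is the geometric mean of the
promoter-half-max concentration and the maximal attainable concentration.

## Sugar preferences and the C-line calibration

Monod parameters for glucose are solved from two anchors (11.1 mM → 1.06
doublings/h, 2 µM → 0.19 doublings/h), giving K_s = 9.17 µM and
λ_max = 0.735 h⁻¹. For lactose, K_s is set to 100 µM and λ_max solved so
growth on saturating lactose (550 µM) equals growth on 50 µM glucose —
placing the induced/uninduced crossover of glucose–lactose mixtures at
50 µM glucose. This is a calibration of the defaults, not a validation.

`calibrate_cline` minimizes the sup-norm of |log(s_center(λ)/c_inv(λ))|
over a growth-rate grid with Nelder–Mead multi-starts, using the exact
dimensionless threshold relation for speed; tests verify the optimum
against the full numerical boundary scan. The calibration context uses
δ = 0: the optimal-tracking argument holds for molecules whose loss is
dilution-dominated, and a finite 48 h half-life degrades the best
achievable tracking to ~6% at the slow end of the grid (δ/λ ≈ 0.2 at
0.1·λ_max). At the calibrated optimum the pole aligns with λ_max
(λ* = 0.734 h⁻¹) and y₀ ≈ 62 µM; the import-efficiency constant
α = 0.00373 (µM·h)⁻¹ per µM LacY was fixed once so this scale is
physiological (tens of µM at full induction).

`predict_induced_set` implements winner-take-all: an option is
supercritical iff its attainable Monod growth rate strictly exceeds every
alternative's (and the designated current rate); exact ties are returned as
a set, never broken randomly, because the coexistence regime near the
crossover is precisely the tie neighbourhood.

## Bulk fitting

The Hill dose-response is fitted by weighted least squares in log-activity
space over (log b, log f, log k, m), with multi-starts (k initialized at
every observed concentration, m ∈ {1, 2, 4}) and bounds f ≥ 1,
m ∈ [0.2, 10]. Standard errors are asymptotic; the SE of log k is the
relative error of the critical concentration and feeds the slope fit as
σᵢ. Fits with fold change below 1.2 are flagged unidentifiable (k is then
meaningless, since it drops out of the model at f = 1).

The slope fit assumes y_i = a x_i + b plus Gaussian noise of variance
σ² + σᵢ² per point, flat priors on (a, b) and a scale prior dσ/σ. The
intercept is marginalized analytically; the (a, b)-marginal likelihood is
maximized over log σ by bounded scalar search on [10⁻⁴, 10]; the posterior
of a at the optimum is Gaussian with mean B/A and variance 1/A, where A, B
are the weighted centered second moments. Tests validate the posterior
against brute-force 2-D grid integration (10⁻³ agreement) and calibrate
frequentist coverage of the ±2 SD interval (≈95% over 500 simulations).

## Plate-reader pipeline

Background is the mean of a 20-point window centered on the channel
minimum (clipped at the edges), subtracted channel-wise. The growth segment
is found from the OD maximum going backward: the maximal contiguous run
with OD < OD_max/3, OD > 0.01 and positive signal, rejecting runs shorter
than 21 points (a typed rejection, not an exception). Growth rate is the
OLS slope of log₂ OD versus time. Miller activity uses the initial 30-min
OD420 slope (per minute) after discarding an initial decreasing phase of up
to one hour (terminated at the first local minimum), A = 1000·s/(0.5·OD₆₀₀)
with OD₆₀₀ on a 1-cm path; promoter activity is α = A·λ, valid because a
stable enzyme's turnover at balanced growth is dilution. The fluorimetry
estimate slides a 21-point window over the segment, extracting per-window
growth rates and log(signal/OD) ratios, combined by inverse-variance
weighting (overlapping windows are correlated, so the combined SE is an
effective precision, not an exact one).

## Single-cell pipeline

Cell growth rates are log₂-length OLS slopes; cells with fewer than 10
frames are filtered. Induction is classified against 250 molecules; traces
induced for more than 5% but less than 95% of their frames are mixed and
discarded. Instantaneous growth, volumic production (fluorophore increment
per spherocylinder volume per hour) and concentration come from centered
rolling regressions (default 5 frames), strictly per cell — never across a
division. Photobleaching is corrected by c = c_u(1 + β/λ), which for
steady-state production also corrects the observed production rate by the
same factor. Three-cell lineage traces prepend the parent and append the
frame-wise average of the two daughters (truncated at the shorter one).

Switch detection works on natural-log concentration (x) and volumic
production (y) against a common threshold of 5.5: an on-switch moves from
both-below (blue) to both-above (yellow), off-switches mirrored; production
excursions that the concentration never follows are not events; the switch
time is the (interpolated) production crossing. A stable quadrant counts as
reached only after a 0.25 h dwell — crossings too brief for the state to
settle do not qualify. Because one physical switch appears in up to three
overlapping lineage traces, `dedupe_switches` merges same-direction events
of one physical unit within 1.5 h, keeping the latest (the crossing closest
to commitment). The switcher-versus-returner comparison samples each
lineage once per transition quadrant (green = low concentration/high
production, orange = the mirror), groups by fate and applies a Welch
two-sample t test with medians and interquartile ranges reported.

## Synthetic data

All generators are pure functions of (config, seed).

**Plate generator.** OD is a lag followed by clean exponential growth
capped at OD_max; the inoculum OD (10⁻⁵) is small enough that the
background window, which inevitably absorbs it, does not bias growth
slopes above the 0.01 floor. Run length is sized per condition so the
culture saturates (the plate practice of tuning dilution per growth rate).
The reporter channel is OD times the condition's Hill-curve expression at
its inducer concentration, with multiplicative log-normal noise (CV 1% OD,
2% signal).

**Threshold generator.** Critical-concentration replicates are the
numerical bistable centers times log-normal scatter exp(ε),
ε ~ N(0, σ_rep), with σᵢ = σ_rep.

**Lineage generator.** Mother-machine channels on glucose/lactose
mixtures. An Ornstein–Uhlenbeck factor (mean reversion 2 h⁻¹, stationary
CV 0.2 — the simplest stationary positively-autocorrelated choice)
multiplies the attainable growth rate; the cell grows on glucose while
uninduced and on lactose once induced; the C-line lac ODE driven by the
instantaneous λ(t) sets expression, so growth dips raise the intracellular
inducer and trigger on-switches — the growth-coupled switching mechanism
itself, with no separate expression noise. Cells grow exponentially in
length (3-min frames), divide at 5 µm with ~5% asymmetry and binomial
fluorophore partitioning; fluorescence is observed every 9 min with
per-exposure bleaching (fraction 1 − e^(−β_exp), β_exp = 0.02; the
continuous-rate equivalent is β_exp divided by the exposure interval) and
linearly interpolated onto the phase frames — frames past a cell's last
exposure are dropped, since holding the signal constant there would fake a
production crash at every division. The truth sidecar applies the same
quadrant walk (threshold, dwell) to the noise-free latent trajectory of
the mother line and of every sibling branch. Near the crossover the
emergent switching is rare (about one event per 40 lineage-hours),
consistent with the few-percent switching fractions such experiments show.

What these tests establish: that the estimators recover the generating
parameters under the stated noise model, and that detection agrees with a
latent truth defined by the same quadrant semantics. They do not establish
robustness to segmentation errors, realistic microscopy noise, non-Hill
dose responses, or growth-law regimes other than those generated.

## Known limitations

* The two-component and lac preset parameter sets are not constrained by
  measured kinetic constants; they are calibrated qualitative stand-ins and
  absolute signal units are arbitrary.
* The exact exponent of the lac critical curve over a finite doubling-time
  window is slightly shallower than −2 whenever δ > 0; analyses that
  require the asymptotic −2 must fit in the regime T ≪ 1/δ.
* The windowed-regression instantaneous estimates are a deliberately simple
  replacement for Gaussian-process trace inference; their edge windows are
  noisier and production estimates inherit the bleach-sawtooth at the
  exposure cadence.
* Inducer hydrolysis (k_hyd > 0) is supported in the dynamics but the
  closed-form threshold relation and the C-line calibration assume a
  gratuitous inducer.
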