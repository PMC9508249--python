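# Methods

This note documents the model, its parameters, the numerical choices, and
what the synthetic-data generator does and does not emulate.

## Device model

The memristive synapse is modelled phenomenologically as a second-order
system with three state variables: a persistent conductance `G_long`, a
short-term conductance `G_short` that relaxes exponentially (time constant
`tau_short` = 45 ms, so a single-pulse transient has decayed below 5% after
200 ms), and a dimensionless activity trace `u` (time constant `tau_u` =
12 ms) that stands in for the slow redistribution of halogenic vacancies
and facilitates closely spaced pulses. Per rectangular pulse (amplitude V,
width w):

    u  <- u + kappa_u
    dG  = sign(V) * eta * |V| * w * (1 + beta*u) * window(G)

with the linear soft window `(G_max - G)/(G_max - G_min)` for potentiation
and its mirror for depression; `retain_frac` of each update is written to
`G_long`, the rest to `G_short`. Integration is event-driven (closed-form
exponential decay between events), so there is no step-size tolerance.

No device ODE is published for this system; this two-component-plus-trace
form is the minimal second-order model that reproduces, simultaneously,
EPSC relaxation (~200 ms), double-exponential paired-pulse facilitation,
frequency-dependent train responses, and history-dependent plasticity.

**Parameters and calibration.** Conductance window 50–350 µS (so that the
standard history states 100/200/300 µS are interior). `eta_p = eta_d =
2.12544...` and `beta = 0.42360...` are not free: they were solved (once,
offline, Newton root-finding, exactly determined) so that a 10-pulse
0.5 V/5 ms train from G₀ = 100 µS peaks at an EPSC of 76.3 µA with 5 ms
inter-pulse intervals and 62.1 µA with 15 ms intervals — the two anchor
currents of the reference device. `retain_frac = 0.04` was chosen so the
four-train history protocol (100/10/1/10 Hz) yields the sign sequence
(+, −, ≈0, +): at 1 Hz the short-term gain decays fully between pulses and
the small persistent gain is what remains, so a small `retain_frac` keeps
that train's net change inside the ±5% band while leaving the other three
trains clearly signed. One unit note: conductance values quoted as "µs" in
some source material are read as µS (microsiemens) throughout.

**Nonlinearity index.** LTP/LTD staircases are summarized by the standard
one-parameter saturating-exponential convention: with normalized pulse
number p ∈ [0, 1], G(p) = G_start + (G_end − G_start)(1 − e^(−ν·p))/(1 −
e^(−ν)); ν is the nonlinearity (ν→0 linear). The extractor pins the curve
endpoints and fits ν alone (bounded scalar minimization), and is validated
by round-trip only — the exact convention used for the printed reference
indices (3.00 LTP / 3.98 LTD) is not published, so no claim is made beyond
self-consistency of this convention.

**PPF recovery experiment.** The double-exponential PPF decay (fast/slow
amplitudes 50/50%, constants 0.28/10.86 ms) is regenerated on a 20-interval
design spanning 0.1–50 ms with replicates concentrated at 0.1, 0.45 and
3 ms. That design minimizes the Cramér–Rao bound of the fast constant under
2% multiplicative noise; with a generic log-spaced grid the bound is ~7%,
i.e. the fast constant would not be reliably recoverable at the 5% level at
all. The fit weights residuals by the measured value (maximum likelihood
for multiplicative noise). Fits in which the two phases are not separable
(single-exponential input) are flagged, not silently returned.

## Pair and triplet STDP

Triplet STDP uses the detector formulation: presynaptic traces r1, r2
(tau_plus, tau_x) and postsynaptic traces o1, o2 (tau_minus, tau_y); pre
spikes depress by `o1·(A2⁻ + A3⁻·r2⁻)`, post spikes potentiate by
`r1·(A2⁺ + A3⁺·o2⁻)`, where the trace value just before the spike's own
increment is used. Because traces accumulate over the whole spike history,
this is the All-to-All interaction scheme. First-spike-dominating
suppression scales each spike's weight update by `1 − exp(−Δt_prev/tau_supp)`
with Δt_prev the lag to the previous same-side spike (tau_supp = 30 ms;
tau_supp = 0 disables it, recovering exact pair-STDP kernels on single
pairs and the closed-form Poisson expectation).

Time constants default to the canonical triplet-model values for visual
cortex (16.8 / 33.7 / 101 / 125 ms). The kernel amplitudes of the reference
hardware are not published (they live in an unavailable supplement), so the
package ships documented defaults (A2⁺ = 3·10⁻³, A2⁻ = 1.05·10⁻², A3⁺ =
6.2·10⁻³, A3⁻ = 10⁻⁴) chosen to (i) satisfy the threshold-positivity
constraint A2⁻τ₋ > A2⁺τ₊ and (ii) reproduce the qualitative quadrant
structure of triplet experiments: pure potentiation for pre-before-post
triplets, pure depression for post-before-pre triplets, a sign flip in the
'post-pre-post' quadrant as |Δt1| grows past |Δt2|, and no sign crossover
near |Δt1| ≈ |Δt2| for 'pre-post-pre' (the suppression-induced decay keeps
that diagonal depressive). Config overrides are supported everywhere.

Pair STDP with device history adds a decay offset D(G₀, |Δt|) =
gain · (G₀ − G_min)/(G_max − G_min) · (1 − e^(−|Δt|/tau_short)) to the
exponential kernel: the elevated short-term conductance of a high history
state relaxes over the pair interval, which flips long-lag potentiation
into depression at G₀ = 300 µS. The exact functional form of this offset is
a modelling choice (none is published); it is an injectable callable.

**Parameter fitting.** `fit_triplet_params` fits all 8 kernel parameters in
log space (positivity built in) within a ±50× box around the starting
values, minimizing relative residuals — the natural weighting for weight
changes measured with multiplicative error, and the choice that keeps the
weakly identified A3⁻ from escaping to compensatory optima. Datasets
lacking either typical-triplet quadrant, or with fewer than 8 points, are
rejected as underdetermined.

## BCM engine

The rate-based reduction uses the expanded drift polynomial with A3⁻ = 0
and A2± scaled by ⟨ρy²⟩/ρ₀², equivalent to φ(ρy, θ) = A₃⁺τ₊τy·ρy(ρy − θ)
with θ = ⟨ρy²⟩(A2⁻τ₋ − A2⁺τ₊)/(ρ₀²A₃⁺τ₊τy). ⟨ρy²⟩ is estimated by an
exponential moving average. Numerical choices:

* **tau_avg = 5 s.** BCM is stable only if the threshold tracks activity
  faster than the weights move. With a 10 s average the threshold lags:
  at usable learning rates the system enters relaxation-oscillator limit
  cycles (weights slam between the bounds); at rates low enough to avoid
  that, losing orientations fail to end below threshold. 5 s of simulated
  time (25 epochs) gives clean selective fixed points across seeds while
  remaining long relative to a single 200 ms epoch.
* **learning_rate = 0.005** is a global prescale of the drift. It cancels
  out of the threshold formula, so it sets the convergence speed without
  moving any fixed point.
* **rho0 = 32 Hz** sets the scale of the threshold and thereby of the
  steady-state rates. It was chosen so that, given the weight range and the
  30/14 Hz input statistics, the selective equilibrium sits in the
  tens-of-Hz regime with the threshold strictly between the winner and
  loser responses (analytically: the single-stimulus attractor
  ρ_eq = ρ₀²A₃⁺τ₊τy/(A2⁻τ₋ − A2⁺τ₊) ≈ 44 Hz must be reachable by the
  bounded weights).
* Weights are dimensionless conductances G/5 mS (range 0.01–0.07), Euler
  integration with dt = one 200 ms epoch, hard clipping at the bounds
  (mirroring the bounded device window). θ is initialized from one probe
  presentation to avoid the θ = 0 pathology at start.

## Network experiments

**Crossbar ('X') task.** Per epoch, each pixel's Poisson optical train
(30 Hz figure / 14 Hz ground) is transduced into ~1 V pulses driving the
device model; the postsynaptic current I = w₀·ΣG (w₀ = 0.5 V) is converted
to a feedback rate ρy = g·I (g = 50 Hz/mA; nine synapses at 200 µS give
0.9 mA and 45 Hz). During the read window the optical pulses excite only
the transient device state — the persistent weight is changed exclusively
by the BCM update. This reflects the hardware loop, where the feedback
pulses realize the net plasticity rule; letting the read pulses also write
the weight double-counts the drive and, because both channels scale with
ρx, erases the figure/ground separation entirely at equilibrium. Initial
weights are uniform on the bottom 10% of the window. The feedback rate
converges onto the sliding threshold (the BCM fixed point), and since the
cumulative update of synapse i is proportional to ρx_i, figure pixels end
above ground pixels.

**Binocular rearing.** The 9×9 two-eye network uses the reduced rate path:
per 200 ms epoch one of the four bar orientations is drawn uniformly;
realized per-pixel rates are Poisson counts over the epoch (this sampling
noise is what breaks the initial symmetry); ρy = G·ρx_realized; BCM update;
per-orientation probe responses and θ are recorded every epoch. Monocular
deprivation feeds the deprived eye i.i.d. uniform 4–6 Hz noise, redrawn
every epoch by default (a frozen mode is available; the redraw cadence of
the reference experiment is unstated). Scaled-down run lengths are used
throughout: the default 8000 epochs (~27 simulated minutes) is past
convergence for almost all seeds; a small fraction of seeds resolve their
two-way winner competition only by ~12000 epochs, which the winner/loser
tests account for by using convergent run lengths. "One-hour" and
"four-hour" protocols correspond to 18000 and 72000 epochs.

The winner is the argmax steady-state orientation (mean over the final 10%
of epochs) if superthreshold; ties within tolerance are reported as
unresolved. Typical outcomes with default parameters: normal rearing —
unique winner ≈ 55 Hz with θ ≈ 46 Hz, loser responses ≈ 41 Hz, winner-bar
weights saturated in both eyes (eye-map cosine ≈ 1); monocular deprivation
— the open eye still selects an orientation but at a lower rate (≈ 46 Hz),
and the deprived eye's weights stay in the bottom quarter of the range
throughout; binocular deprivation — no orientation ends superthreshold.

## What the synthetic generator does and does not emulate

The stimulus module generates exactly the study conditions: width-1
oriented bars through the grid centre (high 30 Hz / low 14 Hz), the 3×3 'X'
(pixels 1,3,5,7,9 high), 4–6 Hz uniform deprivation noise, homogeneous
Poisson spike trains (exponential inter-arrival sampling, per-pixel child
seeds fanned out deterministically from one root), and a solar-cell
transduction that maps each optical spike to a voltage pulse with a
logarithmic Voc–irradiance curve pinned to 1 V at 100 mW/cm². It does not
model optics, spatial irradiance profiles, solar-cell circuit dynamics,
device-to-device variability, or measurement noise on currents — so
passing tests demonstrate the computational model under idealized,
homogeneous input statistics, not robustness to hardware non-idealities.

## Known limitations

* Kernel amplitudes and the absolute threshold positions (40/60/80 Hz vs
  history state) of the reference hardware depend on unpublished fitted
  parameters; this package asserts the monotone threshold sliding and the
  ordering of steady-state rates (deprived < normal), not those absolute
  values.
* With the EMA threshold estimator, the steady-state fluctuation of θ is
  dominated by the winner/loser response spread and is therefore *larger*
  under normal rearing than under monocular deprivation — the reverse of
  the qualitative report for the reference system, whose estimator details
  are unpublished. The deprivation signature asserted here is the weight
  confinement and the reduced winner rate, not the θ variance ordering.
* The device model has no spontaneous decay of the persistent conductance;
  long-term retention loss and DC I–V hysteresis are out of scope.
* The triplet Monte-Carlo/closed-form equivalence holds in the
  suppression-free limit (tau_supp = 0); with suppression active the
  rate-based drift is an approximation.
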