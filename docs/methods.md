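# Methods

This note documents the models, algorithms and parameter choices behind
`firingclamp`, including the places where the design was genuinely open
and what the synthetic validation does and does not demonstrate.

## Units

One consistent unit system is used everywhere: mV, nS, pA, ms, pF.  It
closes under the membrane equation (nS·mV = pA; pF·mV/ms = pA), so no
conversion factors appear in the code.  All file columns and config keys
carry their unit in the name (`V_mV`, `I_pA`, ...).

## The model neuron

A single-compartment conductance-based cell:

    C_m dV/dt = −G_L (V − V_rest) − g_Na m³h (V − E_Na)
                − (g_K n⁴ + g_AHP w)(V − E_K) + I_inj

with Wang–Buzsáki-type rate functions for m, h, n (temperature factor 5
on h and n), all three shifted +10 mV so that spike threshold sits near
−60 mV, plus a slow sigmoidal adaptation gate w (half-activation
−35 mV, slope 10 mV, τ_w = 100 ms).

Defaults: C_m = 15 pF, G_L = 1.5 nS, V_rest = −77 mV, g_Na = 1200 nS,
g_K = 400 nS, g_AHP = 5 nS, E_Na = +55 mV, E_K = −90 mV.  These were
chosen so that the cell

* rests near −77 mV with input conductance 1.5 nS (a small dissociated
  cell; membrane time constant 10 ms),
* fires exactly one probe spike per 0.81 ms positive pulse of
  0.4–0.6 nA from the −75 mV reset,
* repolarizes through the −400 pA negative phase back to −75 mV within
  ~2 ms, leaving a 2–3 ms zero-current window in each 5 ms cycle.

The kinetic shift is the load-bearing choice: the brief positive pulse
lifts the membrane by only ~25 mV from the reset, so the threshold must
lie near −60 mV for the probe spike to be reliable.  A consequence is a
low rheobase (~15–25 pA) and an unstable steady state near −70 mV:
sustained net depolarization beyond that drives the free-running cell
into repetitive firing.  This bounds the subthreshold operating range of
the method on this cell (see *Calibration domain* below) and is
physiologically sensible — a neuron driven far above rheobase fires,
and the probe-cycle windows then contain spontaneous spikes.

Calcium dynamics are deliberately omitted; the slow gate w stands in for
the calcium- and voltage-dependent potassium currents whose state the
constant-rate probe firing is designed to clamp.

### Integration

Fixed-step integration: exponential (Rush–Larsen) updates for the gates
at the pre-step voltage, forward Euler for V.  The protocol-level
default step is 0.03 ms, one cycle of a 30 µs real-time control loop; a
hard bound dt ≤ 0.05 ms guards gate stability.  The high-level
simulation pipeline (`FiringClampExperiment`) uses dt = 0.01 ms: at
0.03 ms the quantization of the voltage-crossing time makes the probe
cycle alternate between two nearby limit cycles, adding ~0.1 mV of
period-two feature noise; at 0.01 ms that noise is < 0.01 mV.  The
protocol-fidelity checks (cycle counts, pulse durations, reset voltage)
are still exercised at the 0.03 ms default.

## The protocol

Meander defaults follow the procedural description: 200 Hz probe rate,
+600 pA for exactly 0.81 ms, then −400 pA until the first sample with
V ≤ −75 mV (sample-and-hold at the control step), then zero current to
the cycle boundary.  The worked-example preset (400/−300 pA, −80 mV
reset) is available as `FIG1_PRESET`.  A safety cap of 3 ms on the
negative phase prevents lock-up when strong excitation holds the
voltage above the reset; capped cycles are marked.

Cycle QC: a probe spike must exceed −35 mV.  The threshold separates
the shunt-attenuated probe-spike peaks of the default cell (≥ −30 mV
over the calibration domain) from its subthreshold excursions
(< −55 mV); it is configurable, and a 50 nS shunt correctly flags every
cycle as spike-failed rather than silently mis-measuring.

## Probe features

* `V_subthr`: mean of V over the zero-current segment, from 0.5 ms
  after the negative-pulse end to the cycle boundary.  Samples above a
  contamination threshold (−50 mV) are excluded as spontaneous-spike
  contamination; cycles losing more than 30 % of their window are
  flagged.
* `V_pulse`: three operational readings are provided.  The default is
  the **probe-spike peak** (maximum V between pulse onset and the end
  of the negative phase): a maximum is insensitive to spike-timing
  jitter, so it is the most reproducible carrier of the shunt signal
  (−1.7 mV/nS on the default cell, with < 0.1 mV cycle noise at
  dt = 0.01 ms).  The literal pulse-end readings (`"difference"`:
  end-minus-start; `"absolute"`: raw end voltage) are available behind
  the config switch; on this model cell the pulse-end voltage rides the
  steep spike upstroke, whose timing jitters with the input history,
  and the resulting feature dispersion is an order of magnitude larger.
  Because calibration and estimation share one definition, any of the
  three yields a self-consistent estimator.

## Calibration

Sinusoidal I and G are injected through the dynamic-clamp law on top of
the meander, per-cycle means of (I, G) are paired with per-cycle
features, and each surface is fitted by OLS — either the 4-term
bilinear form (both printed example surfaces contain exactly those
terms) or the 6-term full quadratic.

Choices that differ from the in-vitro worked example, made after the
simulated cell exposed two failure modes:

* **Periods.**  40 and 70 ms are both integer multiples of the 5 ms
  probe period, so per-cycle (I, G) means retrace a closed Lissajous
  figure: only 56 distinct points, each always sampled at the same
  within-cycle phase, which both under-covers the plane and phase-locks
  a bias into the fit.  `make_calibration_signals` warns on such
  commensurate choices; the simulation pipeline uses slow detuned
  periods (409.7, 695.3 ms) over 6 s (1200 cycles), which sample the
  plane densely and make each cycle quasi-stationary.
* **Domain.**  The "physiologically meaningful domain" is read as the
  inputs that keep the inter-probe membrane subthreshold on this cell:
  I ∈ [−10, 65] pA, G ∈ [0, 2.8] nS.  Beyond ~70 pA the windows fire
  spontaneously and V_subthr saturates at threshold, carrying no
  further current information.
* **Form.**  The pipeline default is `quadratic6`; the residual RMS on
  the simulated cell is 0.07 mV (subthreshold) and 0.28 mV (pulse),
  versus ~2× larger for the bilinear form whose lack of fit turns into
  regional conductance biases of several tenths of nS.  The bilinear
  form remains the primary closed-form path and is what the printed
  example surfaces use.
* **Warm-up.**  Every run starts from 500 ms of quiescent clamped
  firing: the adaptation gate needs ~3 τ_w to reach its rate-clamped
  level, and features drift by ~1 mV until it does.

Fit diagnostics (coefficient SEs from the OLS covariance, residual RMS,
domain, point count) are carried on the result object; a rank-deficient
design (e.g. all calibration points collinear in the I–G plane) raises
immediately, naming the deficiency.

## Inversion and decomposition

For bilinear surfaces, eliminating I reduces the 2×2 system to one
scalar quadratic in G, solved in closed form with the numerically
stable root pair.  Root selection: roots farther than half a domain
width outside the fitted G-domain are discarded (status `failed`, no
silent extrapolation); among admissible roots, in-domain roots are
preferred; among two in-domain roots the one closer to the previous
cycle's estimate wins (temporal continuity), else the one closer to the
domain centre.  I is back-substituted through the better-conditioned of
the two equations, and the solution is accepted only if both residuals
are < 1e−6 mV.  Quadratic surfaces use a Newton solve seeded by the
previous estimate with the same admissibility rules.

**Epoch alignment.**  V_pulse senses the synaptic state at the probe
spike (~1 ms into the cycle); V_subthr senses the late window (~4 ms).
For inputs that change within a cycle (gamma band) the mismatch leaks a
quadrature copy of the fast excitatory component into the conductance
channel — visible as a 40 Hz artifact in G_I.  Before inversion the
pipeline therefore blends a fraction (default 0.4) of the previous
cycle's V_subthr into the current one, shifting its effective epoch
toward the spike.  The weight trades G-channel leak (favouring ~0.6,
full alignment to the spike epoch) against keeping the current estimate
centred on its own cycle (favouring 0); 0.4 is the fixed compromise.
Weight 0 disables the correction, recovering the plain per-cycle
pairing.  This correction is an addition of this implementation, not
part of the original protocol.

Decomposition and composition are the exact algebraic pair given above;
a per-cycle (time-varying) V_I sequence is accepted, supporting the
slow inhibitory-reversal drift seen under sustained GABA exposure
(the drift's functional form is user-supplied; the generator provides a
linear ramp).  |V_E − V_I| < 1 mV is rejected as ill-conditioned.
Negative conductance estimates are reported, never clipped — clipping
is a display decision, and the sign errors are the visible face of the
estimator's dispersion.

## Synthetic scenarios

The generator realizes, on the control grid: sinusoidal conductance
oscillations (gamma default 40 Hz, theta default 6 Hz), Poisson trains
of instantaneous-rise mono-exponential events, agonist application
steps with exponential edges (τ = 150 ms), additive Gaussian
conductance noise clipped at zero, and a linear V_I ramp.  All
randomness flows from the scenario seed; identical (spec, seed) pairs
are bit-identical.

Canonical scenario amplitudes were fixed once against the default
cell's subthreshold operating range: gamma G_E = 0.4 ± 0.25 nS (total
synaptic current stays ≤ 50 pA), theta G_I = 1.5 ± 1.2 nS, glutamate
step 0.8 nS, GABA step 2.0 nS, and a combined scenario (GABA
0.8 + 2.0 nS with a 0.15 nS glutamate episode inside the GABA window)
whose free-membrane response stays subthreshold so the reconstructed
voltage can be compared with a direct unclamped simulation.  The
cycle-averaged ground truth is exported alongside every run: one value
per 5 ms probe cycle is the best the method can resolve, and estimator
error is measured against that, not the raw waveform.

What the synthetic validation does **not** show: electrode artefacts
(series resistance, imperfect compensation), recording noise on V
itself, cell-to-cell variability in channel complement, NMDA-type
voltage-dependent conductances (excluded by the method's assumptions),
or the biophysics behind the V_I drift.  Passing tests demonstrate the
estimator's internal consistency and its behaviour under the modelled
conditions, not performance on real recordings.

## Reference estimators

* **Continuous current clamp** (multi-trial): with the same scenario
  recorded at K ≥ 2 distinct holding currents, each time point gives K
  linear equations `C_m dV_k/dt = I_hold,k + I − (G_L + G)(V_k −
  V_rest)` in the two unknowns; the least-squares solution is
  decomposed as above.  dV/dt by central differences; points with
  suprathreshold samples or with trial voltages closer than 0.5 mV
  (singular system) are flagged; outputs optionally zero-phase low-pass
  filtered (2nd-order Butterworth, default 50 Hz).  On a noiseless
  passive cell the recovery is exact to < 1 %.  On the active cell the
  holding currents must keep all trials well below threshold (the
  default comparison uses −40 and −80 pA), otherwise subthreshold
  sodium current is misattributed to synaptic conductance — the
  classical limitation the firing clamp was designed to avoid.
* **Pulse probe**: periodic hyperpolarizing pulses (default −50 pA,
  40 ms at 10 Hz); total conductance from the Ohmic steady deflection.
  Its sample rate is bounded by the membrane time constant, hence the
  analytic bandwidth ratio of ~20 versus the 5 ms probe cycle (100 ms
  stationarity window of noise-statistics methods ÷ 5 ms).  On a
  conductance chirp the pulse probe decorrelates from the waveform
  above a few Hz while the firing clamp tracks to ~25 Hz and beyond.

## Numerical choices and degenerate inputs

* Steady state: relaxation for up to 2 s with a derivative-norm
  tolerance of 1e−6 per ms; pathological parameter sets (no stable
  rest) raise rather than returning a spurious state.
* Non-finite state variables abort the run naming the variable.
* Inversion residual tolerance 1e−6 mV; domain margin 0.5 of the
  G-domain width; quadratic discriminant < 0 → `failed`.
* Cycles are never dropped: every cycle carries a QC/status flag
  through features and estimates.
* CSV round trips use 17-significant-digit formatting and round-trip
  float parsing, so written and re-read tables are bit-identical.

## Known limitations

* Per-cycle conductance precision on the default cell is ~0.05–0.1 nS
  (slow inputs) but degrades to ~0.3–0.4 nS RMS for gamma-band inputs —
  the inhibitory estimate is the dispersive one, since it inherits the
  noise of both feature channels.  This mirrors the dispersion the
  method shows on fast time scales generally.
* The usable input range is cell-dependent: strong sustained excitation
  (here ≳ 70 pA) drives spontaneous firing between probes, degrading
  V_subthr; the calibration domain should be matched to the expected
  inputs.
* The estimator assumes voltage-independent synaptic conductances; the
  two-surface inversion cannot separate more than two synaptic
  populations.
* The quadratic surface is an approximation; far outside the
  calibration domain the inversion is refused rather than extrapolated.
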