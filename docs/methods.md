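# Methods

## Model and assumptions

The photocurrent is described by a four-state Markov photocycle
(C1, O1, O2, C2) over occupancy probabilities, with a retinal activation
variable `p` gating the light-driven transitions. The state vector
integrated is `(O1, O2, C2, p)`; C1 is eliminated through the
conservation law `C1 = 1 - O1 - O2 - C2`, so the occupancy simplex is
enforced exactly rather than approximately. Units throughout: time ms,
voltage mV, irradiance mW/mm^2, rates ms^-1; conductance density
mS/cm^2 with Cm = 1 uF/cm^2, so current densities are uA/uF == pA/pF.

Key modelling commitments, and why:

* **Rectification as a smooth product.** The empirical rectification
  function G(V) has a 1/V pole. The current only ever uses the product
  G(V)(V - E); with E = 0 this is the closed form
  `10.6408 - 14.6408 exp(-V/42.7671)`, smooth everywhere including V = 0.
  A consequence of the published coefficients is that the current
  crosses zero near +13.6 mV although the nominal reversal potential is
  0 mV; the formulation is kept as published and the crossing is treated
  as the channel's operational zero-current potential. Setting a
  non-zero `e_rev` reintroduces the pole and is rejected by the
  host-cell coupling.
* **Recovery-rate prefactor.** The recovery rate is
  `Gr(V) = 4.34587e-5 exp(-0.0211539274 V)` ms^-1. A prefactor ten
  orders larger appears in some statements of the model but implies
  sub-microsecond recovery, inconsistent with the seconds-scale S1–S2
  recovery and with Gr ~ 1/tau_R; with the adopted value the simulated
  mono-exponential recovery constant at -80 mV is 4.30 s against
  1/Gr(-80) = 4.24 s. The prefactor is an ordinary config field.
* **Photon flux.** `F = 0.0006 I lambda / w_loss` in ms^-1, the
  coefficient being sigma_ret/(h c) with the unit conversions folded in
  (the package cross-checks the two forms to ~1%).
* **Activation sigmoid.** `theta = 100 I` puts the S0 midpoint at
  0.01 of the lowest experimental irradiance, so `p` saturates near 1
  during any realistic pulse with a 1.3 ms lag; both the mapping and the
  sigmoid constants are configurable but kept as published.
* **Dark state.** The dark fixed point is all-C1 with p = 0. S0(0) is
  ~6e-11 rather than exactly 0, so `dp/dt` at the dark state is zero
  only to that residual — irrelevant at solver tolerances but visible in
  exact-zero assertions.

## Protocols and measure extraction

Protocol runners integrate with a stiff-capable adaptive solver
(LSODA; BDF/Radau selectable), restarting at light-segment boundaries so
irradiance is exactly piecewise constant. Default tolerances are
rtol = atol = 1e-10; output sampling defaults to 0.1 ms (10 kHz, the
rate used for kinetics measurements). Voltage-clamp runs start from the
dark-adapted state; matrix cells are independent (idealising the >10 s
inter-trial rest as a full reset); S1–S2 and pacing runs carry one
continuous state. AP-clamp playback linearly interpolates the sampled
command waveform. Since ChR2 is the only conductance simulated under
clamp, the dark AP-clamp trace is identically zero and the difference
current equals the lit trace; all three are still produced to mirror
the experimental subtraction procedure.

Measures are extracted from median-filtered traces (window 5 samples —
no particular filter width is canonical; 5 is the
smallest width that kills single-sample outliers). Ip is the extremal
current during light, taken at the *first* attainment of 99.9% of the
extremum so plateau-shaped responses get a well-defined peak time. Iss
is the mean over onset+400..450 ms. The three time constants come from
mono-exponential trust-region fits (scipy `trf`, tolerances 1e-12,
tau bounded to [0.01, 1e5] ms, initialised by log-linear regression)
over windows anchored at the peak time: rise over the 10 ms before the
peak, inactivation over 10–110 ms after, deactivation over 500–600 ms
after. One guard was added to the published windows: the rising-fit
window never starts earlier than light-on plus min(2 tau_ChR2, half the
rise time), because the sigmoidal retinal-activation delay is not part
of the opening exponential and, unguarded, breaks the tau_ON-vs-
irradiance monotonicity on simulated traces. tau_R is the interval at
which the spline-interpolated IP2/IP1 curve crosses 1 - 1/e (no
extrapolation: an error if the sampled curve never crosses), with a
mono-exponential fit of the same curve as the secondary readout — the
two differ systematically (the ratio curve starts near 0.5, not 0), and
it is the exponential fit that estimates 1/Gr. Default S1–S2 intervals
are {0.5, 1, 3, 7, 15} s (published only as a 0.5–15 s range).

The ratio convention is IP2/IP1 (second peak over first) throughout.

## Fitting

The objective simulates the protocol grid for a candidate parameter set,
extracts the measures and returns a weighted RMS error; weights default
to 1/|target| per measure so ms- and pA/pF-scale quantities are
commensurable (the original weighting is unstated). Simulation or fit
failures map to a large finite penalty (1e6). The optimiser is
Boltzmann-type simulated annealing — `T_k = T0 / ln(k + e)`, Gaussian
proposals scaled by sqrt(T/T0) and reflected into the box, counter reset
every 50 accepted moves — with the published settings (T0 = 1e5,
objective limit 0, evaluation cap 1e6) as defaults, all configurable;
it is followed by a greedy coordinate pattern search with a halving
step. The annealer is hand-rolled because this reannealing schedule is
not exposed by library global optimisers. All stochastic operations take
explicit seeds; there is no global random state. Full multi-parameter
fits are supported, but the validated use-case is few-parameter
recovery: from targets generated by known parameters, the three rates
(e12_dark, e21_dark, Gd2) started ±30% off are recovered to well under
1% (the identifiability of all seven rates from the five measures alone
is not established).

## Temperature scaling

Each of the seven rates carries a Q10; scaling multiplies whole rate
functions (both Gd1 coefficients, the Gr prefactor, both the dark and
log-irradiance coefficients of e12/e21) by `Q10^((T - T_ref)/10)`, so
the factor applies at every voltage and irradiance, and k1/k2 are scaled
through dedicated multipliers. The shipped Q10 defaults were fixed once
on physical grounds: photon absorption (k1, k2) is athermal, Q10 = 1;
the thermal closures Gd1, Gd2, Gr use 2.3, the middle of the classical
ion-channel gating range; e12 = 1.5 and e21 = 2.5 so that warming
enlarges the sustained fraction Iss/Ip, the experimentally observed
direction. With these, 22 -> 37 C shortens tau_INACT from 16.7 to
8.8 ms, tau_OFF from 10.4 to 3.0 ms, and raises Iss/Ip from 0.51 to
0.68 at 5.5 mW/mm^2, -80 mV. The `fit_rate_q10s` pipeline derives
rate Q10s from observable constraint Q10s (tau_ON, tau_OFF, tau_INACT,
Iss/Ip at two temperatures) by the same annealing machinery; note that
Gr's Q10 is only weakly identified by these four constraints (500 ms
pulse measures barely see the seconds-scale recovery).

## Host cells

The ten Tusscher–Panfilov 2006 human ventricular model (epicardial
default; endo/mid selectable) and the Courtemanche–Ramirez–Nattel 1998
human atrial model are implemented from their original equation sets
with numba-compiled right-hand sides; ChR2 enters the membrane equation
as one more sarcolemmal current density and its four states are
co-integrated with the cell state. The ChR2 flux is not added to the
ionic concentration balances (it is carried mostly by Na+/H+ and is
small next to the currents that drive Nai/Ki dynamics). Validation:
with no light both models hold their published resting potentials to
<0.5 mV over 1 s, and the peak IK1 during optically triggered APs —
1.84 pA/pF ventricular, 0.51 pA/pF atrial — reproduces the reported
cell-type contrast.

The Purkinje rectifier for `swap_ik1` is an instantaneous
Iyer-family formulation,
`IK1 = g (Ko/(Ko+13)) (V-EK) / (2 + exp(1.5 F (V-EK)/RT))`, with
g = 0.266 mS/uF calibrated so the swapped ventricular cell reproduces
the reported 0.32 pA/pF Purkinje peak IK1 under the same 10 ms,
1 mW/mm^2 stimulus (measured: 0.322). The full Purkinje (and other)
hosts stay behind the `CellModel` contract. The threshold-ratio
experiment is sensitive to this formulation's shape as well as its
magnitude: with this calibration the Purkinje-IK1 ventricular threshold
at 100 ms pulses is 17% of native (the reported value is 12%), with the
same strong reduction and the same widening at shorter pulses.

Optical thresholds use the published criterion — V exceeding -20 mV
within 400 ms of light onset — found by deterministic bisection on the
irradiance axis to a 1e-3 relative tolerance under a 10 mW/mm^2 cap.
Thresholds move by <0.5% when solver tolerances are halved. The
`MinimalHost` is a one-variable passive membrane (CRN-form rectifier +
ohmic leak) for fast property tests; being inexcitable it cannot reach
the criterion for very short pulses, so its tests use >=20 ms widths.

## Numerical choices

* Default integration tolerances 1e-10, matching how the model was
  originally integrated. The long
  pacing train (200 beats), threshold bisections and fitting loops run
  at 1e-8: the quantities they produce are peak ratios and bracketed
  roots, insensitive at that tolerance, and the runs fit in seconds to
  minutes on one CPU.
* The pacing driver samples each beat finely (0.05 ms) over the first
  50 ms — the ChR2 current peaks within milliseconds of the pulse — and
  coarsely (1 ms) for the rest of the cycle.
* ICaL's exponential singularity (V = 15 mV) and the removable
  singularities in the atrial gate rates are guarded by their analytic
  limits.
* The photothermal transient is the analytic centre-point solution of
  the heated-sphere diffusion problem, evaluated by adaptive quadrature
  of its closed-form integrand; the saturation Q a^2/(2 k) is exact.
  Defaults: beam radius 0.5 mm (0.78 mm^2 spot), water conductivity
  0.6 W/m/K and diffusivity 1.43e-7 m^2/s, effective medium absorption
  20 m^-1 — an order-of-magnitude estimate for dye-bearing physiological
  saline at 470 nm. The resulting 90 ms rise (0.0024 C) and saturation
  (0.023 C < 0.04 C) support neglecting heating; given the absorption
  coefficient's uncertainty the transient value is an order-of-magnitude
  statement, not a precision prediction.

## Synthetic data

The generator emulates the constraining experiment: the 5 voltage x 4
irradiance pulse matrix (optionally S1–S2 pairs) at 10 kHz with additive
Gaussian white noise scaled to each trace's peak, a seeded generator,
optional baseline offset and a per-trace conductance scale. Ground
truth is extracted from the noiseless traces. What it does *not*
emulate: filtered/1-f amplifier noise, capacitive transients, series
resistance, liquid-junction offsets, or cell-to-cell expression
variability beyond the single conductance scale — so tests passing on
synthetic data validate the pipeline's correctness, not its robustness
to every artifact of real recordings.

## Known limitations

* The four-state scheme cannot reproduce the experimentally observed
  dark pre-conditioning effect (larger peaks after positive-voltage
  pre-conditioning): with Gr falling at depolarized potentials the model
  predicts the opposite direction, which is the known motivation for an
  extended scheme with a dark C1<->C2 equilibrium (out of scope here).
  The pre-conditioning protocol is provided and tested for the standard
  model's direction.
* tau_R from the 0.632 crossing of the raw IP2/IP1 curve differs from
  the exponential-fit constant whenever the short-interval ratio starts
  near 0.5; both are reported.
* No pH or wavelength dependence, no stochastic single-channel gating,
  no tissue-level propagation.
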