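# Methods

## The model

Pathological neural synchrony — the correlate of tremor in essential tremor
and of beta-band LFP power in Parkinson's disease — is modelled as `S`
populations of coupled phase oscillators.  Oscillator `n` of population
`sigma` carries a phase `theta_{sigma n}` (where the unit is in its firing
cycle) and evolves by the stochastic multi-population Kuramoto equation

    d theta_{sigma n} = [ omega_{sigma n}
        + sum_{sigma'} w_{sigma'} k_{sigma sigma'} rho_{sigma'}
              sin(psi_{sigma'} - theta_{sigma n})
        + Vhat_sigma(t) Z_sigma(theta_{sigma n}) ] dt
        + sigma_noise dW_{sigma n},

with local order parameters `rho_sigma e^{i psi_sigma} = <e^{i theta}>` per
population, weights `w_sigma = N_sigma / N`, and the global order parameter
`rho e^{i psi} = sum_sigma w_sigma rho_sigma e^{i psi_sigma}`.  The global
amplitude `rho` is the symptom proxy that stimulation tries to suppress; the
observable signal is `f = rho cos(psi)`.  Noise enters as independent Wiener
increments per oscillator (common noise cannot desynchronise a population).

Natural frequencies are Lorentzian with centre `omega0` and half-width
`gamma`.  That choice makes the infinite-`N` single-population system exactly
reducible (Ott–Antonsen) to one complex ODE for `r = rho e^{i psi}`,

    dr/dt = (i omega0 - gamma) r + (k/2) r (1 - |r|^2) + stimulation term,

whose stimulation term, expanded in the Fourier coefficients of the unit
phase response curve (uPRC) `Z(theta) = a0/2 + sum a_m cos(m theta) + b_m
sin(m theta)`, yields closed-form amplitude and phase response curves.  The
reduction is used as an analytic oracle for the finite-`N` integrator, and as
the source of the controller law.

## Response theory and the controllers

Truncating at the first harmonic, the instantaneous change of the global
amplitude under stimulation decomposes per population as
`d rho_stim/dt = (1/2) sum_sigma w_sigma Vhat_sigma Gamma_sigma` with

    Gamma_sigma = [a1 sin psi - b1 cos psi]
                  - rho_sigma a0 sin(psi_sigma - psi)
                  - rho_sigma^2 [a1 sin(2 psi_sigma - psi)
                                 - b1 cos(2 psi_sigma - psi)].

The first term depends only on the global phase; the `a0`-bearing local term
is what multi-contact closed-loop control can exploit and phase-locked
stimulation cannot.  It vanishes identically when all populations receive the
same intensity, or when each contact's transfer coefficients do not
discriminate between populations — hence utility requires focal geometry
(small configuration parameter `eta`), a type-I uPRC (large `|a0|`), and
inter-population phase dispersion (clustering, i.e. large local amplitudes).

Stimulation reaches population `sigma` through the inverse-distance transfer
matrix `d~_{sigma l} = kappa_e / |p_l - p^_sigma|` (point-source contacts and
populations in a homogeneous isotropic medium).  The controllers are:

* **ACD** — each step, contact `l` fires at `I_max` iff
  `sum_sigma d~_{sigma l} w_sigma Gamma_sigma < 0`; this is the exact
  minimiser of the linear per-step objective over `[0, I_max]^L` (greedy in
  time).  Zero coefficient means no stimulation (energy-conservative
  tie-break).
* **PL** — all contacts fire when `a1 sin psi - b1 cos psi < 0`; the law
  cannot distinguish contacts, so they fire together.
* **CR** — open-loop bursts (13 pulses at 130 Hz over 0.1 s, one burst per
  oscillation cycle at 3.92 Hz), time-shifted across contacts by
  `2 pi (l-1) / (omega_bar L)`.

A pulse is one integration step at amplitude `I_l`; no biphasic waveform
(instantaneous-effect model).  `I_max` is set from the per-step phase-kick
budget: `I_max = delta_theta_max / (max_sigma sum_l d~_{sigma l} dt)`, so
`delta_theta_max` is the intensity unit that makes strategies comparable
across geometries.

ACD and PL are rate-capped per contact by a refractory interval `1/f_max`.
Pulses live on the integration grid, so the interval is rounded to the
nearest whole number of steps (3 steps = 7.5 ms at `f_max` = 130 Hz with
`dt` = 2.5 ms); rounding down instead would silently cap the rate at 100 Hz,
far from the configured value.

## Tunable parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| `omega0 / 2 pi` | 3.92 | Hz | centre of the natural-frequency distribution (tremor line) |
| `gamma / 2 pi` | 0.15 | Hz | Lorentzian half-width |
| `k_diag` | 55 | 1/s | intrapopulation coupling (clustering strength) |
| `k_offdiag` | 0 | 1/s | interpopulation coupling |
| `sigma_noise` | 0.1 * omega0 | rad/sqrt(s) | phase-noise amplitude |
| `S`, `N_sigma` | 3, 600 | — | populations, oscillators per population |
| `L` | 3 | — | electrode contacts (collinear on the lead axis) |
| `a0_mean`, `s_a` | 2, 0 | — | uPRC vertical shift, its spread across populations |
| `a1`, `b1` | 0, -1 | — | first uPRC harmonic (`Z = a0/2 - sin theta`) |
| `delta_theta_max` | 0.001 pi | rad | per-step single-oscillator phase-kick budget |
| `f_max` | 130 | Hz | per-contact pulse-rate cap (ACD/PL) |
| `f_burst`, `f_train`, `t_burst` | 3.92, 130, 0.1 | Hz, Hz, s | CR schedule |
| `T`, `t_start`, `t_avg` | 15, 5, 10 | s | trial length, stimulation onset, averaging onset |
| `dt` | 0.0025 | s | Euler–Maruyama step |
| `eta` | 0.1 | — | configuration parameter of generated geometries |

## Geometry generation

The nucleus is a unit-radius sphere with the `L` contacts equally spaced on a
line through its centre.  For a target `eta`, population positions
interpolate between focal anchors (each population 0.051 radii off a distinct
contact, giving `eta ~ 0.1`) and a randomly oriented ring of common height
around the lead axis plus a small jitter (every contact then sees all
populations at nearly equal distances, `eta ~ 0.95`).  The interpolation
coefficient is rejection-sampled until `|eta - target| <= 0.02`.  A plain
uniform draw inside the sphere was rejected as the delocalised anchor because
it cannot exceed `eta ~ 0.6` for three populations, while the benchmarks
sweep `eta` up to 0.8.  `epsilon_min = 0.05` radii bounds every
contact–population distance away from the 1/r singularity.

## Numerical scheme and the trial engine

Integration is fixed-step Euler–Maruyama at `dt = 2.5` ms; the coupling term
uses the mean-field form (local order parameters computed once per step),
which is algebraically identical to the pairwise sums — a test asserts this
against an explicit double loop.  Phases are wrapped to `[0, 2 pi)` each step
for hygiene only.

The benchmark harness advances whole batches of trials in lock-step with
array operations.  Per-trial randomness (geometry, frequencies, initial
phases, uPRC draws) derives from the master seed and the trial index alone,
and the noise stream from the master seed, so strategies and swept values are
compared on common random numbers; this tightens contrasts without biasing
means.  The engine's default `precision="fast"` evaluates the per-oscillator
trigonometry in single precision (phases, reductions and noise stay double):
on this numpy build the double-precision `sin`/`cos` take a scalar libm path
~25x slower than the vectorised single-precision one, and the resulting
~1e-6 rad per-step error is orders of magnitude below the stochastic
trial-to-trial spread (`rho_bar` agrees with the double-precision path to
~1e-4).  `precision="exact"` reproduces the readable single-trial reference
loop (`dynamics.step` plus controller closures) to rounding error, and a test
holds the two paths together.

Problem sizes in the shipped tests: the focal efficacy ordering runs the
prescribed 80 trials per strategy; the configuration-parameter trend runs 120
systems per point; energy-matching linearity checks run 16 trials per point
(delivered energy has very low variance); the reported energy-correction
experiment runs the full 80.

## Measurement model and state estimation

Recording inverts the stimulation geometry: contact voltages are
`V = D f` with `D` the transposed transfer matrix (scale `c = 1`) and
`f_sigma = rho_sigma cos(psi_sigma)` the population activities.  In the
determined case `L = S`, FastICA applied offline to a stretch of recordings
recovers the activities up to permutation, sign and scale; permutation and
sign are fixed by matching the recovered mixing columns against the geometry
(or against reference signals in tests), the scale is irreducible and local
amplitudes are normalised so the envelope peaks at one over the fitting
window.  Offline phase/amplitude extraction uses the analytic signal, with a
periodic-continuation pad at the dominant period (plain Hilbert transforms
leave ~2.5% envelope ripple within the flagged 5% endpoint margin); the
first/last 5% of samples are flagged unreliable regardless.

When the closed loop runs from estimated state, ICA is fitted on the 1–5 s
pre-stimulation window and the controller receives causal estimates from
complex demodulation at `omega0` (single-pole low-pass, `tau = 0.25` s,
~0.6 Hz bandwidth): envelope and phase of each unmixed source, and the global
phase from the measured global (tremor) signal, which is taken to be directly
observable.  No stimulation artefact is injected into recordings.  With
imperfect state, ACD's efficacy degrades but stays between oracle ACD and PL
on the focal benchmark — the shipped test checks exactly that with 2-SE
slack.

## Calibration

`(omega0, gamma)` are recovered by fitting a Lorentzian profile to the power
spectrum of the model's own stimulation-free output in the *uncoupled,
noise-free* regime, where the signal is a superposition of unit oscillators
and its PSD is a sampled copy of the frequency distribution.  (At `k = 55`
the spectral linewidth reflects collective dynamics, and at
`sigma = 0.1 omega0` phase diffusion dominates `gamma`, so recovery is only
well-posed uncoupled.)  Periodogram bins of a single run carry ~100%
multiplicative fading noise — lines within a bin interfere coherently — so
the procedure pools PSDs over 24 replicate runs and fits with relative-error
weighting; across seeds this recovers both parameters to within ~2%.

`k_diag` is calibrated by grid search (default 20–100 in steps of 5): the
global signal is simulated at each candidate at the configured noise level,
Welch spectra averaged over 4 replicate runs are band-normalised to unit
power in `[centre - 2, centre + 2]` Hz (the model's amplitude scale is
arbitrary) and compared to the band-normalised target by summed squared
differences.  Tremor-band filtering is a zero-phase order-2 Butterworth
band-pass at `+/- 2` Hz around the tremor line.

The synthetic tremor fixture is the model's own stimulation-free output at
the default tremor parameters.  It emulates a narrowband, amplitude-
fluctuating 3.92 Hz oscillation; it does not emulate recording artefacts,
nonstationary tremor frequency, movement-related transients, or 1/f
background present in real recordings, so passing calibration tests
demonstrates internal consistency of the workflow, not fidelity to any
patient recording.

## Energy matching across strategies

Delivered energy is `E = sum_steps sum_l I_l dt`.  CR's schedule is open
loop, so `E_CR` is exactly proportional to `delta_theta_max` (zero residual
per trial).  ACD and PL are state-gated; in the small-intensity linear regime
their energies are also nearly proportional to the budget.  The energy-
matching factor fits zero-intercept slopes of mean energy versus
`delta_theta_max` over {0.00025, 0.0005, 0.00075, 0.001} * pi per strategy
(pooled over `a0` in {0, 2}) and reports `slope_ACD / slope_CR` — the
multiplier to apply to CR's intensity for equal delivered energy, which the
harness applies in cross-strategy efficacy sweeps.  A zero-intercept R^2
below 0.98 for either strategy raises a lack-of-fit flag (departure from the
linear regime).  The measured ratio is ~1.3: ACD's gate is open roughly half
of each oscillation cycle, during which the rate cap admits ~66.7 pulses/s
per contact, versus CR's 13 x 3.92 ~ 51.

## Known limitations

* Phases only: no spike trains, conductances, conduction delays, or
  plasticity; coupling topology is diag/off-diag only.
* Instantaneous stimulation effects; real pulses have width and shape.
* Point-source contacts and populations in a homogeneous isotropic medium;
  no lead geometry, anisotropy, or finite-element fields.
* No stimulation artefact in recordings; closed-loop results from estimated
  state are therefore optimistic.
* The greedy ACD law is optimal per step, not over a horizon.
* The Ott–Antonsen reduction assumes the Lorentzian frequency distribution
  and first-harmonic uPRC; higher harmonics can cluster oscillators off the
  reduced manifold.
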