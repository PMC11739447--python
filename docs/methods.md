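# Methods

`bgoctr` is a self-contained study of coincidence timing estimators for
TOF-PET detectors built from slow, Cherenkov-emitting scintillators
(BGO-like crystals on SiPMs with a fast analog readout).  Because no raw
bench waveforms are publicly deposited for this detector class, the
package pairs a Monte-Carlo waveform generator with the full analysis
chain, so that every estimator and every statistic can be exercised,
validated against closed forms, and compared under controlled
conditions.

## 1. Waveform model

Each coincidence event deposits an energy in two opposing crystals.  Per
channel the simulator draws:

* **Energy** — with probability `photopeak_fraction` a full-energy
  511 keV deposit smeared by a Gaussian of fractional FWHM
  `energy_resolution_fwhm_frac`; otherwise a Compton-continuum value on
  [50, 340] keV with an enhancement towards the edge.  The measured
  energy is carried on a separate (unclipped) path, mirroring detectors
  that split timing and energy readout; the clipped timing trace is
  never used for energy.
* **Interaction depth** — exponential attenuation along the crystal
  (attenuation length 11 mm at 511 keV), truncated to the crystal
  length.
* **Photons** — a Poisson number of scintillation photons
  (`detected_scint_yield` per keV) with emission times distributed as
  the rise–decay bi-exponential (sampled exactly as the sum of an
  `Exp(scint_decay_tau)` and an `Exp(scint_rise_tau)` variate, whose
  convolution is that density), plus a Poisson number of prompt
  Cherenkov photons (`cherenkov_mean` at 511 keV, scaling linearly with
  energy) emitted at t = 0.  Every photon then receives a uniform
  transit spread of width `transit_spread_coeff x (crystal_length -
  depth)` (the depth-of-interaction effect) and a Gaussian single-photon
  transit jitter of sd `sptr_sigma`.
* **Trace** — each detected photon fires one SiPM cell, a unit-peak
  difference-of-exponentials pulse (`pulse_rise_tau`, `pulse_fall_tau`)
  scaled by a Gaussian amplitude around `cell_amplitude`; pulses are
  summed on the 5 ps sample grid, white noise of sd `noise_sigma` is
  added per sample, and the trace is clipped at `clip_level`.

Channel r's interaction is offset so that an ideal, jitter-free event
yields a low-threshold crossing difference t_l − t_r exactly equal to
the configured true delay `t_true`.

Defaults (all overridable; chosen once as plausible emulation values for
a 2x2x3 mm³ BGO/SiPM channel, not as measured constants): 5 ps pitch,
150 mV clip, 90 mV single-cell amplitude with 10 % gain spread, 300 ps /
5 ns cell pulse rise/fall, 1 ns / 300 ns scintillation rise/decay,
0.5 detected photons per keV, 1.8 Cherenkov photons at 511 keV, 60 ps
single-photon jitter, 6 ps/mm transit spread, 1 mV noise,
`photopeak_fraction` 0.6, 15 % FWHM energy resolution, `t_true` = 0.

**Trace window.** The analysis only ever touches the rising-edge
neighbourhood of a pulse: the baseline-stability region (1 ns ending
0.5 ns before the crossing), the two threshold crossings, and the
3.5 ns CNN crop.  The default window is therefore 12 ns (2400 samples:
6 ns pre-trigger, 6 ns post-interaction), and photons arriving after
the window end are not rendered.  Longer windows are available through
`trace_length` / `interaction_offset`.

**Randomness.**  One root seed; every (event, channel, component) tuple
owns a named substream (`energy`, `photons`, `amplitude`, `noise`), so
switching noise off does not perturb photon statistics and any single
event is regenerable in isolation.  Identical configs produce
bit-identical datasets.

### What the generator does and does not emulate

It reproduces the statistical structure the estimators exploit: time
walk from photon-counting statistics, heavy tails from Cherenkov-count
fluctuations (events with zero prompt photons are timed by the slow
scintillation onset and arrive hundreds of ps late), and
crystal-length-dependent transit spread.  It does **not** model optical
transport (reflections, wrapping), SiPM crosstalk/afterpulsing, dark
counts, pile-up, electronics transfer functions, or correlated noise.
Passing tests therefore demonstrate the correctness of the estimators
and statistics under a faithful photon-counting model, not the absolute
CTR of any physical detector; absolute widths depend strongly on the
detected photon counts, which are emulation choices here.

## 2. Event selection and features

* **Threshold crossings** — first upward crossing of 10 mV (timing) and
  100 mV (rise time) per channel, linearly interpolated between the
  bracketing 5 ps samples.  `t_led = t_low,l − t_low,r`;
  `t_rise = t_high − t_low` per channel.  The sign convention (l minus
  r, with channel r shifted by +t_led during alignment) is fixed once
  and used everywhere.
* **Energy gate** — both channels inside the closed interval
  [440, 665] keV.  A Gaussian-plus-linear fit of the photopeak region is
  computed for QC and reported in the manifest, but the fixed window is
  authoritative.
* **Coincidence window** — |t_led| ≤ 1 ns (3 mm profile) or 2 ns
  (20 mm profile), closed interval.
* **Baseline stability** — in the 1 ns region ending 0.5 ns before the
  low crossing, a robust noise sd is estimated as 1.4826 x the median
  absolute deviation about the region median; the event fails if more
  than 13.5 % of region samples deviate beyond 2 x that sd.  At the
  2-sigma band ~4.5 % of stationary Gaussian samples are expected
  outside, so the 3x allowance passes ordinary noise while level steps,
  pickup bursts or pulse tails fail.  A literal "no sample beyond
  2 sigma" rule would reject essentially every trace carrying white
  noise (the max of ~200 samples is ~3 sigma).  The sd is per-event; a
  degenerate noiseless region (sd = 0) passes.
* **CNN inputs** — channel r is shifted onto channel l's crossing by
  t_led rounded to the sample pitch (integer-sample shift: no
  resampling artifacts; the sub-sample residual stays in the waveform
  and the label keeps the exact value), a 700-sample (3.5 ns) window
  starting 1.5 ns before the crossing is cropped, and each channel is
  min-max normalized to [0, 1] on its own.  The label is
  t_err = t_led − t_true.  Events whose window leaves the trace or
  whose crop is flat are dropped and counted.

Splits are random, disjoint and exhaustive at 65 % / 5 % / 30 %
(train / validation / test), reproducible from a seed.

## 3. Estimators

* **LED** — t_led as-is.
* **TWC** — per channel, ordinary least squares of t_led on that
  channel's rise time (unweighted OLS; nothing in the two-threshold
  method prescribes a weighting, so the simplest fit is used); the event
  is corrected by half the sum of the two per-channel predictions,
  `t_twc = t_led − ½ Σ_j (p0_j + p1_j t_rise_j)`.  Note the ½ factor
  means an independently injected per-channel walk is only half removed;
  the validation closed forms account for this exactly.  The model is
  fitted on the training split only (≥ 100 usable events; degenerate
  rise-time variance is an error), so LED, TWC and CNN are all scored on
  the same untouched test split.
* **CNN** — three 1-D convolutions over the 2x700 input (the first
  spans both channels with a 2x5 kernel, 32 filters; then two 1x3
  kernels with 64 filters), each followed by ReLU and 1x3 max pooling;
  a 256-neuron ReLU layer; one linear output t*.  Adam, squared-error
  loss, minibatches of 32; learning rate decays x0.1 at 30 % and 60 %
  of the epochs (defaults: 100 epochs at 1e-4 for the 3 mm profile,
  1e-5 for 20 mm).  The estimate is t_est = t_led − t*, so a perfect
  network returns the true delay and a zero network degrades gracefully
  to LED.  Weights are retained at the best validation loss (the
  validation split's use is a design choice; monitoring-only is the
  alternative).

The network is implemented directly on NumPy (im2col convolutions,
fan-in-scaled Gaussian init, exact Adam), which makes training
single-threaded and bit-reproducible from its seed — the
reproducibility contract of `run-study` is exact, with no
floating-point tolerance needed.  Labels are standardized internally
(the network regresses (t_err − mean)/sd of the training labels);
without this the output layer, initialized at unit scale, cannot reach
the ±hundreds-of-ps label range within a realistic schedule.  Recorded
losses are mapped back to ps².

## 4. CTR statistics

Timing values are histogrammed (bin width max(5 ps, range/200)) and
fitted with the two-Gaussian TOF kernel (narrow Cherenkov-like
component: sd σ_C, abundance r_C; broad scintillation-like component:
σ_S, 1 − r_C; common mean μ; scale N).  Numerical choices, each made
against a failure mode observed with the naive fit:

* expected counts are the kernel **integrated over each bin** (erf
  differences), not midpoint density x width — otherwise a narrow
  component comparable to the bin width inflates;
* initial weights 1/√(count+1), start values from sample quantiles
  (μ₀ = median, σ_C₀ = half the IQR-based sd, σ_S₀ = 3σ_C₀, r₀ = 0.5)
  plus a heavy-tail start and three jittered restarts; every start is
  fitted and the lowest weighted SSR wins (the model has well-known
  local minima);
* widths bounded by the data range (stops the broad component from
  degenerating into a flat background on window-truncated tails);
* a **parsimony guard**: a single Gaussian is fitted too and kept
  (r_C = 1, σ_C = σ_S) unless the second component improves the
  weighted SSR by more than 10 — on effectively Gaussian data the free
  fit otherwise plants a spurious per-mille narrow spike that biases
  the FWHM low by several per cent;
* one **reweighting pass** with model-based bin errors
  (√max(expected, 1)) — empirical small-count weights otherwise bias
  the broad width low and understate all uncertainties;
* σ_C ≤ σ_S enforced by a post-fit swap.

From the fitted kernel: FWHM and FWTM by bisection on each side of μ to
0.01 ps; the unlabeled equivalent resolution
σ_eq = 1/(2√π ∫k²) using the closed form
∫k² = r²/(2√π σ_C) + (1−r)²/(2√π σ_S) + 2r(1−r)/√(2π(σ_C²+σ_S²));
and the labeled equivalent resolution (r/σ_C + (1−r)/σ_S)⁻¹.  Both are
quoted as equivalent CTRs after multiplication by 2.355.  The labeled
value never exceeds the unlabeled one; both reduce to σ in the Gaussian
limit, as do the widths (2√(2ln2)σ, 2√(2ln10)σ) — these identities are
enforced by the test suite.

**Bootstrap.**  Uncertainty on every metric comes from repeated random
re-splits of the selected event set (50 by default; a with-replacement
variant is available behind `with_replacement`): each resample refits
the TWC model and retrains the CNN on its training split, evaluates all
methods on its test split, and refits the kernel.  Reported values are
the mean ± sd over resamples; gains over LED,
(LED − method)/LED x 100 %, carry a first-order (delta-method) error
that keeps the per-resample pairing, i.e. uses the across-resample
covariance of the LED and method values.  A resample whose kernel fit
fails even after restarts is dropped and counted; more than 20 %
dropped aborts the run.

## 5. Run profiles and problem sizes

* `bgo3` (default) — 3 mm crystal, 1 ns coincidence window, 100-epoch
  CNN at 1e-4.
* `bgo20` — 20 mm crystal, 2 ns window, 1e-5 learning rate.
* `fast` — the reduced study used by the validation suite and the
  worked example: 20 000 simulated pairs, 20 epochs at 1e-3 (the
  shorter schedule takes a proportionally larger initial rate, decayed
  at the same 30 %/60 % fractions), 5 bootstrap resamples.  About
  28 % of default-config pairs survive selection, so one resample
  trains on ≈ 3 600 examples.

## 6. Known limitations

* Absolute CTR values are emulation-dependent; only relative estimator
  comparisons and the closed-form controls are meaningful claims.
* The TWC linear model is the only correction implemented; curved
  time-walk relations would need a richer regression.
* The kernel fit's parsimony threshold (ΔSSR = 10) is a fixed
  heuristic; near-degenerate mixtures (σ_S/σ_C ≲ 1.3) are reported as
  single Gaussians with an unidentified abundance.
* At the default photon statistics the simulated waveforms are
  information-poor: with ~0.85 detected scintillation photons per ns,
  the 3.5 ns crop contains only a couple of photon pulses beyond the
  crossings, so most of the recoverable timing information is already
  in the two thresholds.  In this regime the CNN learns mainly the
  extreme tails — on the `fast` profile it delivers the best unlabeled
  equivalent CTR (a tail-weighted metric) while its prediction noise
  (~40 ps on well-timed events) makes its FWHM *worse* than LED's.
  Waveform regression overtaking the two-threshold correction on the
  FWHM requires a photon-richer emulation (or real bench waveforms)
  than the defaults provide; dense-light detectors are the physically
  analogous regime where single-point timing is already sufficient.
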