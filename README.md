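# bgoctr — coincidence timing estimators for Cherenkov-assisted BGO TOF-PET

Time-of-flight PET localizes each annihilation along its line of
response from the arrival-time difference of the two 511 keV photons;
the figure of merit is the coincidence time resolution (CTR).  BGO
scintillators are attractive (cheap, high stopping power) but slow, so
plain leading-edge discrimination (LED) suffers large time walk: events
timed by the few prompt Cherenkov photons are early and sharp, events
timed by the slow scintillation onset are late.  Two remedies use more
of the waveform:

* **TWC** — time-walk correction from a second threshold: per detector
  channel a line t_led = p0 + p1·t_rise is fitted, and each event is
  corrected by `t_twc = t_led − ½ Σ_{j∈{l,r}} (p0_j + p1_j t_rise_j)`,
  with t_rise the 10 mV → 100 mV crossing-time difference;
* **CNN** — a small convolutional network regresses the LED error
  t_err = t_led − t_true from the aligned, cropped, min–max-normalized
  2×700 waveform pair, and the estimate is t_est = t_led − t*.

This package is for detector-physics researchers who want a tested,
reproducible re-implementation of that comparison: a Monte-Carlo
generator of coincidence waveform pairs with the relevant statistical
structure (Cherenkov-count fluctuations, photon-statistics time walk,
depth-of-interaction transit spread), the three estimators, and the
CTR statistics used to score them — the two-Gaussian TOF kernel

    k(x) = N/√(2π) · [ r_C/σ_C · e^{−(x−μ)²/2σ_C²}
                     + (1−r_C)/σ_S · e^{−(x−μ)²/2σ_S²} ],

its FWHM/FWTM, the equivalent single-Gaussian resolutions for a
hot-spot detection task (unlabeled: σ_eq = 1/(2√π∫k²); labeled:
(r_C/σ_C + (1−r_C)/σ_S)⁻¹, both ×2.355 to FWHM), and a bootstrap
protocol that re-splits, refits and retrains per resample to put
error bars on every metric and on the percentage gains over LED.

The CNN is implemented directly on NumPy (im2col convolutions, Adam),
so training is single-threaded and bit-reproducible from its seed.

## Worked example

Run the reduced-scale study profile (20 000 simulated pairs, 20 CNN
epochs, 5 bootstrap resamples) from the command line:

```bash
bgoctr run-study --profile fast --out fast_run
```

The run prints the selection breakdown and the per-resample results,
ending with (numbers from this exact command):

```
simulating 20000 coincidence pairs (crystal 3 mm, seed 0)
selection: no_low_crossing=1852, outside_photopeak=11217, outside_coincidence_window=1504, baseline_unstable=3, pass=5424
built 5421 CNN examples (3 dropped at crop)
...
study complete
  LED: CTR_FWHM = 190.3 ± 2.8 ps
  TWC: CTR_FWHM = 181.5 ± 2.2 ps
  CNN: CTR_FWHM = 205.4 ± 8.5 ps
```

Reading the output: about 27 % of the simulated pairs survive the
photopeak gate ([440, 665] keV in both channels), the coincidence
window (|t_led| ≤ 1 ns) and the baseline-stability cut.  On the
surviving events the rise-time correction improves the FWHM CTR over
plain leading-edge timing by ~5 %; the ± values are 1σ spreads over
the bootstrap resamples.  The CNN at this scale corrects the extreme
tails (its unlabeled equivalent CTR improves by 13 ± 8 % over LED,
the best of the three methods) but adds prediction noise to the
well-timed core, so its FWHM is worse than LED's — at the default
sparse photon statistics the 3.5 ns crop carries little timing
information beyond the two threshold crossings, the regime where a
single- or two-point estimator already captures what the waveform
offers (see `docs/methods.md`).  `fast_run/`
contains the per-event timing table (`timing_records.csv`), the
per-resample metrics (`ctr_resamples.csv`), the full report
(`report.json`, `report.md` with FWHM/FWTM/equivalent-CTR columns and
gains), and a provenance manifest.  Absolute widths depend on the
generator's photon-statistics settings (see `docs/methods.md`); the
meaningful outputs are the relative comparisons and their errors.

The same pipeline is available piecewise (`bgoctr simulate`,
`preprocess`, `fit-twc`, `train-cnn`, `estimate`, `evaluate`) and as a
library:

```python
from bgoctr import SimConfig, SelectionConfig, generate_dataset
from bgoctr import extract_timing_records, fit_double_gaussian, fwhm_fwtm
from bgoctr.preprocess import qc_passed

ds = generate_dataset(SimConfig(n_events=5000, seed=1))
rec = extract_timing_records(ds, SelectionConfig())
kernel = fit_double_gaussian(rec.loc[qc_passed(rec), "t_led"])
print(fwhm_fwtm(kernel))
```

Profiles: `bgo3` (3 mm crystal, 1 ns window, 100-epoch CNN at 1e-4),
`bgo20` (20 mm, 2 ns, 1e-5), `fast` (above).  Any field can be
overridden with `--set section.key=value` or a YAML config.

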