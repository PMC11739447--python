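"""Event selection and feature extraction.

From raw coincidence waveform pairs this module derives, per event, the
two-threshold crossing times (10 mV / 100 mV by default), the coincidence
time delay t_led (low-threshold crossing difference, channel l minus
channel r), per-channel rise times, and quality flags (photopeak energy
gate, coincidence window, baseline stability).  It also builds the
aligned / cropped / min-max-normalized 2x700 inputs and t_err labels the
CNN estimator trains on, and the train/validation/test split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .config import SelectionConfig
from .simulate import WaveformDataset

__all__ = [
    "crossing_time",
    "crossing_times",
    "extract_timing_records",
    "photopeak_window",
    "qc_filter",
    "CnnExampleSet",
    "build_cnn_examples",
    "align_records",
    "split_dataset",
    "save_examples",
    "load_examples",
]


def crossing_time(trace: np.ndarray, threshold: float,
                  sample_pitch: float) -> float | None:
    """First upward threshold crossing of one trace, in ps.

    Linear interpolation between the bracketing samples; ``None`` if the
    trace never reaches the threshold.  A trace already above threshold at
    its first sample crosses at time 0.
    """
    t = crossing_times(np.asarray(trace, dtype=float)[None, :], threshold,
                       sample_pitch)[0]
    return None if math.isnan(t) else float(t)


def crossing_times(traces: np.ndarray, threshold: float,
                   sample_pitch: float) -> np.ndarray:
    """Vectorized :func:`crossing_time` over the leading axis (NaN = absent)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    traces = np.asarray(traces, dtype=float)
    above = traces >= threshold
    has = above.any(axis=-1)
    idx = above.argmax(axis=-1)
    out = np.full(traces.shape[:-1], np.nan)
    hit = has & (idx > 0)
    if np.any(hit):
        i = idx[hit]
        rows = np.nonzero(hit)
        v1 = traces[rows + (i,)]
        v0 = traces[rows + (i - 1,)]
        frac = (threshold - v0) / (v1 - v0)
        out[hit] = (i - 1 + frac) * sample_pitch
    out[has & (idx == 0)] = 0.0
    return out


def _baseline_ok(traces: np.ndarray, t_cross: np.ndarray,
                 cfg: SelectionConfig, pitch: float):
    """Baseline-stability flag per trace.

    The test region spans ``baseline_span`` ps and ends ``baseline_gap`` ps
    before the low-threshold crossing.  A trace is unstable when the
    fraction of region samples deviating from the region median by more
    than ``baseline_k`` times a robust noise sd (1.4826 x the median
    absolute deviation) exceeds ``baseline_max_exceed_frac`` — for Gaussian
    noise at k = 2 about 4.5 % of samples are expected beyond the band, so
    the default limit of 13.5 % (3x) passes stationary noise while steps,
    pickup or pulse tails that shift a stretch of the baseline fail.
    Traces whose region would start before the trace, or without a
    crossing, are marked invalid (second return).
    """
    n = traces.shape[0]
    span = max(2, int(round(cfg.baseline_span / pitch)))
    ok = np.zeros(n, dtype=bool)
    valid = np.zeros(n, dtype=bool)
    has = ~np.isnan(t_cross)
    end = np.zeros(n, dtype=int)
    end[has] = np.floor((t_cross[has] - cfg.baseline_gap) / pitch).astype(int)
    start = end - span
    usable = has & (start >= 0) & (end <= traces.shape[1])
    valid[usable] = True
    if np.any(usable):
        cols = start[usable, None] + np.arange(span)[None, :]
        region = traces[np.nonzero(usable)[0][:, None], cols]
        med = np.median(region, axis=1, keepdims=True)
        dev = np.abs(region - med)
        sd = 1.4826 * np.median(dev, axis=1, keepdims=True)
        exceed = (dev > cfg.baseline_k * sd + 1e-12).mean(axis=1)
        ok[usable] = exceed <= cfg.baseline_max_exceed_frac
    return ok, valid


def extract_timing_records(ds: WaveformDataset,
                           cfg: SelectionConfig) -> pd.DataFrame:
    """Per-event timing table: crossings, t_led, rise times, energies, flags.

    Columns: event_id, t_cross_low_l/r, t_cross_high_l/r, t_led,
    t_rise_l/r, energy_l/r, in_photopeak, in_coincidence_window,
    baseline_ok, baseline_valid, has_both_low, has_both_high, t_true.
    Missing crossings are NaN.
    """
    pitch = ds.sample_pitch
    wl, wr = ds.waveforms[:, 0, :], ds.waveforms[:, 1, :]
    low_l = crossing_times(wl, cfg.threshold_low, pitch)
    low_r = crossing_times(wr, cfg.threshold_low, pitch)
    high_l = crossing_times(wl, cfg.threshold_high, pitch)
    high_r = crossing_times(wr, cfg.threshold_high, pitch)
    t_led = low_l - low_r
    lo, hi = cfg.energy_window
    e_l = ds.truth["energy_l"].to_numpy()
    e_r = ds.truth["energy_r"].to_numpy()
    in_peak = (e_l >= lo) & (e_l <= hi) & (e_r >= lo) & (e_r <= hi)
    in_window = np.abs(t_led) <= cfg.coincidence_window
    in_window &= ~np.isnan(t_led)
    ok_l, valid_l = _baseline_ok(wl, low_l, cfg, pitch)
    ok_r, valid_r = _baseline_ok(wr, low_r, cfg, pitch)
    df = pd.DataFrame({
        "event_id": ds.truth["event_id"].to_numpy(),
        "t_cross_low_l": low_l, "t_cross_low_r": low_r,
        "t_cross_high_l": high_l, "t_cross_high_r": high_r,
        "t_led": t_led,
        "t_rise_l": high_l - low_l, "t_rise_r": high_r - low_r,
        "energy_l": e_l, "energy_r": e_r,
        "in_photopeak": in_peak,
        "in_coincidence_window": in_window,
        "baseline_ok": ok_l & ok_r,
        "baseline_valid": valid_l & valid_r,
        "has_both_low": ~np.isnan(low_l) & ~np.isnan(low_r),
        "has_both_high": ~np.isnan(high_l) & ~np.isnan(high_r),
        "t_true": ds.truth["t_true"].to_numpy(),
    })
    return df


def qc_passed(records: pd.DataFrame) -> pd.Series:
    """Events passing the full selection (energy, window, baseline)."""
    return (records["in_photopeak"] & records["in_coincidence_window"]
            & records["baseline_ok"] & records["baseline_valid"]
            & records["has_both_low"])


def qc_filter(pair, record: dict | pd.Series, cfg: SelectionConfig) -> dict:
    """Quality flags for a single event (scalar convenience wrapper).

    ``pair`` is a :class:`~bgoctr.simulate.WaveformPair`; ``record`` must
    carry ``t_led`` and the per-channel low crossings.
    """
    pitch = pair.sample_pitch
    t_led = record["t_led"]
    in_window = bool(np.isfinite(t_led) and abs(t_led) <= cfg.coincidence_window)
    crossings = np.array([record["t_cross_low_l"], record["t_cross_low_r"]],
                         dtype=float)
    ok, valid = _baseline_ok(np.asarray(pair.voltages, dtype=float),
                             crossings, cfg, pitch)
    return {
        "in_coincidence_window": in_window,
        "baseline_ok": bool(ok.all()),
        "baseline_valid": bool(valid.all()),
    }


def _gauss_lin(e, amp, mu, sigma, slope, intercept):
    return amp * np.exp(-0.5 * ((e - mu) / sigma) ** 2) + slope * e + intercept


def photopeak_window(energies: np.ndarray,
                     fixed_window: tuple[float, float] = (440.0, 665.0),
                     n_bins: int = 120):
    """Locate the full-energy peak and return the analysis energy window.

    Fits a Gaussian plus linear background around the spectrum's upper
    mode for QC; the returned window is the fixed one (the fit reports the
    peak position/width but does not move the gate).  Returns
    ``(window, fit)`` where fit holds amp/mu/sigma/slope/intercept and a
    ``converged`` flag.
    """
    energies = np.asarray(energies, dtype=float)
    energies = energies[np.isfinite(energies)]
    if energies.size < 500:
        raise ValueError("photopeak fit needs at least 500 energy values")
    counts, edges = np.histogram(energies, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # upper mode: strongest bin in the top half of the energy range
    upper = centers > 0.5 * (centers[0] + centers[-1])
    if not upper.any():
        upper = np.ones_like(centers, dtype=bool)
    mu0 = centers[upper][np.argmax(counts[upper])]
    sel = np.abs(centers - mu0) < 0.35 * mu0
    p0 = [counts[sel].max(), mu0, 0.06 * mu0, 0.0, np.median(counts[sel])]
    fit = {"converged": False, "amp": np.nan, "mu": np.nan, "sigma": np.nan,
           "slope": np.nan, "intercept": np.nan}
    try:
        popt, _ = curve_fit(_gauss_lin, centers[sel], counts[sel], p0=p0,
                            maxfev=20_000)
        fit.update(converged=True, amp=popt[0], mu=popt[1],
                   sigma=abs(popt[2]), slope=popt[3], intercept=popt[4])
    except RuntimeError:
        pass
    return tuple(fixed_window), fit


@dataclass
class CnnExampleSet:
    """Aligned, cropped, normalized CNN inputs with t_err labels.

    ``inputs`` is (n, 2, crop_samples) in [0, 1]; ``labels`` the LED error
    t_err = t_led - t_true in ps; ``t_led`` kept so the final estimate
    t_led - t* can be formed; ``n_dropped`` counts events lost to window
    bounds or degenerate (flat) crops.
    """

    inputs: np.ndarray
    labels: np.ndarray
    t_led: np.ndarray
    event_ids: np.ndarray
    n_dropped: int = 0

    def __len__(self) -> int:
        return self.inputs.shape[0]


def normalize_minmax(windows: np.ndarray) -> np.ndarray:
    """Per-channel min-max normalization to [0, 1] (idempotent)."""
    lo = windows.min(axis=-1, keepdims=True)
    hi = windows.max(axis=-1, keepdims=True)
    return (windows - lo) / (hi - lo)


def build_cnn_examples(ds: WaveformDataset, records: pd.DataFrame,
                       cfg: SelectionConfig,
                       mask: np.ndarray | None = None) -> CnnExampleSet:
    """Build CNN training examples from QC-passing events.

    Channel r is shifted onto channel l's time base by t_led rounded to the
    sample pitch (integer-sample shift; the sub-sample residual stays in
    the waveform while the label keeps the exact t_led - t_true).  A
    ``crop_samples``-long window starts ``crop_pre`` ps before channel l's
    low-threshold crossing; each channel is min-max normalized on its own.
    Events whose window leaves the trace, or with a flat crop, are dropped
    and counted.
    """
    pitch = ds.sample_pitch
    T = ds.waveforms.shape[2]
    span = cfg.crop_samples
    if mask is None:
        mask = qc_passed(records).to_numpy()
    mask = np.asarray(mask, dtype=bool)
    idx = np.nonzero(mask)[0]
    t_led = records["t_led"].to_numpy()[idx]
    t_l = records["t_cross_low_l"].to_numpy()[idx]
    shift = np.round(t_led / pitch).astype(int)
    start = np.round((t_l - cfg.crop_pre) / pitch).astype(int)
    ok = (start >= 0) & (start + span <= T)
    ok &= (start - shift >= 0) & (start - shift + span <= T)
    n_dropped = int((~ok).sum())
    idx, t_led, shift, start = idx[ok], t_led[ok], shift[ok], start[ok]
    offs = np.arange(span)[None, :]
    win_l = ds.waveforms[idx[:, None], 0, start[:, None] + offs]
    win_r = ds.waveforms[idx[:, None], 1, (start - shift)[:, None] + offs]
    windows = np.stack([win_l, win_r], axis=1).astype(np.float64)
    rng_span = windows.max(axis=-1) - windows.min(axis=-1)
    flat = (rng_span <= 0).any(axis=-1)
    n_dropped += int(flat.sum())
    keep = ~flat
    windows, idx, t_led = windows[keep], idx[keep], t_led[keep]
    inputs = normalize_minmax(windows).astype(np.float32)
    t_true = records["t_true"].to_numpy()[idx]
    return CnnExampleSet(
        inputs=inputs,
        labels=(t_led - t_true).astype(np.float64),
        t_led=t_led.astype(np.float64),
        event_ids=records["event_id"].to_numpy()[idx],
        n_dropped=n_dropped,
    )


def align_records(records: pd.DataFrame, event_ids: np.ndarray) -> pd.DataFrame:
    """Rows of ``records`` reordered to match ``event_ids`` (one per example)."""
    pos = {eid: i for i, eid in enumerate(records["event_id"].to_numpy())}
    return records.iloc[[pos[e] for e in event_ids]].reset_index(drop=True)


def split_dataset(n_or_examples, fractions=(0.65, 0.05, 0.30),
                  seed: int = 0,
                  rng: np.random.Generator | None = None):
    """Random disjoint train/validation/test index split.

    ``n_or_examples`` is an int or anything with ``len``.  Sizes are the
    rounded fractions (train and validation rounded, test takes the rest).
    Reproducible from ``seed`` (or an explicit ``rng``).
    """
    n = n_or_examples if isinstance(n_or_examples, (int, np.integer)) \
        else len(n_or_examples)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if n < 3:
        raise ValueError("need at least 3 examples to split")
    if rng is None:
        rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    if n_train + n_val >= n:
        raise ValueError("split leaves no test examples")
    return (np.sort(perm[:n_train]),
            np.sort(perm[n_train:n_train + n_val]),
            np.sort(perm[n_train + n_val:]))


def save_examples(examples: CnnExampleSet, path: str) -> None:
    """Persist a CNN example set as HDF5 (/inputs [n,2,W], /labels [n], ...)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("inputs", data=examples.inputs, dtype="float32")
        f.create_dataset("labels", data=examples.labels)
        f.create_dataset("t_led", data=examples.t_led)
        f.create_dataset("event_ids", data=examples.event_ids)
        f.attrs["n_dropped"] = examples.n_dropped


def load_examples(path: str) -> CnnExampleSet:
    with h5py.File(path, "r") as f:
        return CnnExampleSet(
            inputs=f["inputs"][...],
            labels=f["labels"][...],
            t_led=f["t_led"][...],
            event_ids=f["event_ids"][...],
            n_dropped=int(f.attrs["n_dropped"]),
        )
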