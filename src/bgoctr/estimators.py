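"""The three coincidence timing estimators.

* LED — the low-threshold crossing difference t_led, used as-is.
* TWC — time-walk correction: per detector channel, an ordinary
  least-squares line of t_led against that channel's rise time is fitted,
  and each event is corrected by half the sum of the two per-channel
  predictions:

      t_twc_i = t_led_i - 1/2 * sum_{j in {l,r}} (p0_j + p1_j * t_rise_j)

* CNN — the network regresses the LED error t_err = t_led - t_true from
  the aligned waveform pair; the estimate is t_est = t_led - t*, so a
  perfect network returns the true delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cnn import CnnModel, train_cnn
from .config import TrainSpec
from .preprocess import CnnExampleSet

__all__ = ["TwcModel", "estimate_led", "fit_twc", "apply_twc",
           "estimate_cnn", "train_cnn_estimator"]


def estimate_led(records: pd.DataFrame | pd.Series | dict) -> np.ndarray | float:
    """LED estimator: the t_led values, unchanged."""
    if isinstance(records, pd.DataFrame):
        return records["t_led"].to_numpy().copy()
    return float(records["t_led"])


@dataclass
class TwcModel:
    """Per-channel linear time-walk model: t_led ~ p0 + p1 * t_rise."""

    p0_l: float
    p1_l: float
    p0_r: float
    p1_r: float
    se_p1_l: float
    se_p1_r: float
    residual_sd_l: float
    residual_sd_r: float
    n_fit: int

    def correction(self, t_rise_l, t_rise_r):
        """The subtracted term of the correction formula (ps)."""
        return 0.5 * ((self.p0_l + self.p1_l * np.asarray(t_rise_l))
                      + (self.p0_r + self.p1_r * np.asarray(t_rise_r)))


def _ols_line(x: np.ndarray, y: np.ndarray):
    """Slope/intercept with the slope's standard error and residual sd."""
    n = x.size
    vx = np.var(x)
    if vx <= 0:
        raise ValueError("zero variance in t_rise: degenerate time-walk fit")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    dof = max(n - 2, 1)
    resid_sd = float(np.sqrt(resid @ resid / dof))
    se_slope = resid_sd / np.sqrt(n * vx)
    return float(intercept), float(slope), float(se_slope), resid_sd


def fit_twc(records: pd.DataFrame, min_events: int = 100) -> TwcModel:
    """Fit the per-channel time-walk lines on QC-passing events.

    ``records`` must already be restricted to the fit population (typically
    the training split of photopeak events having both threshold
    crossings); rows with a missing rise time are dropped here.
    """
    usable = records.dropna(subset=["t_led", "t_rise_l", "t_rise_r"])
    if len(usable) < min_events:
        raise ValueError(f"time-walk fit needs at least {min_events} usable "
                         f"events, got {len(usable)}")
    t_led = usable["t_led"].to_numpy()
    p0_l, p1_l, se_l, sd_l = _ols_line(usable["t_rise_l"].to_numpy(), t_led)
    p0_r, p1_r, se_r, sd_r = _ols_line(usable["t_rise_r"].to_numpy(), t_led)
    return TwcModel(p0_l=p0_l, p1_l=p1_l, p0_r=p0_r, p1_r=p1_r,
                    se_p1_l=se_l, se_p1_r=se_r,
                    residual_sd_l=sd_l, residual_sd_r=sd_r, n_fit=len(usable))


def apply_twc(records: pd.DataFrame | pd.Series | dict,
              model: TwcModel) -> np.ndarray | float:
    """Corrected timing values; events lacking a rise time come back NaN."""
    if isinstance(records, pd.DataFrame):
        t_led = records["t_led"].to_numpy()
        corr = model.correction(records["t_rise_l"].to_numpy(),
                                records["t_rise_r"].to_numpy())
        return t_led - corr
    return float(records["t_led"]
                 - model.correction(records["t_rise_l"], records["t_rise_r"]))


def train_cnn_estimator(examples: CnnExampleSet, train_idx: np.ndarray,
                        val_idx: np.ndarray, spec: TrainSpec,
                        seed: int = 0, verbose: bool = False) -> CnnModel:
    """Train the CNN on the t_err labels of the given split."""
    return train_cnn(examples.inputs[train_idx], examples.labels[train_idx],
                     examples.inputs[val_idx], examples.labels[val_idx],
                     spec, seed=seed, verbose=verbose)


def estimate_cnn(examples: CnnExampleSet, model: CnnModel,
                 idx: np.ndarray | None = None) -> np.ndarray:
    """CNN estimator: t_est = t_led - t* on the given (test) examples."""
    if idx is None:
        idx = np.arange(len(examples))
    t_star = model.predict(examples.inputs[idx])
    return examples.t_led[idx] - t_star
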