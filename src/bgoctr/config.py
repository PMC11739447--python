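"""Configuration objects for the simulation / timing-analysis pipeline.

Every tunable of the study lives in one of the dataclasses below.  All of
them validate eagerly: construct, call :meth:`validate`, get back a list of
human-readable problems (empty when the config is usable).  The CLI and the
YAML loader aggregate these instead of failing on the first error.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import yaml

__all__ = [
    "SimConfig",
    "SelectionConfig",
    "TrainSpec",
    "BootstrapSpec",
    "RunConfig",
    "ConfigError",
    "load_run_config",
    "validate_config",
]


class ConfigError(ValueError):
    """Raised when a configuration fails validation.

    ``errors`` holds the full list of problems; the string form joins them.
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.errors))


@dataclass
class SimConfig:
    """Monte-Carlo generator settings for coincidence waveform pairs.

    The defaults emulate a pair of 2x2x3 mm^3 BGO crystals on blue-sensitive
    SiPMs with a high-frequency readout: a slow scintillation pulse
    (~300 ns decay) with a couple of prompt Cherenkov photons on top,
    digitized at 5 ps pitch on a 150 mV scale.  Photon yields, pulse shape
    constants and jitters are emulation choices (see docs/methods.md), not
    measured values; everything is overridable.
    """

    sample_pitch: float = 5.0          # ps per sample
    trace_length: int = 2400           # samples; 12 ns at the default pitch
    interaction_offset: float = 6000.0  # ps from trace start to interaction
    clip_level: float = 150.0          # mV, digitizer full scale
    cell_amplitude: float = 90.0       # mV, single SiPM cell peak
    cell_amplitude_cv: float = 0.1     # relative gain spread per fired cell
    pulse_rise_tau: float = 300.0      # ps, single-cell pulse rise
    pulse_fall_tau: float = 5000.0     # ps, single-cell pulse fall
    scint_rise_tau: float = 1000.0     # ps, scintillation emission rise
    scint_decay_tau: float = 300_000.0  # ps, scintillation decay (BGO-like)
    detected_scint_yield: float = 0.5  # detected photons per keV
    cherenkov_mean: float = 1.8        # mean detected prompt photons at 511 keV
    cherenkov_count_fixed: Optional[int] = None  # exact count instead of Poisson
    sptr_sigma: float = 60.0           # ps, single-photon transit jitter (sd)
    crystal_length: float = 3.0        # mm
    attenuation_length: float = 11.0   # mm, 511 keV in BGO
    transit_spread_coeff: float = 6.0  # ps/mm of remaining crystal path
    noise_sigma: float = 1.0           # mV, additive white noise per sample
    photopeak_fraction: float = 0.6    # probability an interaction is full-energy
    energy_resolution_fwhm_frac: float = 0.15  # FWHM/511 of the photopeak
    t_true: float = 0.0                # ps, true inter-detector delay
    n_events: int = 1000
    seed: int = 0

    def validate(self) -> list[str]:
        errs = []
        if self.sample_pitch <= 0:
            errs.append("sample_pitch must be > 0")
        if self.trace_length < 10:
            errs.append("trace_length must be at least 10 samples")
        if not 0 < self.interaction_offset < self.sample_pitch * self.trace_length:
            errs.append("interaction_offset must fall inside the trace")
        if self.clip_level <= 0:
            errs.append("clip_level must be > 0")
        if self.cell_amplitude <= 0:
            errs.append("cell_amplitude must be > 0")
        if self.cell_amplitude_cv < 0:
            errs.append("cell_amplitude_cv must be >= 0")
        for name in ("pulse_rise_tau", "pulse_fall_tau", "scint_rise_tau",
                     "scint_decay_tau"):
            if getattr(self, name) <= 0:
                errs.append(f"{name} must be > 0")
        if self.pulse_rise_tau >= self.pulse_fall_tau:
            errs.append("pulse_rise_tau must be < pulse_fall_tau")
        if self.detected_scint_yield < 0:
            errs.append("detected_scint_yield must be >= 0")
        if self.cherenkov_mean < 0:
            errs.append("cherenkov_mean must be >= 0")
        if self.cherenkov_count_fixed is not None and self.cherenkov_count_fixed < 0:
            errs.append("cherenkov_count_fixed must be >= 0 when set")
        if self.sptr_sigma < 0:
            errs.append("sptr_sigma must be >= 0")
        if self.crystal_length <= 0:
            errs.append("crystal_length must be > 0")
        if self.attenuation_length <= 0:
            errs.append("attenuation_length must be > 0")
        if self.transit_spread_coeff < 0:
            errs.append("transit_spread_coeff must be >= 0")
        if self.noise_sigma < 0:
            errs.append("noise_sigma must be >= 0")
        if not 0.0 <= self.photopeak_fraction <= 1.0:
            errs.append("photopeak_fraction must be in [0, 1]")
        if self.energy_resolution_fwhm_frac < 0:
            errs.append("energy_resolution_fwhm_frac must be >= 0")
        if self.n_events < 0:
            errs.append("n_events must be >= 0")
        # pulse peak must fit in the post-interaction part of the trace
        post = self.sample_pitch * self.trace_length - self.interaction_offset
        if post < 4 * self.pulse_rise_tau:
            errs.append("trace too short after interaction_offset to contain "
                        "the pulse peak")
        return errs


@dataclass
class SelectionConfig:
    """Event selection and CNN-input construction settings.

    Thresholds, energy window, coincidence windows, baseline test and crop
    geometry follow the two-threshold bench analysis they emulate.
    """

    threshold_low: float = 10.0      # mV, timing (LED) threshold
    threshold_high: float = 100.0    # mV, rise-time threshold
    energy_window: tuple[float, float] = (440.0, 665.0)  # keV, closed interval
    coincidence_window: float = 1000.0  # ps; 2000 for 20 mm crystals
    baseline_span: float = 1000.0    # ps, length of the baseline region
    baseline_gap: float = 500.0      # ps between region end and low crossing
    baseline_k: float = 2.0          # sigma multiplier for the stability test
    baseline_max_exceed_frac: float = 0.135  # tolerated fraction beyond k*sigma
    crop_pre: float = 1500.0         # ps of baseline kept before the crossing
    crop_samples: int = 700          # samples per channel fed to the CNN

    def validate(self, clip_level: float | None = None) -> list[str]:
        errs = []
        if self.threshold_low <= 0:
            errs.append("threshold_low must be > 0")
        if self.threshold_high <= self.threshold_low:
            errs.append("threshold_high must exceed threshold_low "
                        f"(got threshold_high={self.threshold_high}, "
                        f"threshold_low={self.threshold_low})")
        if clip_level is not None and self.threshold_high >= clip_level:
            errs.append("threshold_high must be below the digitizer clip level")
        lo, hi = self.energy_window
        if not lo < hi:
            errs.append("energy_window must be (low, high) with low < high")
        if self.coincidence_window <= 0:
            errs.append("coincidence_window must be > 0")
        if self.baseline_span <= 0 or self.baseline_gap < 0:
            errs.append("baseline_span must be > 0 and baseline_gap >= 0")
        if self.baseline_k <= 0:
            errs.append("baseline_k must be > 0")
        if not 0 <= self.baseline_max_exceed_frac < 1:
            errs.append("baseline_max_exceed_frac must be in [0, 1)")
        if self.crop_pre < 0:
            errs.append("crop_pre must be >= 0")
        if self.crop_samples < 2:
            errs.append("crop_samples must be >= 2")
        return errs


@dataclass
class TrainSpec:
    """CNN architecture + optimisation schedule.

    The architecture is fixed to three convolutional layers (2x5/1x3/1x3
    kernels with 32/64/64 filters, ReLU + 1x3 max pooling after each), a
    256-neuron fully connected ReLU layer and a single linear output; only
    the schedule is tunable here.  Learning rate decays x0.1 at 30 % and
    60 % of the epochs.
    """

    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-4     # 1e-5 for the 20 mm profile
    decay_fracs: tuple[float, float] = (0.3, 0.6)
    conv_filters: tuple[int, int, int] = (32, 64, 64)
    conv_kernels: tuple[int, int, int] = (5, 3, 3)  # lengths; first spans both rows
    pool_size: int = 3
    fc_units: int = 256

    def validate(self) -> list[str]:
        errs = []
        if self.epochs < 1:
            errs.append("epochs must be >= 1")
        if self.batch_size < 1:
            errs.append("batch_size must be >= 1")
        if self.learning_rate <= 0:
            errs.append("learning_rate must be > 0")
        if len(self.conv_filters) != 3 or any(f < 1 for f in self.conv_filters):
            errs.append("conv_filters must be three positive counts")
        if len(self.conv_kernels) != 3 or any(k < 1 for k in self.conv_kernels):
            errs.append("conv_kernels must be three positive lengths")
        if self.pool_size < 1:
            errs.append("pool_size must be >= 1")
        if self.fc_units < 1:
            errs.append("fc_units must be >= 1")
        if not all(0 < f < 1 for f in self.decay_fracs):
            errs.append("decay_fracs must lie in (0, 1)")
        return errs


@dataclass
class BootstrapSpec:
    """Resampling protocol for CTR uncertainty estimation."""

    n_resamples: int = 50
    split_fractions: tuple[float, float, float] = (0.65, 0.05, 0.30)
    with_replacement: bool = False   # re-split (default) vs classic bootstrap
    fit_min_values: int = 500        # minimum test-split size for a kernel fit
    seed: int = 0

    def validate(self) -> list[str]:
        errs = []
        if self.n_resamples < 1:
            errs.append("n_resamples must be >= 1")
        if self.fit_min_values < 20:
            errs.append("fit_min_values must be >= 20")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            errs.append("split_fractions must sum to 1")
        if any(f < 0 for f in self.split_fractions):
            errs.append("split_fractions must be >= 0")
        return errs


@dataclass
class RunConfig:
    """Everything a full study run needs."""

    sim: SimConfig = field(default_factory=SimConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    train: TrainSpec = field(default_factory=TrainSpec)
    bootstrap: BootstrapSpec = field(default_factory=BootstrapSpec)
    methods: tuple[str, ...] = ("LED", "TWC", "CNN")
    output_dir: str = "bgoctr_out"
    verbosity: int = 1

    def validate(self) -> list[str]:
        errs = []
        errs += self.sim.validate()
        errs += self.selection.validate(clip_level=self.sim.clip_level)
        errs += self.train.validate()
        errs += self.bootstrap.validate()
        bad = set(self.methods) - {"LED", "TWC", "CNN"}
        if bad:
            errs.append(f"unknown methods: {sorted(bad)}")
        if "LED" not in self.methods:
            errs.append("methods must include LED (gain reference)")
        return errs

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


# built-in profiles mirroring the two crystal geometries
PROFILES: dict[str, dict[str, Any]] = {
    "bgo3": {},
    "bgo20": {
        "sim": {"crystal_length": 20.0},
        "selection": {"coincidence_window": 2000.0},
        "train": {"learning_rate": 1e-5},
    },
    # reduced-scale profile for quick runs: fewer events and epochs, a
    # proportionally larger initial learning rate, few resamples
    "fast": {
        "sim": {"n_events": 20_000},
        "train": {"epochs": 20, "learning_rate": 1e-3},
        "bootstrap": {"n_resamples": 5},
    },
}

_SECTION_TYPES = {
    "sim": SimConfig,
    "selection": SelectionConfig,
    "train": TrainSpec,
    "bootstrap": BootstrapSpec,
}

_TUPLE_FIELDS = {
    "energy_window", "decay_fracs", "conv_filters", "conv_kernels",
    "split_fractions", "methods",
}


def _build_section(cls, data: dict[str, Any], where: str, errors: list[str]):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    for key in sorted(unknown):
        errors.append(f"unknown key '{key}' in section '{where}'")
    kwargs = {}
    for key, value in data.items():
        if key in known:
            if key in _TUPLE_FIELDS and isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:  # wrong type for a field
        errors.append(f"section '{where}': {exc}")
        return cls()


def validate_config(raw: dict[str, Any] | None,
                    profile: str | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a raw mapping, rejecting unknown keys.

    ``profile`` applies one of the built-in presets first; explicit keys
    override it.  Raises :class:`ConfigError` with the aggregated list of
    problems if anything is wrong.  An empty/None mapping yields the
    defaults.
    """
    raw = dict(raw or {})
    errors: list[str] = []

    merged: dict[str, Any] = {}
    if profile is not None:
        if profile not in PROFILES:
            raise ConfigError([f"unknown profile '{profile}' "
                               f"(available: {sorted(PROFILES)})"])
        for section, vals in PROFILES[profile].items():
            merged[section] = dict(vals)
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                errors.append(f"section '{key}' must be a mapping")
                continue
            merged.setdefault(key, {}).update(value)
        else:
            merged[key] = value

    top_known = {f.name for f in dataclasses.fields(RunConfig)}
    sections = {}
    top_kwargs: dict[str, Any] = {}
    for key, value in merged.items():
        if key in _SECTION_TYPES:
            sections[key] = _build_section(_SECTION_TYPES[key], value, key, errors)
        elif key in top_known:
            if key in _TUPLE_FIELDS and isinstance(value, list):
                value = tuple(value)
            top_kwargs[key] = value
        else:
            errors.append(f"unknown key '{key}' at top level")

    cfg = RunConfig(**{**sections, **top_kwargs})

    # auto-select the coincidence window for long crystals unless overridden
    if ("selection" not in merged or
            "coincidence_window" not in merged.get("selection", {})):
        if cfg.sim.crystal_length >= 10.0:
            cfg.selection.coincidence_window = 2000.0

    errors += cfg.validate()
    if errors:
        raise ConfigError(errors)
    return cfg


def load_run_config(path: str, profile: str | None = None) -> RunConfig:
    """Load a YAML (or JSON — YAML is a superset) config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError([f"config file {path} must contain a mapping"])
    return validate_config(raw, profile=profile)
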