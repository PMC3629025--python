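"""Configuration dataclasses for the synthetic MSIT study and its analysis.

The defaults encode the study design this package emulates: five 3-minute
event-related runs of the multi-source interference task (MSIT), each with
24 congruent, 24 incongruent and 12 fixation trials of 3 s (0.5 s stimulus +
2.5 s fixation), acquired at TR = 2 s.  Behaviour is calibrated so that
condition mean RTs are 686.9 ms (congruent) and 969.8 ms (incongruent) and
error rates are 0.1% and 8.2%.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "ScheduleSpec",
    "ConditionBehavior",
    "RTModel",
    "BoldTruth",
    "HRFSpec",
    "PipelineConfig",
    "load_config",
    "save_config",
]


@dataclass
class ScheduleSpec:
    """Trial schedule of one participant's scanning session."""

    n_runs: int = 5
    n_congruent_per_run: int = 24
    n_incongruent_per_run: int = 24
    n_fixation_per_run: int = 12
    trial_duration: float = 3.0  # s, stimulus + post-stimulus fixation
    stimulus_duration: float = 0.5  # s
    tr: float = 2.0  # s
    seed: int | None = None

    def __post_init__(self) -> None:
        counts = (
            self.n_runs,
            self.n_congruent_per_run,
            self.n_incongruent_per_run,
            self.n_fixation_per_run,
        )
        if any(c < 0 for c in counts):
            raise ValueError("trial/run counts must be non-negative")
        if self.trial_duration <= 0 or self.tr <= 0:
            raise ValueError("trial_duration and tr must be positive")
        if not 0 <= self.stimulus_duration <= self.trial_duration:
            raise ValueError("stimulus_duration must lie within the trial")

    @property
    def n_trials_per_run(self) -> int:
        return (
            self.n_congruent_per_run
            + self.n_incongruent_per_run
            + self.n_fixation_per_run
        )

    @property
    def run_duration(self) -> float:
        """Span of one run in seconds."""
        return self.n_trials_per_run * self.trial_duration

    @property
    def n_volumes_per_run(self) -> int:
        import math

        return math.ceil(self.run_duration / self.tr) if self.n_trials_per_run else 0


@dataclass
class ConditionBehavior:
    """Ex-Gaussian RT parameters and response probabilities for one condition.

    The ex-Gaussian (Gaussian(mu, sigma) + Exponential(tau)) is the standard
    descriptive model for RT distributions; its mean is mu + tau and its SD
    is sqrt(sigma**2 + tau**2).
    """

    mu: float  # ms
    sigma: float  # ms
    tau: float  # ms
    p_error: float = 0.0
    p_omission: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.tau < 0:
            raise ValueError("require sigma > 0 and tau >= 0")
        for p in (self.p_error, self.p_omission):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def mean_rt(self) -> float:
        return self.mu + self.tau

    @property
    def sd_rt(self) -> float:
        return float((self.sigma**2 + self.tau**2) ** 0.5)


def _default_congruent() -> ConditionBehavior:
    # mean 536.9 + 150 = 686.9 ms, SD ~170 ms
    return ConditionBehavior(mu=536.9, sigma=80.0, tau=150.0,
                             p_error=0.001, p_omission=0.005)


def _default_incongruent() -> ConditionBehavior:
    # mean 789.8 + 180 = 969.8 ms, SD ~201 ms
    return ConditionBehavior(mu=789.8, sigma=90.0, tau=180.0,
                             p_error=0.082, p_omission=0.005)


@dataclass
class RTModel:
    """Per-condition behavioural model for the two task conditions."""

    congruent: ConditionBehavior = field(default_factory=_default_congruent)
    incongruent: ConditionBehavior = field(default_factory=_default_incongruent)

    def for_condition(self, condition: str) -> ConditionBehavior:
        try:
            return getattr(self, condition)
        except AttributeError:
            raise KeyError(f"no behavioural model for condition {condition!r}")


@dataclass
class BoldTruth:
    """Generative ground truth for trial-evoked BOLD amplitudes.

    Each responded trial evokes an amplitude
    ``baseline(condition) + rt_slope * RT + congruency_increment * [incongruent]``
    which is convolved with the HRF.  With ``congruency_increment = 0`` the two
    conditions differ only through their RT distributions, i.e. any apparent
    congruency effect is an RT confound by construction.
    """

    baseline_congruent: float = 0.0  # signal units
    baseline_incongruent: float = 0.0  # signal units
    rt_slope: float = 0.002  # signal units per ms
    congruency_increment: float = 0.0  # signal units
    noise_sd: float = 1.0  # stationary SD of the AR(1) noise, signal units
    ar1: float = 0.3
    drift_amplitude: float = 0.5  # SD of random low-frequency cosine drift terms
    n_drift_terms: int = 3

    def __post_init__(self) -> None:
        if not -1.0 < self.ar1 < 1.0:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise/drift scales must be non-negative")

    def baseline(self, condition: str) -> float:
        if condition == "congruent":
            return self.baseline_congruent
        if condition == "incongruent":
            return self.baseline_incongruent
        raise KeyError(f"no baseline for condition {condition!r}")


@dataclass
class HRFSpec:
    """Canonical double-gamma haemodynamic response function (SPM convention)."""

    peak_delay: float = 6.0  # s
    undershoot_delay: float = 16.0  # s
    peak_dispersion: float = 1.0  # s
    undershoot_dispersion: float = 1.0  # s
    undershoot_ratio: float = 1.0 / 6.0
    microtime_dt: float = 0.1  # s, oversampled grid for convolution
    duration: float = 32.0  # s, kernel support

    def __post_init__(self) -> None:
        positive = (
            self.peak_delay,
            self.undershoot_delay,
            self.peak_dispersion,
            self.undershoot_dispersion,
            self.microtime_dt,
            self.duration,
        )
        if any(v <= 0 for v in positive):
            raise ValueError("HRF timing parameters must be positive")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be non-negative")


@dataclass
class PipelineConfig:
    """Everything needed to simulate and analyse a cohort end to end."""

    n_participants: int = 28
    schedule: ScheduleSpec = field(default_factory=ScheduleSpec)
    rt_model: RTModel = field(default_factory=RTModel)
    bold_truth: BoldTruth = field(default_factory=BoldTruth)
    hrf: HRFSpec = field(default_factory=HRFSpec)
    sd_threshold: float = 3.0  # RT outlier rule, conditional SDs
    hp_cutoff: float = 128.0  # s, high-pass period cutoff
    match_window: float = 10.0  # ms
    rt_orders: int = 4  # polynomial RT modulators, orders 1..rt_orders
    orthogonalize: bool = True
    include_motion: bool = False  # 24-parameter motion expansion as nuisance
    run_equate: bool = True
    run_match: bool = True
    run_subsample: bool = True
    age_range: tuple[float, float] = (8.0, 18.0)  # yrs, for the age covariate
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        if self.match_window < 0:
            raise ValueError("match_window must be non-negative")
        if not 1 <= self.rt_orders <= 4:
            raise ValueError("rt_orders must be in 1..4")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(config: PipelineConfig, path: str | Path) -> None:
    """Write a :class:`PipelineConfig` to YAML."""
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    """Read a :class:`PipelineConfig` from YAML (missing keys take defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return _config_from_dict(raw)


def _config_from_dict(raw: dict) -> PipelineConfig:
    kwargs = dict(raw)
    if "schedule" in kwargs:
        kwargs["schedule"] = ScheduleSpec(**kwargs["schedule"])
    if "rt_model" in kwargs:
        rm = kwargs["rt_model"]
        kwargs["rt_model"] = RTModel(
            congruent=ConditionBehavior(**rm["congruent"]),
            incongruent=ConditionBehavior(**rm["incongruent"]),
        )
    if "bold_truth" in kwargs:
        kwargs["bold_truth"] = BoldTruth(**kwargs["bold_truth"])
    if "hrf" in kwargs:
        kwargs["hrf"] = HRFSpec(**kwargs["hrf"])
    if "age_range" in kwargs:
        kwargs["age_range"] = tuple(kwargs["age_range"])
    return PipelineConfig(**kwargs)
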