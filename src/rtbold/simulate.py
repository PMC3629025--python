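"""Synthetic MSIT datasets with known ground truth.

This module generates everything the analysis consumes: a randomised trial
schedule (24 congruent + 24 incongruent + 12 fixation trials per 3-minute
run), ex-Gaussian reaction times and accuracy flags calibrated to the target
condition means (686.9 / 969.8 ms) and error rates (0.1% / 8.2%), and BOLD
series in which each responded trial evokes an amplitude linear in its RT
(plus an optional genuine congruency increment), convolved with the canonical
HRF and corrupted by low-frequency cosine drift and AR(1) Gaussian noise.

Because the generative truth is recorded alongside every series, parameter
recovery and null calibration of the downstream RT-control procedures can be
checked exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import BoldTruth, HRFSpec, RTModel, ScheduleSpec
from .hrf import canonical_hrf
from .roi import GridSpec, ROISpec, sphere_voxels

__all__ = [
    "SignalSeries",
    "generate_schedule",
    "sample_behavior",
    "synthesize_bold",
    "synthesize_bold_volume",
    "synthesize_motion",
    "simulate_participant",
    "write_dataset",
    "read_series",
]

EVENT_COLUMNS = ["trial_id", "run", "onset", "duration", "trial_type",
                 "response_time", "accuracy"]


@dataclass
class SignalSeries:
    """Sampled BOLD time course(s): volumes x signals, with run structure."""

    data: np.ndarray  # (n_volumes_total, n_signals)
    tr: float
    run: np.ndarray  # 1-based run index per volume
    names: list[str] = field(default_factory=lambda: ["roi"])
    truth: BoldTruth | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] == 1 and len(self.run) != 1:
            self.data = self.data.T
        self.run = np.asarray(self.run, dtype=int)
        if self.data.shape[0] != self.run.shape[0]:
            raise ValueError("one run label required per volume")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_signals(self) -> int:
        return self.data.shape[1]

    def frame_times(self) -> np.ndarray:
        """Within-run acquisition time (s) of each volume."""
        times = np.empty(self.n_volumes)
        for r in np.unique(self.run):
            m = self.run == r
            times[m] = np.arange(m.sum()) * self.tr
        return times

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.data, columns=self.names)
        frame.insert(0, "run", self.run)
        frame.insert(1, "time", self.frame_times())
        return frame


def generate_schedule(spec: ScheduleSpec, seed: int | None = None) -> pd.DataFrame:
    """Randomised trial schedule for one participant.

    Within each run the specified numbers of congruent, incongruent and
    fixation trials are shuffled into a random order; onsets fall at
    consecutive multiples of ``trial_duration`` starting at 0 within the run.
    Fixation trials carry no RT or accuracy.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows = []
    for run in range(1, spec.n_runs + 1):
        conditions = (
            ["congruent"] * spec.n_congruent_per_run
            + ["incongruent"] * spec.n_incongruent_per_run
            + ["fixation"] * spec.n_fixation_per_run
        )
        rng.shuffle(conditions)
        for i, cond in enumerate(conditions):
            duration = (
                spec.trial_duration if cond == "fixation" else spec.stimulus_duration
            )
            rows.append(
                {
                    "trial_id": f"run{run:02d}_t{i:03d}",
                    "run": run,
                    "onset": i * spec.trial_duration,
                    "duration": duration,
                    "trial_type": cond,
                    "response_time": np.nan,
                    "accuracy": np.nan,
                }
            )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def _ex_gaussian(rng: np.random.Generator, mu: float, sigma: float,
                 tau: float, size: int) -> np.ndarray:
    """Positive ex-Gaussian draws (non-positive values redrawn)."""
    rt = rng.normal(mu, sigma, size)
    if tau > 0:
        rt = rt + rng.exponential(tau, size)
    bad = rt <= 0
    while bad.any():
        rt[bad] = rng.normal(mu, sigma, bad.sum()) + (
            rng.exponential(tau, bad.sum()) if tau > 0 else 0.0
        )
        bad = rt <= 0
    return rt


def sample_behavior(table: pd.DataFrame, rt_model: RTModel,
                    seed: int | None = None) -> pd.DataFrame:
    """Attach reaction times and accuracy to a schedule.

    Each non-fixation trial draws an ex-Gaussian RT (truncated at > 0) and an
    accuracy flag; omitted responses get no RT and no accuracy.  Fixation
    trials are left untouched.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    for cond in ("congruent", "incongruent"):
        mask = out["trial_type"] == cond
        n = int(mask.sum())
        if n == 0:
            continue
        params = rt_model.for_condition(cond)
        rt = _ex_gaussian(rng, params.mu, params.sigma, params.tau, n)
        omitted = rng.random(n) < params.p_omission
        errors = rng.random(n) < params.p_error
        rt[omitted] = np.nan
        acc = np.where(errors, 0.0, 1.0)
        acc[omitted] = np.nan
        out.loc[mask, "response_time"] = rt
        out.loc[mask, "accuracy"] = acc
    return out


def _trial_amplitude(row: pd.Series, truth: BoldTruth) -> float:
    amp = truth.baseline(row["trial_type"])
    if np.isfinite(row["response_time"]):
        amp += truth.rt_slope * row["response_time"]
        if row["trial_type"] == "incongruent":
            amp += truth.congruency_increment
    return amp


def _run_layout(table: pd.DataFrame, spec: ScheduleSpec | None,
                tr: float) -> tuple[list[int], float, int]:
    """Runs present, run span (s) and volumes per run."""
    runs = sorted(table["run"].unique()) if len(table) else [1]
    if spec is not None:
        span = spec.run_duration
        tr = spec.tr
    else:
        # infer the span from the trial grid: onsets are consecutive
        # multiples of the trial duration
        onsets = np.sort(table["onset"].unique())
        step = float(np.diff(onsets).min()) if len(onsets) > 1 else tr
        span = (float(table["onset"].max()) + step) if len(table) else 0.0
    n_vols = int(np.ceil(span / tr))
    return [int(r) for r in runs], span, n_vols


def _noise_and_drift(rng: np.random.Generator, truth: BoldTruth, n_vols: int,
                     tr: float, size: int = 1) -> np.ndarray:
    """AR(1) noise (stationary SD = noise_sd) plus random cosine drift.

    Returns an array of shape (n_vols, size).
    """
    out = np.zeros((n_vols, size))
    if truth.noise_sd > 0:
        innov_sd = truth.noise_sd * np.sqrt(1.0 - truth.ar1**2)
        e = rng.normal(0.0, truth.noise_sd, size)
        for t in range(n_vols):
            out[t] = e
            e = truth.ar1 * e + rng.normal(0.0, innov_sd, size)
    if truth.drift_amplitude > 0 and truth.n_drift_terms > 0 and n_vols > 1:
        t = np.arange(n_vols)
        amps = rng.normal(0.0, truth.drift_amplitude,
                          (truth.n_drift_terms, size))
        for k in range(1, truth.n_drift_terms + 1):
            basis = np.cos(np.pi * k * (2 * t + 1) / (2 * n_vols))
            out += basis[:, None] * amps[k - 1]
    return out


def _task_signal(table: pd.DataFrame, truth: BoldTruth, hrf: HRFSpec,
                 runs: list[int], span: float, n_vols: int,
                 tr: float) -> np.ndarray:
    """Noise-free trial-evoked signal, one column per run concatenated."""
    correct_missing = (
        (table["trial_type"] != "fixation")
        & (table["accuracy"] == 1)
        & ~np.isfinite(table["response_time"])
    )
    if correct_missing.any():
        bad = table.loc[correct_missing, "trial_id"].tolist()
        raise ValueError(f"correct trials without an RT: {bad}")
    dt = hrf.microtime_dt
    _, kernel = canonical_hrf(hrf)
    n_micro = int(np.ceil(span / dt))
    vol_idx = np.minimum((np.arange(n_vols) * tr / dt).round().astype(int),
                         max(n_micro - 1, 0))
    signal = np.zeros(len(runs) * n_vols)
    for i, run in enumerate(runs):
        u = np.zeros(n_micro)
        sub = table[(table["run"] == run) & (table["trial_type"] != "fixation")]
        for _, row in sub.iterrows():
            j = int(round(row["onset"] / dt))
            u[min(j, n_micro - 1)] += _trial_amplitude(row, truth)
        conv = np.convolve(u, kernel)[:n_micro]
        signal[i * n_vols:(i + 1) * n_vols] = conv[vol_idx]
    return signal


def synthesize_bold(table: pd.DataFrame, truth: BoldTruth,
                    hrf: HRFSpec | None = None,
                    spec: ScheduleSpec | None = None, tr: float = 2.0,
                    seed: int | None = None) -> SignalSeries:
    """Single-signal (ROI-series) BOLD simulation for one participant.

    Trial amplitudes follow the generative equation in :class:`BoldTruth`;
    impulses at stimulus onsets are convolved with the canonical HRF on the
    microtime grid and sampled at the TR, then cosine drift and AR(1) noise
    are added per run.
    """
    hrf = hrf or HRFSpec()
    runs, span, n_vols = _run_layout(table, spec, tr)
    tr = spec.tr if spec is not None else tr
    rng = np.random.default_rng(seed)
    signal = _task_signal(table, truth, hrf, runs, span, n_vols, tr)
    noise = np.concatenate(
        [_noise_and_drift(rng, truth, n_vols, tr)[:, 0] for _ in runs]
    )
    run_labels = np.repeat(runs, n_vols)
    return SignalSeries(data=signal + noise, tr=tr, run=run_labels,
                        names=["roi"], truth=truth)


def synthesize_bold_volume(table: pd.DataFrame, truth: BoldTruth,
                           grid: GridSpec | None = None,
                           roi: ROISpec | None = None,
                           hrf: HRFSpec | None = None,
                           spec: ScheduleSpec | None = None, tr: float = 2.0,
                           seed: int | None = None):
    """Volumetric BOLD simulation: the task signal is placed in a sphere.

    Voxels whose centres fall inside ``roi`` carry the trial-evoked signal;
    every voxel receives independent drift + AR(1) noise.  Returns a
    ``nibabel.Nifti1Image`` with time as the fourth axis (the grid affine is
    stored in the header) plus the active voxel index array.
    """
    import nibabel as nib

    grid = grid or GridSpec()
    roi = roi or ROISpec()
    hrf = hrf or HRFSpec()
    runs, span, n_vols = _run_layout(table, spec, tr)
    tr = spec.tr if spec is not None else tr
    rng = np.random.default_rng(seed)
    signal = _task_signal(table, truth, hrf, runs, span, n_vols, tr)
    n_total = len(runs) * n_vols
    n_flat = int(np.prod(grid.shape))
    data = np.empty((n_total, n_flat))
    for i in range(len(runs)):
        data[i * n_vols:(i + 1) * n_vols] = _noise_and_drift(
            rng, truth, n_vols, tr, size=n_flat
        )
    active = sphere_voxels(roi, grid)
    flat_active = np.ravel_multi_index(active.T, grid.shape)
    data[:, flat_active] += signal[:, None]
    vol = data.reshape(n_total, *grid.shape).transpose(1, 2, 3, 0)
    img = nib.Nifti1Image(vol.astype(np.float32), grid.affine)
    img.header.set_zooms((*grid.voxel_size, tr))
    return img, active


def synthesize_motion(n_volumes: int, seed: int | None = None,
                      step_sd: float = 0.02) -> np.ndarray:
    """Six smooth random-walk rigid-body motion series (n_volumes x 6)."""
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, step_sd, (n_volumes, 6)).cumsum(axis=0)


def simulate_participant(schedule: ScheduleSpec, rt_model: RTModel,
                         truth: BoldTruth, hrf: HRFSpec | None = None,
                         seed: int | None = None
                         ) -> tuple[pd.DataFrame, SignalSeries]:
    """Convenience wrapper: schedule -> behaviour -> ROI-series BOLD."""
    ss = np.random.SeedSequence(seed)
    s_sched, s_beh, s_bold = [int(c.generate_state(1)[0] % (2**31))
                              for c in ss.spawn(3)]
    table = generate_schedule(schedule, seed=s_sched)
    table = sample_behavior(table, rt_model, seed=s_beh)
    series = synthesize_bold(table, truth, hrf=hrf, spec=schedule, seed=s_bold)
    return table, series


def _format_events(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    out["response_time"] = [
        "n/a" if not np.isfinite(v) else repr(float(v))
        for v in out["response_time"]
    ]
    out["accuracy"] = [
        "n/a" if not np.isfinite(v) else str(int(v)) for v in out["accuracy"]
    ]
    return out


def write_dataset(table: pd.DataFrame, series: SignalSeries | None,
                  path: str | Path) -> list[Path]:
    """Write one participant's events (per-run BIDS-style TSV) and series.

    Events use ``n/a`` for missing RT/accuracy.  The series is written as a
    ``bold.tsv`` (volumes x signals, with run and time columns) plus a JSON
    sidecar carrying the TR.  Returns the written paths; the dataset
    round-trips losslessly through :func:`rtbold.events.read_events` and
    :func:`read_series`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    runs = sorted(table["run"].unique()) if len(table) else []
    if not runs:  # empty table: still emit a valid header-only file
        p = path / "run-01_events.tsv"
        _format_events(table).to_csv(p, sep="\t", index=False)
        written.append(p)
    for run in runs:
        p = path / f"run-{int(run):02d}_events.tsv"
        _format_events(table[table["run"] == run]).to_csv(p, sep="\t", index=False)
        written.append(p)
    if series is not None:
        p = path / "bold.tsv"
        series.to_frame().to_csv(p, sep="\t", index=False)
        written.append(p)
        meta = path / "bold.json"
        meta.write_text(json.dumps({"tr": series.tr, "names": series.names}))
        written.append(meta)
    return written


def read_series(path: str | Path) -> SignalSeries:
    """Read a ``bold.tsv`` + ``bold.json`` pair written by :func:`write_dataset`."""
    path = Path(path)
    meta = json.loads((path / "bold.json").read_text())
    frame = pd.read_csv(path / "bold.tsv", sep="\t")
    names = list(meta["names"])
    return SignalSeries(data=frame[names].to_numpy(), tr=float(meta["tr"]),
                        run=frame["run"].to_numpy(), names=names)
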