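"""First-level design matrices.

Each condition of interest contributes a main regressor (unit impulses at
stimulus onsets convolved with the canonical HRF) and, in the full model,
polynomial RT modulators of orders 1-4 whose impulse weights are powers of
the mean-centred RT of that condition, applied *before* convolution.  Higher
orders are sequentially orthogonalised against the main column and lower
orders of the same condition (switchable), mirroring the SPM convention.
Nuisance structure comprises per-run discrete-cosine high-pass columns
(periods above the cutoff, default 128 s), per-run constants, and optionally
a 24-parameter motion expansion (the six rigid-body series, their squares,
derivatives and squared derivatives).

RT weights are raw millisecond deviations, so the order-1 coefficient is in
signal units per ms — the scale the RT-equating contrast needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import HRFSpec
from .events import CONDITIONS, FilterResult
from .hrf import canonical_hrf

__all__ = [
    "DesignMatrix",
    "build_design",
    "build_matched_design",
    "build_subsampled_design",
    "motion_expansion",
    "cosine_drift_basis",
]


class DesignError(ValueError):
    pass


@dataclass
class DesignMatrix:
    """Time x regressor matrix with named columns and run structure."""

    frame: pd.DataFrame
    run: np.ndarray
    tr: float
    conditional_means: dict[str, float] = field(default_factory=dict)
    omitted: list[str] = field(default_factory=list)

    @property
    def n_volumes(self) -> int:
        return len(self.frame)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def cosine_drift_basis(n_volumes: int, tr: float, hp_cutoff: float) -> np.ndarray:
    """Unit-norm DCT-II columns with periods longer than ``hp_cutoff`` seconds.

    Component k has period 2 * n * tr / k; k runs from 1 to
    floor(2 * n * tr / hp_cutoff).  The constant (k = 0) is excluded.
    """
    if n_volumes == 0 or hp_cutoff <= 0:
        return np.zeros((n_volumes, 0))
    k_max = int(np.floor(2.0 * n_volumes * tr / hp_cutoff))
    t = np.arange(n_volumes)
    cols = [
        np.sqrt(2.0 / n_volumes) * np.cos(np.pi * k * (2 * t + 1) / (2 * n_volumes))
        for k in range(1, k_max + 1)
    ]
    return np.column_stack(cols) if cols else np.zeros((n_volumes, 0))


def motion_expansion(motion: np.ndarray, run: np.ndarray) -> np.ndarray:
    """24-parameter expansion of six motion series.

    Columns: the six series, their squares, their first differences (zero at
    each run start) and the squared differences.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise DesignError("motion must be an (n_volumes, 6) array")
    deriv = np.zeros_like(motion)
    for r in np.unique(run):
        m = np.flatnonzero(run == r)
        deriv[m[1:]] = motion[m[1:]] - motion[m[:-1]]
    return np.hstack([motion, motion**2, deriv, deriv**2])


def _convolve_runs(onsets_by_run: dict[int, tuple[np.ndarray, np.ndarray]],
                   runs: list[int], n_vols: int, tr: float,
                   hrf: HRFSpec) -> np.ndarray:
    """Convolve weighted impulse trains with the HRF, sample at the TR."""
    dt = hrf.microtime_dt
    _, kernel = canonical_hrf(hrf)
    span = n_vols * tr
    n_micro = int(np.ceil(span / dt))
    vol_idx = np.minimum((np.arange(n_vols) * tr / dt).round().astype(int),
                         n_micro - 1)
    out = np.zeros(len(runs) * n_vols)
    for i, r in enumerate(runs):
        if r not in onsets_by_run:
            continue
        onsets, weights = onsets_by_run[r]
        u = np.zeros(n_micro)
        idx = np.minimum((np.asarray(onsets) / dt).round().astype(int),
                         n_micro - 1)
        np.add.at(u, idx, weights)
        conv = np.convolve(u, kernel)[:n_micro]
        out[i * n_vols:(i + 1) * n_vols] = conv[vol_idx]
    return out


def _grouped(table: pd.DataFrame, ids: list[str],
             weights: dict[str, float] | None = None):
    """Onsets (and weights) per run for the given trial ids."""
    sub = table[table["trial_id"].isin(ids)]
    missing = set(ids) - set(sub["trial_id"])
    if missing:
        raise DesignError(f"trial ids absent from table: {sorted(missing)}")
    by_run: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for r, grp in sub.groupby("run"):
        w = (
            np.array([weights[t] for t in grp["trial_id"]])
            if weights is not None
            else np.ones(len(grp))
        )
        by_run[int(r)] = (grp["onset"].to_numpy(dtype=float), w)
    return by_run


def _orthogonalize_block(block: np.ndarray) -> np.ndarray:
    """Sequentially residualise each column against the preceding ones."""
    out = block.copy()
    for j in range(1, out.shape[1]):
        prev = out[:, :j]
        coef, *_ = np.linalg.lstsq(prev, out[:, j], rcond=None)
        out[:, j] = out[:, j] - prev @ coef
    return out


def _assemble(columns: dict[str, np.ndarray], runs: list[int], n_vols: int,
              tr: float, hp_cutoff: float,
              motion: np.ndarray | None) -> tuple[pd.DataFrame, np.ndarray]:
    run_labels = np.repeat(runs, n_vols)
    frame = pd.DataFrame(columns)
    if motion is not None:
        m24 = motion_expansion(motion, run_labels)
        for j in range(24):
            frame[f"motion_{j + 1:02d}"] = m24[:, j]
    for i, r in enumerate(runs):
        basis = cosine_drift_basis(n_vols, tr, hp_cutoff)
        for k in range(basis.shape[1]):
            col = np.zeros(len(run_labels))
            col[i * n_vols:(i + 1) * n_vols] = basis[:, k]
            frame[f"run{r}_cos{k + 1}"] = col
        const = np.zeros(len(run_labels))
        const[i * n_vols:(i + 1) * n_vols] = 1.0
        frame[f"run{r}_const"] = const
    return frame, run_labels


def _class_columns(table: pd.DataFrame, filt: FilterResult,
                   classes: dict[str, list[str]], runs: list[int],
                   n_vols: int, tr: float, hrf: HRFSpec):
    """Unmodulated columns for trial classes plus error/excluded columns."""
    columns: dict[str, np.ndarray] = {}
    omitted: list[str] = []
    for name, ids in classes.items():
        if not ids:
            omitted.append(name)
            continue
        columns[name] = _convolve_runs(_grouped(table, ids), runs, n_vols, tr, hrf)
    for reason_name, reasons in (
        ("error", ["error"]),
        ("excluded", ["omission", "rt_outlier"]),
    ):
        ids = filt.excluded.loc[
            filt.excluded["reason"].isin(reasons), "trial_id"
        ].tolist()
        # omissions have no onset weight issue: weight 1 at onset
        if ids:
            columns[reason_name] = _convolve_runs(
                _grouped(table, ids), runs, n_vols, tr, hrf
            )
        else:
            omitted.append(reason_name)
    return columns, omitted


def _layout(table: pd.DataFrame, tr: float,
            n_volumes_per_run: int) -> tuple[list[int], int]:
    if n_volumes_per_run <= 0:
        raise DesignError("n_volumes_per_run must be positive")
    runs = sorted(int(r) for r in table["run"].unique()) if len(table) else [1]
    last = float(table["onset"].max()) if len(table) else 0.0
    if last >= n_volumes_per_run * tr:
        raise DesignError("trial onsets extend beyond the sampled run")
    return runs, n_volumes_per_run


def build_design(table: pd.DataFrame, filt: FilterResult, tr: float,
                 n_volumes_per_run: int, hrf: HRFSpec | None = None,
                 hp_cutoff: float = 128.0, motion: np.ndarray | None = None,
                 rt_orders: int = 4, orthogonalize: bool = True) -> DesignMatrix:
    """Full first-level design: condition mains + polynomial RT modulators.

    For each condition of interest the retained correct trials contribute a
    main column and modulator columns of orders ``1..rt_orders`` built from
    mean-centred RTs (centred on that condition's retained-trial mean).
    Error and excluded trials get their own unmodulated columns; per-run
    cosine high-pass columns and constants close the model.
    """
    hrf = hrf or HRFSpec()
    runs, n_vols = _layout(table, tr, n_volumes_per_run)
    rt_by_id = dict(zip(table["trial_id"], table["response_time"]))

    columns: dict[str, np.ndarray] = {}
    omitted: list[str] = []
    means: dict[str, float] = {}
    for cond in CONDITIONS:
        ids = filt.retained[f"correct_{cond}"]
        if not ids:
            omitted.append(cond)
            continue
        mean_rt = filt.mean_rt(cond)
        means[cond] = mean_rt
        block_cols = [_convolve_runs(_grouped(table, ids), runs, n_vols, tr, hrf)]
        names = [cond]
        for p in range(1, rt_orders + 1):
            weights = {t: (rt_by_id[t] - mean_rt) ** p for t in ids}
            col = _convolve_runs(
                _grouped(table, ids, weights), runs, n_vols, tr, hrf
            )
            block_cols.append(col)
            names.append(f"{cond}_rt{p}")
        block = np.column_stack(block_cols)
        if orthogonalize:
            block = _orthogonalize_block(block)
        for name, col in zip(names, block.T):
            if np.allclose(col, 0.0):  # e.g. all RTs equal -> zero modulator
                if name != f"{cond}_rt1":
                    omitted.append(name)
                    continue
            columns[name] = col

    extra, extra_omitted = _class_columns(table, filt, {}, runs, n_vols, tr, hrf)
    columns.update(extra)
    omitted += extra_omitted

    frame, run_labels = _assemble(columns, runs, n_vols, tr, hp_cutoff, motion)
    return DesignMatrix(frame=frame, run=run_labels, tr=tr,
                        conditional_means=means, omitted=omitted)


def build_matched_design(table: pd.DataFrame, filt: FilterResult, matched,
                         tr: float, n_volumes_per_run: int,
                         hrf: HRFSpec | None = None, hp_cutoff: float = 128.0,
                         motion: np.ndarray | None = None) -> DesignMatrix:
    """First-level design for the RT-matched analysis.

    Categorical regressors only: (a) RT-matched congruent trials,
    (b) RT-matched incongruent trials, (c) non-matched correct trials,
    (d) error trials (plus the excluded-trial column and nuisance terms).
    """
    hrf = hrf or HRFSpec()
    runs, n_vols = _layout(table, tr, n_volumes_per_run)
    matched_c = [p.congruent_id for p in matched.pairs]
    matched_i = [p.incongruent_id for p in matched.pairs]
    selected = set(matched_c) | set(matched_i)
    unmatched = [t for t in filt.retained_ids() if t not in selected]
    classes = {
        "matched_congruent": matched_c,
        "matched_incongruent": matched_i,
        "unmatched_correct": unmatched,
    }
    columns, omitted = _class_columns(table, filt, classes, runs, n_vols, tr, hrf)
    frame, run_labels = _assemble(columns, runs, n_vols, tr, hp_cutoff, motion)
    return DesignMatrix(frame=frame, run=run_labels, tr=tr, omitted=omitted)


def build_subsampled_design(table: pd.DataFrame, filt: FilterResult, sub,
                            tr: float, n_volumes_per_run: int,
                            hrf: HRFSpec | None = None,
                            hp_cutoff: float = 128.0,
                            motion: np.ndarray | None = None) -> DesignMatrix:
    """First-level design for the RT-subsampled analysis (categorical only)."""
    hrf = hrf or HRFSpec()
    runs, n_vols = _layout(table, tr, n_volumes_per_run)
    sel_c = list(sub.selected["congruent"])
    sel_i = list(sub.selected["incongruent"])
    selected = set(sel_c) | set(sel_i)
    other = [t for t in filt.retained_ids() if t not in selected]
    classes = {
        "subsampled_congruent": sel_c,
        "subsampled_incongruent": sel_i,
        "other_correct": other,
    }
    columns, omitted = _class_columns(table, filt, classes, runs, n_vols, tr, hrf)
    frame, run_labels = _assemble(columns, runs, n_vols, tr, hp_cutoff, motion)
    return DesignMatrix(frame=frame, run=run_labels, tr=tr, omitted=omitted)
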