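"""Trial event tables: reading, validation and trial exclusion.

The exclusion rule mirrors standard first-level practice for RT analyses:
error trials and response omissions are set aside, and among the remaining
correct trials any RT further than ``sd_threshold`` (default 3) conditional
standard deviations from its condition's mean is excluded as an outlier.
Bounds are computed once from the pre-exclusion correct-trial set (a single
pass, no iteration), use the sample (n-1) SD, and the inequality is strict,
so a trial exactly at the bound is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import EVENT_COLUMNS

__all__ = ["FilterResult", "read_events", "validate", "filter_trials"]

logger = logging.getLogger(__name__)

CONDITIONS = ("congruent", "incongruent")


class EventsParseError(ValueError):
    """Raised when an events file cannot be parsed into a trial table."""


@dataclass
class FilterResult:
    """Partition of the non-fixation trials into retained and excluded sets.

    ``retained`` maps ``correct_congruent`` / ``correct_incongruent`` to trial
    ids; ``excluded`` lists every removed trial with a reason (``error``,
    ``omission`` or ``rt_outlier``).  ``summaries`` holds per-condition mean
    RT, SD and n of the retained correct trials (the quantities downstream
    mean-centering and RT-equating use); ``bounds`` records the pre-exclusion
    outlier bounds actually applied.
    """

    retained: dict[str, list[str]]
    excluded: pd.DataFrame  # columns: trial_id, reason
    summaries: pd.DataFrame  # index: condition; columns: mean_rt, sd_rt, n
    bounds: dict[str, tuple[float, float]]

    def retained_ids(self) -> list[str]:
        return self.retained["correct_congruent"] + self.retained["correct_incongruent"]

    def mean_rt(self, condition: str) -> float:
        return float(self.summaries.loc[condition, "mean_rt"])

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    def to_frame(self) -> pd.DataFrame:
        """Flat audit table: one row per non-fixation trial with class/reason."""
        rows = [
            {"trial_id": tid, "class": cls}
            for cls, ids in self.retained.items()
            for tid in ids
        ]
        rows += [
            {"trial_id": r.trial_id, "class": f"excluded:{r.reason}"}
            for r in self.excluded.itertuples()
        ]
        return pd.DataFrame(rows, columns=["trial_id", "class"])


def read_events(paths: str | Path | list[str | Path]) -> pd.DataFrame:
    """Read one or more BIDS-style events TSVs into a single trial table.

    ``n/a`` entries become NaN; rows are ordered by (run, onset).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = []
    for path in paths:
        try:
            frame = pd.read_csv(path, sep="\t", na_values=["n/a"],
                                keep_default_na=True)
        except Exception as exc:  # pragma: no cover - pandas message varies
            raise EventsParseError(f"{path}: {exc}") from exc
        missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
        if missing:
            raise EventsParseError(f"{path}: missing columns {missing}")
        for line, onset in enumerate(frame["onset"], start=2):
            if not np.isfinite(onset):
                raise EventsParseError(f"{path}, line {line}: malformed onset")
        frames.append(frame[EVENT_COLUMNS])
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=EVENT_COLUMNS
    )
    for col in ("onset", "duration", "response_time", "accuracy"):
        table[col] = pd.to_numeric(table[col], errors="coerce")
    return table.sort_values(["run", "onset"], kind="stable").reset_index(drop=True)


def validate(table: pd.DataFrame) -> list[str]:
    """Check structural invariants of a trial table; returns a list of issues."""
    issues = []
    dup = table["trial_id"][table["trial_id"].duplicated()]
    for tid in dup.unique():
        issues.append(f"duplicate trial_id {tid!r}")
    neg = table[table["onset"] < 0]
    for tid in neg["trial_id"]:
        issues.append(f"negative onset for trial {tid!r}")
    known = set(CONDITIONS) | {"fixation"}
    bad_cond = table[~table["trial_type"].isin(known)]
    for tid, cond in zip(bad_cond["trial_id"], bad_cond["trial_type"]):
        issues.append(f"unknown trial_type {cond!r} for trial {tid!r}")
    bad_rt = table[table["response_time"] <= 0]
    for tid in bad_rt["trial_id"]:
        issues.append(f"non-positive RT for trial {tid!r}")
    fix = table[table["trial_type"] == "fixation"]
    for tid in fix.loc[np.isfinite(fix["response_time"]), "trial_id"]:
        issues.append(f"fixation trial {tid!r} carries an RT")
    return issues


def filter_trials(table: pd.DataFrame, sd_threshold: float = 3.0) -> FilterResult:
    """Partition non-fixation trials into retained correct trials and exclusions.

    Errors (``accuracy == 0``) and omissions (missing RT or missing accuracy)
    are excluded with their reason.  Among correct trials, per condition, an
    RT strictly further than ``sd_threshold`` sample SDs from the conditional
    mean is excluded as ``rt_outlier``.  A condition with fewer than two
    correct trials has no defined SD: no outlier exclusion is applied there
    and a warning is logged.
    """
    task = table[table["trial_type"].isin(CONDITIONS)].copy()
    for col in ("response_time", "accuracy"):
        task[col] = pd.to_numeric(task[col], errors="coerce")
    excluded: list[dict] = []
    retained: dict[str, list[str]] = {
        "correct_congruent": [],
        "correct_incongruent": [],
    }
    bounds: dict[str, tuple[float, float]] = {}

    omitted = ~np.isfinite(task["response_time"]) | ~np.isfinite(task["accuracy"])
    errors = ~omitted & (task["accuracy"] == 0)
    for tid in task.loc[omitted, "trial_id"]:
        excluded.append({"trial_id": tid, "reason": "omission"})
    for tid in task.loc[errors, "trial_id"]:
        excluded.append({"trial_id": tid, "reason": "error"})

    correct = task[~omitted & ~errors]
    summary_rows = []
    for cond in CONDITIONS:
        sub = correct[correct["trial_type"] == cond]
        rt = sub["response_time"].to_numpy(dtype=float)
        if len(rt) >= 2:
            mean, sd = float(rt.mean()), float(rt.std(ddof=1))
            lo, hi = mean - sd_threshold * sd, mean + sd_threshold * sd
        else:
            logger.warning(
                "condition %r has %d correct trial(s); conditional SD "
                "undefined, skipping outlier exclusion", cond, len(rt)
            )
            lo, hi = -np.inf, np.inf
        bounds[cond] = (lo, hi)
        keep = (rt >= lo) & (rt <= hi)  # strict rule: exactly at bound stays
        for tid in sub.loc[~keep, "trial_id"]:
            excluded.append({"trial_id": tid, "reason": "rt_outlier"})
        kept_ids = sub.loc[keep, "trial_id"].tolist()
        retained[f"correct_{cond}"] = kept_ids
        kept_rt = rt[keep]
        summary_rows.append(
            {
                "condition": cond,
                "mean_rt": float(kept_rt.mean()) if len(kept_rt) else np.nan,
                "sd_rt": float(kept_rt.std(ddof=1)) if len(kept_rt) > 1 else np.nan,
                "n": int(len(kept_rt)),
            }
        )

    return FilterResult(
        retained=retained,
        excluded=pd.DataFrame(excluded, columns=["trial_id", "reason"]),
        summaries=pd.DataFrame(summary_rows).set_index("condition"),
        bounds=bounds,
    )
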