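"""End-to-end orchestration: simulate -> filter -> fit -> RT-control -> group.

`run_experiment` simulates a cohort, analyses every participant (full model,
RT-equated contrast, RT-matched model, RT-subsampled model) and computes the
group statistics; `run_pipeline` additionally writes all artefacts and a
manifest to disk.  All randomness descends from a single seed through
`numpy.random.SeedSequence`, so a fixed seed gives a bit-identical result
bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, ScheduleSpec, _to_plain
from .design import build_design, build_matched_design, build_subsampled_design
from .events import FilterResult, filter_trials
from .group import GroupResult, ancova_age, congruency_by_sampling_anova, one_sample_t
from .model import FirstLevelModel
from .rt_control import (
    MatchedSet,
    SubsampledSet,
    match_trials,
    rt_equate,
    subsample_trials,
)
from .simulate import SignalSeries, simulate_participant, synthesize_motion

__all__ = ["ParticipantResult", "ExperimentResult", "analyze_participant",
           "run_experiment", "run_pipeline", "group_rt_congruency_effect"]

logger = logging.getLogger(__name__)

ANALYSES = ("full", "equated", "matched", "subsampled")


@dataclass
class ParticipantResult:
    """Per-participant effect estimates and bookkeeping."""

    participant: str
    filter_result: FilterResult
    effects: dict[str, float]  # analysis -> congruency effect (signal units)
    rt_effects: dict[str, float]  # analysis -> behavioural effect (ms)
    matched: MatchedSet | None = None
    subsampled: SubsampledSet | None = None
    n_retained: int = 0
    ar1: float = np.nan


@dataclass
class ExperimentResult:
    """Cohort-level bundle: per-participant results plus group statistics."""

    config: PipelineConfig
    participants: list[ParticipantResult]
    group: dict[str, GroupResult] = field(default_factory=dict)
    ages: np.ndarray | None = None
    timings: dict[str, float] = field(default_factory=dict)

    def effects_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            row = {"participant": p.participant, "n_retained": p.n_retained}
            row.update({a: p.effects.get(a, np.nan) for a in ANALYSES})
            row.update(
                {f"rt_{a}": p.rt_effects.get(a, np.nan)
                 for a in ("full", "matched", "subsampled")}
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        frame = self.effects_frame()
        lines = [
            "RT-controlled congruency analysis",
            "=" * 56,
            f"participants: {len(self.participants)}",
        ]
        for a in ("full", "matched", "subsampled"):
            col = frame[f"rt_{a}"]
            if col.notna().any():
                lines.append(
                    f"behavioural congruency effect ({a}): "
                    f"{col.mean():.1f} ms"
                )
        lines.append("-" * 56)
        for name in ANALYSES:
            if name in self.group:
                lines.append(f"{name:<11s} {self.group[name]}")
        for name in ("anova_congruency", "anova_interaction",
                     "ancova_congruency_at_mean_age", "ancova_age_slope"):
            if name in self.group:
                lines.append(f"{name:<11s} {self.group[name]}")
        lines.append("=" * 56)
        return "\n".join(lines)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def group_rt_congruency_effect(config: PipelineConfig,
                               seed: int | None = None) -> tuple[float, int]:
    """Behavioural congruency effect of a simulated cohort.

    Simulates ``config.n_participants`` participants (schedule + behaviour
    only), applies the trial filter, and returns the across-participant mean
    of (mean retained incongruent RT - mean retained congruent RT) in ms,
    together with the cohort size.
    """
    from .simulate import generate_schedule, sample_behavior

    seed = config.seed if seed is None else seed
    seeds = _child_seeds(seed, config.n_participants)
    diffs = []
    for s in seeds:
        ss = np.random.SeedSequence(s)
        s_sched, s_beh = [int(c.generate_state(1)[0] % (2**31))
                          for c in ss.spawn(3)[:2]]
        table = generate_schedule(config.schedule, seed=s_sched)
        table = sample_behavior(table, config.rt_model, seed=s_beh)
        filt = filter_trials(table, sd_threshold=config.sd_threshold)
        diffs.append(filt.mean_rt("incongruent") - filt.mean_rt("congruent"))
    return float(np.mean(diffs)), config.n_participants


def analyze_participant(table: pd.DataFrame, series: SignalSeries,
                        config: PipelineConfig, participant: str = "sub-01",
                        motion: np.ndarray | None = None) -> ParticipantResult:
    """Run every enabled analysis on one participant's data."""
    spec: ScheduleSpec = config.schedule
    filt = filter_trials(table, sd_threshold=config.sd_threshold)
    kwargs = dict(
        tr=spec.tr,
        n_volumes_per_run=spec.n_volumes_per_run,
        hrf=config.hrf,
        hp_cutoff=config.hp_cutoff,
        motion=motion,
    )
    design = build_design(
        table, filt, rt_orders=config.rt_orders,
        orthogonalize=config.orthogonalize, **kwargs
    )
    fit = FirstLevelModel(series, design).fit()

    rt_by_id = dict(zip(table["trial_id"], table["response_time"]))
    cong = [(t, rt_by_id[t]) for t in filt.retained["correct_congruent"]]
    incong = [(t, rt_by_id[t]) for t in filt.retained["correct_incongruent"]]

    effects = {"full": fit.coef("incongruent") - fit.coef("congruent")}
    rt_effects = {
        "full": filt.mean_rt("incongruent") - filt.mean_rt("congruent")
    }
    result = ParticipantResult(
        participant=participant,
        filter_result=filt,
        effects=effects,
        rt_effects=rt_effects,
        n_retained=len(filt.retained_ids()),
        ar1=float(fit.ar1[0]),
    )

    if config.run_equate:
        eq = rt_equate(fit, filt.mean_rt("congruent"),
                       filt.mean_rt("incongruent"))
        effects["equated"] = eq.contrast

    matched = None
    if config.run_match or config.run_subsample:
        matched = match_trials(cong, incong, window=config.match_window)
        result.matched = matched
    if config.run_match and matched is not None and len(matched):
        mdesign = build_matched_design(table, filt, matched, **kwargs)
        mfit = FirstLevelModel(series, mdesign).fit()
        effects["matched"] = (
            mfit.coef("matched_incongruent") - mfit.coef("matched_congruent")
        )
        rt_effects["matched"] = matched.rt_effect()
    if config.run_subsample and matched is not None and len(matched):
        sub = subsample_trials(cong, incong, k=len(matched))
        result.subsampled = sub
        sdesign = build_subsampled_design(table, filt, sub, **kwargs)
        sfit = FirstLevelModel(series, sdesign).fit()
        effects["subsampled"] = (
            sfit.coef("subsampled_incongruent") - sfit.coef("subsampled_congruent")
        )
        sel_rt = {
            c: np.mean([rt_by_id[t] for t in sub.selected[c]])
            for c in ("congruent", "incongruent")
        }
        rt_effects["subsampled"] = float(
            sel_rt["incongruent"] - sel_rt["congruent"]
        )
    return result


def run_experiment(config: PipelineConfig,
                   seed: int | None = None) -> ExperimentResult:
    """Simulate and analyse a full cohort; compute group statistics."""
    seed = config.seed if seed is None else seed
    n = config.n_participants
    seeds = _child_seeds(seed, n + 1)
    age_rng = np.random.default_rng(seeds[-1])
    ages = age_rng.uniform(*config.age_range, size=n)

    t0 = time.perf_counter()
    participants = []
    for i in range(n):
        table, series = simulate_participant(
            config.schedule, config.rt_model, config.bold_truth,
            hrf=config.hrf, seed=seeds[i],
        )
        motion = (
            synthesize_motion(series.n_volumes, seed=seeds[i])
            if config.include_motion else None
        )
        participants.append(
            analyze_participant(table, series, config,
                                participant=f"sub-{i + 1:02d}", motion=motion)
        )
    t1 = time.perf_counter()

    result = ExperimentResult(config=config, participants=participants,
                              ages=ages)
    if n < 2:
        warnings.warn("fewer than two participants: group statistics skipped",
                      stacklevel=2)
    else:
        frame = result.effects_frame()
        for a in ANALYSES:
            vals = frame[a].dropna()
            if len(vals) >= 2 and vals.std(ddof=1) > 0:
                result.group[a] = one_sample_t(vals)
        if {"matched", "subsampled"} <= set(frame.columns):
            m, s = frame["matched"], frame["subsampled"]
            if m.notna().all() and s.notna().all():
                anova = congruency_by_sampling_anova(m, s)
                result.group["anova_congruency"] = anova["congruency"]
                result.group["anova_interaction"] = anova["interaction"]
        if config.run_equate and frame["full"].notna().all():
            anc = ancova_age(frame["full"], ages)
            result.group["ancova_congruency_at_mean_age"] = anc[
                "congruency_at_mean_age"
            ]
            result.group["ancova_age_slope"] = anc["age_slope"]
    result.timings = {"participants_s": t1 - t0,
                      "group_s": time.perf_counter() - t1}
    return result


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(_to_plain(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig,
                 output_dir: str | Path | None = None) -> ExperimentResult:
    """Run the full pipeline and persist artefacts + manifest to disk."""
    out = Path(output_dir or config.output_dir or "rtbold_output")
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: %d participants, seed %d",
                config.n_participants, config.seed)
    result = run_experiment(config)

    result.effects_frame().to_csv(out / "effects.tsv", sep="\t", index=False)
    group_json = {
        name: dataclasses.asdict(res) for name, res in result.group.items()
    }
    (out / "group_stats.json").write_text(
        json.dumps(group_json, indent=2, sort_keys=True)
    )
    for p in result.participants:
        pdir = out / p.participant
        pdir.mkdir(exist_ok=True)
        p.filter_result.to_frame().to_csv(pdir / "filter_report.tsv",
                                          sep="\t", index=False)
        if p.matched is not None:
            pd.DataFrame(p.matched.to_records()).to_csv(
                pdir / "matched_pairs.tsv", sep="\t", index=False
            )
        if p.subsampled is not None:
            rows = [
                {"condition": c, "trial_id": t}
                for c, ids in p.subsampled.selected.items()
                for t in ids
            ]
            pd.DataFrame(rows).to_csv(pdir / "subsampled.tsv", sep="\t",
                                      index=False)
    (out / "summary.txt").write_text(result.summary() + "\n")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "n_participants": config.n_participants,
        "timings": result.timings,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    logger.info("pipeline done: artefacts in %s", out)
    return result
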