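"""The three RT-control procedures.

A congruency contrast (incongruent minus congruent BOLD amplitude) confounds
genuine condition differences with the fact that incongruent trials are
simply slower.  Three complementary controls are implemented:

* **RT-equating** extrapolates congruent activity to the incongruent mean RT
  using the within-condition RT-BOLD slope: ``congruent_eq = beta_cong +
  slope_cong * (mean_rt_incong - mean_rt_cong)``; the controlled contrast is
  ``beta_incong - congruent_eq``.
* **RT-matching** pairs congruent with incongruent trials whose RTs differ by
  at most a tolerance window (default 10 ms), maximising the number of pairs;
  the contrast is then computed between the matched subsets.
* **RT-subsampling** draws the same *number* of trials per condition as the
  matched set, at uniform strides through the RT-sorted lists, preserving
  each condition's native RT distribution — a power control for the matched
  analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RTEquatedContrast",
    "MatchedPair",
    "MatchedSet",
    "SubsampledSet",
    "rt_equate",
    "match_trials",
    "subsample_trials",
]


@dataclass
class RTEquatedContrast:
    """Regression-derived congruency contrast at equated mean RT."""

    beta_cong_main: float
    beta_incong_main: float
    slope_cong: float  # signal units per ms
    mean_rt_cong: float  # ms
    mean_rt_incong: float  # ms
    congruent_eq: float = field(init=False)
    contrast: float = field(init=False)
    uncorrected: float = field(init=False)

    def __post_init__(self) -> None:
        delta = self.mean_rt_incong - self.mean_rt_cong
        self.congruent_eq = self.beta_cong_main + self.slope_cong * delta
        self.contrast = self.beta_incong_main - self.congruent_eq
        self.uncorrected = self.beta_incong_main - self.beta_cong_main


def rt_equate(fit, mean_rt_cong: float, mean_rt_incong: float,
              signal: int | str = 0) -> RTEquatedContrast:
    """RT-equated congruency contrast from a fitted full model.

    ``fit`` is a :class:`~rtbold.model.FirstLevelResults` whose design
    contains the ``congruent``, ``congruent_rt1`` and ``incongruent``
    regressors; the conditional mean RTs come from the trial filter
    summaries.  Raises ``KeyError`` when a required coefficient is missing.
    """
    return RTEquatedContrast(
        beta_cong_main=fit.coef("congruent", signal),
        beta_incong_main=fit.coef("incongruent", signal),
        slope_cong=fit.coef("congruent_rt1", signal),
        mean_rt_cong=float(mean_rt_cong),
        mean_rt_incong=float(mean_rt_incong),
    )


@dataclass(frozen=True)
class MatchedPair:
    congruent_id: str
    incongruent_id: str
    rt_congruent: float
    rt_incongruent: float


@dataclass
class MatchedSet:
    """Disjoint congruent/incongruent trial pairs with |RT difference| <= window."""

    pairs: list[MatchedPair]
    window: float

    def __post_init__(self) -> None:
        for p in self.pairs:
            if abs(p.rt_congruent - p.rt_incongruent) > self.window + 1e-9:
                raise ValueError(
                    f"pair ({p.congruent_id}, {p.incongruent_id}) violates the "
                    f"{self.window} ms window"
                )
        ids = [p.congruent_id for p in self.pairs] + [
            p.incongruent_id for p in self.pairs
        ]
        if len(set(ids)) != len(ids):
            raise ValueError("a trial appears in more than one pair")

    def __len__(self) -> int:
        return len(self.pairs)

    def rt_effect(self) -> float:
        """Mean incongruent RT minus mean congruent RT over the pairs (ms)."""
        if not self.pairs:
            return 0.0
        return float(
            np.mean([p.rt_incongruent for p in self.pairs])
            - np.mean([p.rt_congruent for p in self.pairs])
        )

    def to_records(self) -> list[dict]:
        return [
            {
                "congruent_id": p.congruent_id,
                "incongruent_id": p.incongruent_id,
                "rt_congruent": p.rt_congruent,
                "rt_incongruent": p.rt_incongruent,
            }
            for p in self.pairs
        ]


def _sorted_by_rt(trials) -> list[tuple[str, float]]:
    items = [(str(t), float(rt)) for t, rt in trials]
    for t, rt in items:
        if not np.isfinite(rt) or rt <= 0:
            raise ValueError(f"trial {t!r} has invalid RT {rt}")
    return sorted(items, key=lambda x: (x[1], x[0]))


def match_trials(congruent, incongruent, window: float = 10.0) -> MatchedSet:
    """Maximum-cardinality RT matching within a tolerance window.

    Both inputs are sequences of ``(trial_id, rt_ms)``.  Trials are RT-sorted
    (ties broken by id) and paired by a two-pointer greedy sweep, which
    attains the maximum matching for this interval structure: an edge joins a
    congruent and an incongruent trial iff their RTs differ by at most
    ``window`` ms, and each trial enters at most one pair.  Deterministic.
    """
    cong = _sorted_by_rt(congruent)
    incong = _sorted_by_rt(incongruent)
    pairs: list[MatchedPair] = []
    i = j = 0
    while i < len(cong) and j < len(incong):
        cid, crt = cong[i]
        iid, irt = incong[j]
        if abs(crt - irt) <= window:
            pairs.append(MatchedPair(cid, iid, crt, irt))
            i += 1
            j += 1
        elif crt < irt:
            i += 1
        else:
            j += 1
    return MatchedSet(pairs=pairs, window=window)


@dataclass
class SubsampledSet:
    """Uniform-stride selection from RT-sorted trial lists, k per condition."""

    selected: dict[str, list[str]]  # condition -> trial ids
    target_k: int

    def __len__(self) -> int:
        return self.target_k


def subsample_trials(congruent, incongruent, k: int,
                     centered: bool = False) -> SubsampledSet:
    """Select ``k`` trials per condition at uniform intervals through RT.

    Each condition's trials are sorted by RT and the indices
    ``floor(j * n / k)`` for ``j = 0..k-1`` are selected (``floor((j + 0.5) *
    n / k)`` with ``centered=True``), so the selection walks the RT
    distribution at stride ``n / k`` and preserves its shape.
    """
    out: dict[str, list[str]] = {}
    for name, trials in (("congruent", congruent), ("incongruent", incongruent)):
        items = _sorted_by_rt(trials)
        n = len(items)
        if k > n:
            raise ValueError(
                f"cannot select {k} trials from {n} {name} trials"
            )
        if k < 0:
            raise ValueError("k must be non-negative")
        offset = 0.5 if centered else 0.0
        idx = [int(np.floor((j + offset) * n / k)) for j in range(k)] if k else []
        out[name] = [items[i][0] for i in idx]
    return SubsampledSet(selected=out, target_k=k)
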