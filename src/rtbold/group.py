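"""Group-level (random-effects) statistics.

Inference follows the summary-statistics approach: one effect estimate per
participant enters a second-level test, so conclusions generalise to the
population.  The 2x2 within-participant ANOVA (congruency x sampling method)
is computed through its exact paired-t identities: the interaction
F(1, n-1) is the squared paired t on the difference of the two congruency
effects, and the congruency main effect is the squared one-sample t on their
mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GroupResult",
    "one_sample_t",
    "paired_t",
    "congruency_by_sampling_anova",
    "ancova_age",
]


@dataclass
class GroupResult:
    """One second-level test: statistic, degrees of freedom, p, effect size."""

    kind: str  # one_sample_t | paired_t | anova_F | ancova
    statistic: float
    df: tuple[int, ...]
    p: float  # two-tailed
    effect: float  # mean effect (or slope) in the effect's own units
    se: float

    def significant(self, alpha: float = 0.05) -> bool:
        return bool(self.p < alpha)

    def __str__(self) -> str:
        df = ", ".join(str(d) for d in self.df)
        letter = "F" if self.kind == "anova_F" else "t"
        return (
            f"{self.kind}: {letter}({df}) = {self.statistic:.3f}, "
            f"p = {self.p:.4g}, effect = {self.effect:.4g} (se {self.se:.4g})"
        )


def one_sample_t(values) -> GroupResult:
    """Two-tailed one-sample t-test of per-participant effects against 0."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two participants")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("degenerate input: zero variance across participants")
    se = sd / np.sqrt(n)
    t = x.mean() / se
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return GroupResult("one_sample_t", float(t), (n - 1,), float(p),
                       float(x.mean()), float(se))


def paired_t(a, b) -> GroupResult:
    """Paired two-tailed t-test (a minus b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    res = one_sample_t(a - b)
    return GroupResult("paired_t", res.statistic, res.df, res.p, res.effect,
                       res.se)


def congruency_by_sampling_anova(matched_effects, subsampled_effects
                                 ) -> dict[str, GroupResult]:
    """Within-participant 2x2 ANOVA: congruency x sampling method.

    Inputs are per-participant congruency effects (incongruent minus
    congruent) under the two sampling methods, paired by participant.
    Returns the congruency main effect and the congruency-by-method
    interaction, each as F(1, n-1).
    """
    m = np.asarray(matched_effects, dtype=float)
    s = np.asarray(subsampled_effects, dtype=float)
    if m.shape != s.shape:
        raise ValueError("participants mismatch between the two effect sets")
    main_t = one_sample_t((m + s) / 2.0)
    n = m.size
    if np.array_equal(m, s):  # identical effect sets: interaction exactly 0
        inter_t = GroupResult("paired_t", 0.0, (n - 1,), 1.0, 0.0, 0.0)
    else:
        inter_t = paired_t(s, m)
    out = {}
    for name, t_res in (("congruency", main_t), ("interaction", inter_t)):
        out[name] = GroupResult(
            "anova_F",
            t_res.statistic**2,
            (1, t_res.df[0]),
            t_res.p,
            t_res.effect,
            t_res.se,
        )
    return out


def ancova_age(effects, ages) -> dict[str, GroupResult]:
    """Congruency effect regressed on mean-centred age.

    The intercept tests the congruency effect at the mean age; the slope
    tests its age modulation.  A perfectly collinear (constant-age) design
    raises; a perfect fit (zero residual variance) is flagged with a warning.
    """
    import statsmodels.api as sm

    y = np.asarray(effects, dtype=float)
    age = np.asarray(ages, dtype=float)
    if y.shape != age.shape:
        raise ValueError("effects and ages must be paired per participant")
    if np.ptp(age) == 0.0:
        raise ValueError("constant ages: age slope undefined")
    X = sm.add_constant(age - age.mean())
    fit = sm.OLS(y, X).fit()
    if fit.df_resid > 0 and fit.ssr <= 1e-12 * max(1.0, float(y @ y)):
        warnings.warn("effects are exactly linear in age: zero residual "
                      "variance", stacklevel=2)
    df = (int(fit.df_resid),)
    out = {}
    for name, idx in (("congruency_at_mean_age", 0), ("age_slope", 1)):
        out[name] = GroupResult(
            "ancova",
            float(fit.tvalues[idx]),
            df,
            float(fit.pvalues[idx]),
            float(fit.params[idx]),
            float(fit.bse[idx]),
        )
    return out
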