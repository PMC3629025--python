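"""Bar plots of congruency effects across sampling schemes."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_congruency_effects"]


def plot_congruency_effects(effects_by_analysis: dict, ax=None,
                            ylabel: str = "congruency effect (signal units)"):
    """Bar chart of group-mean congruency effects with SEM error bars.

    ``effects_by_analysis`` maps an analysis label (e.g. ``full``,
    ``equated``, ``matched``, ``subsampled``) to the per-participant effect
    values.  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    labels = list(effects_by_analysis)
    means, sems = [], []
    for label in labels:
        vals = np.asarray(effects_by_analysis[label], dtype=float)
        means.append(vals.mean())
        sems.append(vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0)
    ax.bar(labels, means, yerr=sems, capsize=4, color="0.6",
           edgecolor="black")
    ax.axhline(0.0, color="black", linewidth=0.8)
    ax.set_ylabel(ylabel)
    ax.figure.tight_layout()
    return ax
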