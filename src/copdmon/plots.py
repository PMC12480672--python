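"""Figures: moderation / interaction visualisations.

Vector (SVG) output with deterministic metadata so repeated runs produce
identical files.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from copdmon._naming import display_name


def interaction_plot(strata, feature: str, moderator: str, path) -> None:
    """Stratified slope estimates with 95% CI bands across moderator levels.

    One point per occupied stratum (estimate with CI whiskers and a shaded
    band), mirroring the estimate-versus-moderator-level presentation used
    for moderation analyses.
    """
    xs, ys, lo, hi, labels = [], [], [], [], []
    for i, s in enumerate(strata):
        labels.append(s.label)
        if s.empty:
            continue
        xs.append(i)
        ys.append(s.result.estimate)
        lo.append(s.result.ci_low)
        hi.append(s.result.ci_high)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    if xs:
        xs = np.array(xs, dtype=float)
        ax.fill_between(xs, lo, hi, alpha=0.25, linewidth=0)
        ax.errorbar(xs, ys, yerr=[np.array(ys) - np.array(lo),
                                  np.array(hi) - np.array(ys)],
                    fmt="o-", capsize=3)
    ax.axhline(0 if (strata and not strata[0].empty
                     and strata[0].result.scale == "beta") else 1,
               color="grey", linewidth=0.8, linestyle="--")
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=20, fontsize=7)
    ax.set_xlabel(display_name(moderator))
    ax.set_ylabel(f"{display_name(feature)} effect")
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
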