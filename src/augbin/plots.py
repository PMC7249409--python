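"""A single figure: fitted response weights against the continuous component.

Shows how the augmented analysis grades patients smoothly by distance to the
responder threshold while the binary analysis sees only 0/1.  matplotlib is
imported lazily so the core library has no plotting dependency.
"""
from __future__ import annotations

import numpy as np

from .data import TrialData
from .rules import CompositeRule

__all__ = ["plot_response_weights"]


def plot_response_weights(
    data: TrialData, weights: np.ndarray, rule: CompositeRule, path
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    oy = ~np.isnan(data.y)
    fig, ax = plt.subplots(figsize=(6, 4))
    for b_val, marker, label in ((1.0, "o", "binary criterion met"),
                                 (0.0, "x", "binary criterion failed")):
        sel = oy & (data.b == b_val)
        ax.scatter(data.y[sel], weights[sel], marker=marker, s=18, alpha=0.6,
                   label=label)
    tau = rule.continuous_rule.threshold
    ax.axvline(tau, ls="--", lw=1, color="grey",
               label=f"threshold ({rule.continuous_rule.direction.value} {tau:g})")
    ax.set_xlabel("continuous component")
    ax.set_ylabel("fitted response weight")
    ax.set_ylim(-0.05, 1.05)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
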