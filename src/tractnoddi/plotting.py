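"""Profile plots: normative mean +/- SD band with optional patient overlay."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .deviation import DeviationFlags, HIGH, LOW
from .normative import NormativeProfile
from .profile import AlongTractProfile


def plot_profile(
    normative: NormativeProfile,
    patient: AlongTractProfile | None = None,
    flags: DeviationFlags | None = None,
    out_path=None,
    ax=None,
):
    """Normative band (mean +/- SD, gray) with the patient curve overlaid
    and flagged runs marked; x axis labelled by the original point indices.
    """
    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 3.2))
    else:
        fig = ax.figure
    x = normative.point_index
    ax.fill_between(
        x, normative.mean - normative.sd, normative.mean + normative.sd,
        color="0.8", label="healthy mean ± SD",
    )
    ax.plot(x, normative.mean, color="0.4", lw=1)
    if patient is not None:
        ax.plot(x, patient.mean, color="C3", lw=1.4, label="patient")
    if flags is not None:
        for state, color in ((LOW, "C0"), (HIGH, "C1")):
            hit = flags.state == state
            if np.any(hit) and patient is not None:
                ax.plot(x[hit], patient.mean[hit], ".", color=color, ms=5,
                        label=f"{state} (|z| ≥ 2)")
    ax.set_xlabel("along-tract point")
    ax.set_ylabel(normative.metric)
    title = " ".join(filter(None, [normative.tract, normative.side, normative.metric]))
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
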