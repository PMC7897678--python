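"""Optional plot artifacts (observed-vs-null CFD envelope, flow density plot)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .flow import EventTable, GateSpec
from .shuffle import ShuffleEnvelope


def plot_envelope(env: ShuffleEnvelope, path: str | Path, title: str = "") -> None:
    """Observed minimal-distance CFD against the mean shuffled CFD ± 95% band."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.fill_between(
        env.grid_nm, env.ci_low, env.ci_high, alpha=0.3, label="95% envelope"
    )
    ax.plot(env.grid_nm, env.mean_null_cfd, "--", label="mean shuffled")
    ax.step(
        env.observed.distances_nm,
        env.observed.cum_freq,
        where="post",
        label="observed",
    )
    ax.set_xlabel("minimal center-to-center distance (nm)")
    ax.set_ylabel("cumulative frequency")
    ax.set_xlim(0, env.grid_nm[-1])
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_flow_density(
    events: EventTable, gate: GateSpec, path: str | Path, title: str = ""
) -> None:
    """Log-log event density with the quadrant gate cross-hairs."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    a = np.maximum(events.intensity_A, 1.0)
    b = np.maximum(events.intensity_B, 1.0)
    ax.hexbin(a, b, xscale="log", yscale="log", gridsize=60, bins="log", cmap="viridis")
    ax.axvline(max(gate.threshold_A, 1.0), color="w", ls="--", lw=1)
    ax.axhline(max(gate.threshold_B, 1.0), color="w", ls="--", lw=1)
    ax.set_xlabel("channel A intensity")
    ax.set_ylabel("channel B intensity")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
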