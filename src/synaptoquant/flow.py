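"""Flow-cytometry quadrant quantification for immunolabeled synaptosomes.

Gates are rectangular and derived per channel from a secondary-antibody
control at a 1% false-positive rate: the threshold is the nearest-rank
(1 - fpr) empirical quantile of the control intensities, so it is always an
observed intensity.  Events strictly exceeding a threshold are positive for
that channel; quadrant percentages and the conditional co-occurrence ratios
(e.g. "share of C1q-positive synaptosomes that are also NP1-positive")
follow by simple arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EventTable",
    "GateSpec",
    "QuadrantStats",
    "derive_gate",
    "quadrant_stats",
    "conditional_percentages",
]


@dataclass
class EventTable:
    """Per-event intensities of the two detection channels."""

    intensity_A: np.ndarray
    intensity_B: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.intensity_A = np.asarray(self.intensity_A, dtype=float).ravel()
        self.intensity_B = np.asarray(self.intensity_B, dtype=float).ravel()
        if len(self.intensity_A) != len(self.intensity_B):
            raise ValueError("channel columns must have equal length")
        if len(self.intensity_A) < 1:
            raise ValueError("an EventTable needs at least one event")
        if not (
            np.all(np.isfinite(self.intensity_A))
            and np.all(np.isfinite(self.intensity_B))
        ):
            raise ValueError("intensities must be finite")

    @property
    def n_events(self) -> int:
        return len(self.intensity_A)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sample_id: str = "") -> "EventTable":
        return cls(
            intensity_A=df["intensity_A"].to_numpy(),
            intensity_B=df["intensity_B"].to_numpy(),
            sample_id=sample_id,
        )


@dataclass(frozen=True)
class GateSpec:
    """Per-channel intensity thresholds set on a secondary-antibody control."""

    threshold_A: float
    threshold_B: float
    control_fpr: float = 0.01


def _nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """q-th quantile as the ceil(q*n)-th smallest observed value (1-based)."""
    v = np.sort(values)
    rank = int(np.ceil(q * len(v)))
    rank = min(max(rank, 1), len(v))
    return float(v[rank - 1])


def derive_gate(control: EventTable, control_fpr: float = 0.01) -> GateSpec:
    """Thresholds at the nearest-rank (1 - fpr) quantile of the control.

    With strict exceedance as positivity, applying the gate back to the
    control yields at most ``control_fpr`` positives per channel.
    """
    if control.n_events < 100:
        raise ValueError("control must have at least 100 events to set a gate")
    if not 0.0 <= control_fpr < 1.0:
        raise ValueError("control_fpr must lie in [0, 1)")
    q = 1.0 - control_fpr
    return GateSpec(
        threshold_A=_nearest_rank_quantile(control.intensity_A, q),
        threshold_B=_nearest_rank_quantile(control.intensity_B, q),
        control_fpr=control_fpr,
    )


@dataclass
class QuadrantStats:
    """Quadrant percentages plus conditional co-occurrence ratios.

    The four quadrant percentages sum to 100 exactly; conditionals are NaN
    when their reference population is empty.
    """

    pct_A_pos: float
    pct_B_pos: float
    pct_double: float
    pct_neg: float

    @property
    def pct_A_only(self) -> float:
        return self.pct_A_pos - self.pct_double

    @property
    def pct_B_only(self) -> float:
        return self.pct_B_pos - self.pct_double

    @property
    def conditional_B_given_A(self) -> float:
        if self.pct_A_pos == 0:
            return float("nan")
        return 100.0 * self.pct_double / self.pct_A_pos

    @property
    def conditional_A_given_B(self) -> float:
        if self.pct_B_pos == 0:
            return float("nan")
        return 100.0 * self.pct_double / self.pct_B_pos


def quadrant_stats(sample: EventTable, gate: GateSpec) -> QuadrantStats:
    """Classify events into quadrants by strict exceedance of each threshold.

    ``pct_A_pos`` / ``pct_B_pos`` are marginal positive percentages (single
    plus double), matching how quadrant displays are read.
    """
    a = sample.intensity_A > gate.threshold_A
    b = sample.intensity_B > gate.threshold_B
    n = sample.n_events
    pct = lambda m: 100.0 * np.count_nonzero(m) / n  # noqa: E731
    return QuadrantStats(
        pct_A_pos=pct(a),
        pct_B_pos=pct(b),
        pct_double=pct(a & b),
        pct_neg=pct(~a & ~b),
    )


def conditional_percentages(
    pct_A_pos: float, pct_B_pos: float, pct_double: float
) -> tuple[float, float]:
    """Conditional ratios straight from printed quadrant percentages.

    Returns (B-given-A, A-given-B) as percentages, e.g. the share of
    C1q-positive synaptosomes that are also NP-positive.
    """
    stats = QuadrantStats(
        pct_A_pos=pct_A_pos,
        pct_B_pos=pct_B_pos,
        pct_double=pct_double,
        pct_neg=100.0 - pct_A_pos - pct_B_pos + pct_double,
    )
    return stats.conditional_B_given_A, stats.conditional_A_given_B
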