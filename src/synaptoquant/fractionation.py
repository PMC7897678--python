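"""Sub-synaptic fraction deconvolution via a 3x3 linear system.

Biochemical fractionation of synaptosomes yields three preparations —
synaptic plasma membrane (SPM), synaptic cytoplasm, and synaptic
mitochondria — none of which is perfectly pure.  Compartment-exclusive
markers (Psd95 -> SPM, Ldhb -> cytoplasm, Cox4 -> mitochondria) quantified by
Western-blot densitometry give each preparation's composition: column k of
the mixing matrix is marker k's signal per fraction divided by that marker's
total, so each column sums to 1.  For a protein of interest with observed
per-fraction signals b, solving M x = b yields the protein level x
attributable to each true compartment (x = SPM, y = cytoplasm,
z = mitochondria, in the same arbitrary densitometry units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core import Summary, summarize

__all__ = [
    "MixingMatrix",
    "CompartmentLevels",
    "build_mixing_matrix",
    "solve_compartments",
    "solve_replicates",
]

COMPARTMENTS = ("SPM", "Cytoplasm", "Mitochondria")
DEFAULT_MARKER_ORDER = ("Psd95", "Ldhb", "Cox4")


@dataclass
class MixingMatrix:
    """Per-fraction compartment composition inferred from markers.

    ``matrix[i, k]`` is the share of compartment ``k`` material ending up in
    measured fraction ``i``; each column sums to 1.
    """

    matrix: np.ndarray
    derived_from: str = ""
    condition_bound: float = 1e6

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("mixing matrix must be 3x3")
        if np.any(self.matrix < 0):
            raise ValueError("mixing coefficients must be non-negative")

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    @property
    def ill_conditioned(self) -> bool:
        return self.condition_number > self.condition_bound


@dataclass
class CompartmentLevels:
    """Solved per-compartment protein levels (arbitrary densitometry units)."""

    x_spm: float
    y_cytoplasm: float
    z_mitochondria: float
    residual_norm: float

    @property
    def values(self) -> np.ndarray:
        return np.array([self.x_spm, self.y_cytoplasm, self.z_mitochondria])

    @property
    def has_negative(self) -> bool:
        return bool(np.any(self.values < 0))


def build_mixing_matrix(
    marker_table: pd.DataFrame,
    marker_order: tuple[str, str, str] = DEFAULT_MARKER_ORDER,
    fraction_order: tuple[str, str, str] = COMPARTMENTS,
    normalization: str = "column",
) -> MixingMatrix:
    """Mixing matrix from a long marker densitometry table.

    ``marker_table`` has columns (fraction, marker_or_protein, signal);
    replicate columns, if present, are averaged first.  Column k is marker
    k's mean signal per fraction divided by that marker's total across
    fractions ("column" normalization, the default reading of composition as
    the marker's relative amount in the lysates).  The "row" alternative
    normalizes each measured fraction's marker signals to sum to 1 instead.
    """
    df = (
        marker_table.groupby(["fraction", "marker_or_protein"])["signal"]
        .mean()
        .reset_index()
    )
    M = np.zeros((3, 3))
    for k, marker in enumerate(marker_order):
        sub = df[df["marker_or_protein"] == marker]
        sig = {
            row["fraction"]: row["signal"] for _, row in sub.iterrows()
        }
        col = np.array([sig.get(f, 0.0) for f in fraction_order])
        if np.any(col < 0):
            raise ValueError(f"marker {marker!r} has negative signal")
        if col.sum() == 0:
            raise ValueError(f"marker {marker!r} is zero in every fraction")
        M[:, k] = col
    if normalization == "column":
        M /= M.sum(axis=0, keepdims=True)
    elif normalization == "row":
        M /= M.sum(axis=1, keepdims=True)
    else:
        raise ValueError("normalization must be 'column' or 'row'")
    return MixingMatrix(matrix=M, derived_from=",".join(marker_order))


def solve_compartments(
    M: MixingMatrix,
    observed: np.ndarray,
    non_negative: bool = False,
) -> CompartmentLevels:
    """Solve M x = observed for the per-compartment protein levels.

    The default is the exact (unconstrained) 3x3 solve; negative components
    are reported as-is and flagged via ``has_negative``.  ``non_negative``
    switches to non-negative least squares for noisy data.
    """
    b = np.asarray(observed, dtype=float).reshape(3)
    if np.linalg.matrix_rank(M.matrix) < 3:
        raise np.linalg.LinAlgError("mixing matrix is singular")
    if non_negative:
        x, rnorm = nnls(M.matrix, b)
        residual = float(rnorm)
    else:
        x = np.linalg.solve(M.matrix, b)
        residual = float(np.linalg.norm(M.matrix @ x - b))
    return CompartmentLevels(
        x_spm=float(x[0]),
        y_cytoplasm=float(x[1]),
        z_mitochondria=float(x[2]),
        residual_norm=residual,
    )


def solve_replicates(
    marker_table: pd.DataFrame,
    protein: str,
    non_negative: bool = False,
    normalization: str = "column",
) -> tuple[list[CompartmentLevels], dict[str, Summary]]:
    """Per-replicate solves followed by a mean ± SEM summary per compartment.

    Each replicate gets its own mixing matrix (from that replicate's marker
    rows) and its own solve, matching a per-animal experimental structure.
    """
    reps = sorted(marker_table["replicate"].unique())
    per_rep: list[CompartmentLevels] = []
    for rep in reps:
        sub = marker_table[marker_table["replicate"] == rep]
        M = build_mixing_matrix(sub, normalization=normalization)
        obs_rows = sub[sub["marker_or_protein"] == protein]
        sig = {r["fraction"]: r["signal"] for _, r in obs_rows.iterrows()}
        b = np.array([sig[f] for f in COMPARTMENTS])
        per_rep.append(solve_compartments(M, b, non_negative=non_negative))
    stacked = np.stack([lv.values for lv in per_rep])
    summaries = {
        comp: summarize(stacked[:, k]) for k, comp in enumerate(COMPARTMENTS)
    }
    return per_rep, summaries
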