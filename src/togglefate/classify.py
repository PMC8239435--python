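"""Cell-fate classification: scores → phase portrait → attractor basins.

Each cell's two signature z-scores place it as a time-0 starting point on
the toggle-switch phase portrait: the immunogenic axis score maps to the
I coordinate and the tolerogenic axis score to the T coordinate, each
min–max scaled to ``[0, x_max]``.  The cell's trajectory is integrated to
its attractor and the cell inherits that attractor's fate; per-condition
fate proportions are then tallied over converged cells.

Scaling is pooled across all cells being analysed together by default,
so that conditions plotted on the same portrait remain comparable; a
per-condition switch is provided for sensitivity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSignature
from .model import (
    FATE_LABELS,
    UNCONVERGED,
    FixedPoint,
    ToggleParams,
    classify_starting_points,
    find_fixed_points,
    stable_attractors,
)
from .scoring import score_signature

logger = logging.getLogger(__name__)

__all__ = ["FateResult", "scale_scores", "classify_cells", "summarize_fates"]

FATES = tuple(FATE_LABELS.values())  # ("immunogenic", "tolerogenic", "ambivalent")


@dataclass
class FateResult:
    """Per-cell fate assignments and per-condition fate proportions."""

    cells: pd.DataFrame
    """Columns: cell_id, condition, x_raw, y_raw, x_scaled, y_scaled, fate, converged."""

    proportions: pd.DataFrame
    """Rows: condition; columns: immunogenic/tolerogenic/ambivalent fractions
    over converged cells (each row sums to 1)."""

    counts: pd.DataFrame
    """Same layout as ``proportions`` but with cell counts, plus an
    ``unconverged`` column."""

    attractors: list[FixedPoint] = field(default_factory=list)


def scale_scores(
    x_raw: np.ndarray,
    y_raw: np.ndarray,
    x_max: float,
    x_range: tuple[float, float] | None = None,
    y_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Min–max scale raw z-scores onto the phase portrait ``[0, x_max]²``.

    Each axis is scaled independently over all cells passed in (pass the
    pooled cells of every condition compared on one portrait).  A fixed
    scaling window can be imposed with ``x_range`` / ``y_range``.  An axis
    with no spread maps every cell to the window midpoint ``x_max / 2``
    (with a warning) — there is no information to separate cells on it.
    """
    x_raw = np.asarray(x_raw, dtype=float)
    y_raw = np.asarray(y_raw, dtype=float)
    if x_raw.shape != y_raw.shape or x_raw.ndim != 1:
        raise ValueError("x_raw and y_raw must be 1-D arrays of equal length")
    if len(x_raw) < 2:
        raise ValueError("scaling needs at least 2 cells")
    if not (np.all(np.isfinite(x_raw)) and np.all(np.isfinite(y_raw))):
        raise ValueError("scores contain non-finite values")

    def _scale(values: np.ndarray, window, axis_name: str) -> np.ndarray:
        lo, hi = (values.min(), values.max()) if window is None else window
        if hi <= lo:
            logger.warning("axis %s has no spread; mapping all cells to x_max/2", axis_name)
            return np.full_like(values, x_max / 2)
        return (values - lo) * (x_max / (hi - lo))

    return _scale(x_raw, x_range, "x"), _scale(y_raw, y_range, "y")


def classify_cells(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    immunogenic_axis: GeneSignature,
    tolerogenic_axis: GeneSignature,
    params: ToggleParams | None = None,
    pooled_scaling: bool = True,
) -> FateResult:
    """Score, scale, integrate and classify every cell of ``matrix``.

    Pipeline: per-axis signature z-scores → min–max scaling into the
    portrait window (pooled across conditions unless ``pooled_scaling``
    is off) → trajectory integration from each cell's starting point →
    nearest-attractor assignment → per-condition fate proportions.
    Cells whose trajectories do not settle at an attractor are reported
    as unconverged and excluded from the proportions.
    """
    p = params or ToggleParams()
    x = score_signature(matrix, immunogenic_axis)
    y = score_signature(matrix, tolerogenic_axis)
    meta = metadata.set_index("cell_id")
    missing = [c for c in matrix.cell_ids if c not in meta.index]
    if missing:
        raise ValueError(f"cells without metadata rows: {missing[:5]}")
    conditions = meta["condition"].reindex(matrix.cell_ids)

    if pooled_scaling:
        xs, ys = scale_scores(x.to_numpy(), y.to_numpy(), p.x_max)
    else:
        xs = np.empty(len(x))
        ys = np.empty(len(y))
        for label in conditions.unique():
            sel = (conditions == label).to_numpy()
            xs[sel], ys[sel] = scale_scores(x.to_numpy()[sel], y.to_numpy()[sel], p.x_max)

    attractors = stable_attractors(find_fixed_points(p))
    starts = np.column_stack([xs, ys])
    labels, _terminals = classify_starting_points(starts, p, attractors)

    cells = pd.DataFrame(
        {
            "cell_id": matrix.cell_ids,
            "condition": conditions.to_numpy(),
            "x_raw": x.to_numpy(),
            "y_raw": y.to_numpy(),
            "x_scaled": xs,
            "y_scaled": ys,
            "fate": labels,
            "converged": labels != UNCONVERGED,
        }
    )
    counts = (
        cells.pivot_table(index="condition", columns="fate", values="cell_id", aggfunc="count")
        .reindex(columns=list(FATES) + [UNCONVERGED])
        .fillna(0)
        .astype(int)
    )
    counts.columns.name = None
    counts = counts.rename(columns={UNCONVERGED: "unconverged"})
    converged_totals = counts[list(FATES)].sum(axis=1)
    if (converged_totals == 0).any():
        bad = converged_totals.index[converged_totals == 0].tolist()
        raise ValueError(f"no converged cells in condition(s) {bad}")
    proportions = counts[list(FATES)].div(converged_totals, axis=0)
    return FateResult(cells=cells, proportions=proportions, counts=counts, attractors=attractors)


def summarize_fates(result: FateResult) -> pd.DataFrame:
    """Long-form per-condition fate table with counts and percentages.

    Percentages are over converged cells and rounded to two decimals
    (they sum to 100 within rounding); the unconverged count is carried
    as its own column.
    """
    if result.cells.empty:
        raise ValueError("empty fate result")
    rows = []
    for condition, row in result.counts.iterrows():
        total = int(sum(row[f] for f in FATES))
        for fate in FATES:
            rows.append(
                {
                    "condition": condition,
                    "fate": fate,
                    "count": int(row[fate]),
                    "percentage": round(100.0 * row[fate] / total, 2) if total else float("nan"),
                    "unconverged": int(row.get("unconverged", 0)),
                }
            )
    return pd.DataFrame(rows)
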