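"""Enumeration and ranking of candidate TF-combination toggle models.

Each candidate pairs an immunogenic TF set with a tolerogenic TF set and
is judged on two directional criteria comparing a stimulated against an
unstimulated condition:

1. the stimulated immunogenic fraction exceeds the unstimulated one, and
2. the stimulated tolerogenic fraction is below the unstimulated one.

Candidates are ranked by the number of criteria satisfied, then by the
margin ``Δ immunogenic − Δ tolerogenic`` (stimulated minus unstimulated).
With the default pools — immunogenic sets anchored on IRF1 and optionally
extended by IRF4, crossed with every non-empty subset of
{KRAS, SOX4, IRF4, RELB, ELK1} — there are 2 × 31 = 62 candidates; the
full pairing of {IRF1, IRF4} with all five tolerogenic TFs is the
configuration referred to here as the full model.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .classify import classify_cells
from .io import ExpressionMatrix, GeneSignature
from .model import ToggleParams

__all__ = [
    "DEFAULT_IMMUNOGENIC_POOL",
    "DEFAULT_TOLEROGENIC_POOL",
    "CandidateModel",
    "ModelEvaluation",
    "enumerate_models",
    "evaluate_models",
    "evaluations_to_frame",
]

DEFAULT_IMMUNOGENIC_POOL = ("IRF1", "IRF4")
DEFAULT_TOLEROGENIC_POOL = ("KRAS", "SOX4", "IRF4", "RELB", "ELK1")


@dataclass(frozen=True)
class CandidateModel:
    """One TF-combination hypothesis for the two programme axes."""

    model_id: int
    immunogenic_tfs: tuple[str, ...]
    tolerogenic_tfs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.immunogenic_tfs or not self.tolerogenic_tfs:
            raise ValueError("both TF sets must be non-empty")

    @property
    def x_signature(self) -> GeneSignature:
        return GeneSignature(name=f"model{self.model_id}_x", genes=self.immunogenic_tfs)

    @property
    def y_signature(self) -> GeneSignature:
        return GeneSignature(name=f"model{self.model_id}_y", genes=self.tolerogenic_tfs)


@dataclass(frozen=True)
class ModelEvaluation:
    """Fate proportions and criterion outcomes for one candidate."""

    model: CandidateModel
    proportions: dict[str, tuple[float, float, float]]  # condition -> (imm, tol, amb)
    criterion_1: bool  # stimulated immunogenic fraction > unstimulated
    criterion_2: bool  # stimulated tolerogenic fraction < unstimulated
    margin: float  # Δ immunogenic − Δ tolerogenic (stimulated − unstimulated)
    evaluable: bool = True

    @property
    def n_criteria(self) -> int:
        return int(self.criterion_1) + int(self.criterion_2)


def _anchored_subsets(pool: tuple[str, ...]) -> list[tuple[str, ...]]:
    """Subsets of ``pool`` that contain its first (anchor) element."""
    anchor, rest = pool[0], pool[1:]
    out = []
    for r in range(len(rest) + 1):
        for combo in combinations(rest, r):
            out.append((anchor, *combo))
    return out


def _nonempty_subsets(pool: tuple[str, ...]) -> list[tuple[str, ...]]:
    out = []
    for r in range(1, len(pool) + 1):
        for combo in combinations(pool, r):
            out.append(combo)
    return out


def enumerate_models(
    immunogenic_pool: tuple[str, ...] = DEFAULT_IMMUNOGENIC_POOL,
    tolerogenic_pool: tuple[str, ...] = DEFAULT_TOLEROGENIC_POOL,
) -> list[CandidateModel]:
    """All candidate axis pairings in a deterministic order.

    Immunogenic sets are the subsets of ``immunogenic_pool`` containing
    its first TF (the anchor, IRF1 by default: the anchor is always
    tested, alone or extended).  Tolerogenic sets are every non-empty
    subset of ``tolerogenic_pool``.  Model ids are assigned sequentially
    from 1 in enumeration order and are stable for fixed pools.
    """
    if not immunogenic_pool or not tolerogenic_pool:
        raise ValueError("TF pools must be non-empty")
    candidates = []
    model_id = 1
    for imm in _anchored_subsets(tuple(immunogenic_pool)):
        for tol in _nonempty_subsets(tuple(tolerogenic_pool)):
            candidates.append(
                CandidateModel(model_id=model_id, immunogenic_tfs=imm, tolerogenic_tfs=tol)
            )
            model_id += 1
    return candidates


def evaluate_models(
    candidates: list[CandidateModel],
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    params: ToggleParams | None = None,
    condition_pair: tuple[str, str] = ("unstimulated", "TNF"),
) -> list[ModelEvaluation]:
    """Classify cells under every candidate and rank by the two criteria.

    ``condition_pair`` is (unstimulated, stimulated).  Candidates whose
    axis genes are entirely absent from the matrix are returned as
    unevaluable rather than raising.  The returned list is sorted by
    (criteria satisfied, margin) descending, ties broken by model id.
    """
    p = params or ToggleParams()
    unstim, stim = condition_pair
    present = set(metadata["condition"])
    for label in condition_pair:
        if label not in present:
            raise ValueError(f"condition {label!r} not present in metadata")
    evaluations: list[ModelEvaluation] = []
    for cand in candidates:
        try:
            result = classify_cells(matrix, metadata, cand.x_signature, cand.y_signature, p)
        except ValueError:
            evaluations.append(
                ModelEvaluation(
                    model=cand,
                    proportions={},
                    criterion_1=False,
                    criterion_2=False,
                    margin=float("-inf"),
                    evaluable=False,
                )
            )
            continue
        props = {
            cond: tuple(result.proportions.loc[cond, ["immunogenic", "tolerogenic", "ambivalent"]])
            for cond in result.proportions.index
        }
        d_imm = props[stim][0] - props[unstim][0]
        d_tol = props[stim][1] - props[unstim][1]
        evaluations.append(
            ModelEvaluation(
                model=cand,
                proportions=props,
                criterion_1=d_imm > 0,
                criterion_2=d_tol < 0,
                margin=d_imm - d_tol,
            )
        )
    evaluations.sort(key=lambda ev: (-ev.n_criteria, -ev.margin, ev.model.model_id))
    return evaluations


def evaluations_to_frame(evaluations: list[ModelEvaluation]) -> pd.DataFrame:
    """Flatten ranked evaluations into a table (one row per candidate)."""
    rows = []
    for rank, ev in enumerate(evaluations, start=1):
        row = {
            "rank": rank,
            "model_id": ev.model.model_id,
            "immunogenic_tfs": "+".join(ev.model.immunogenic_tfs),
            "tolerogenic_tfs": "+".join(ev.model.tolerogenic_tfs),
            "criterion_1": ev.criterion_1,
            "criterion_2": ev.criterion_2,
            "margin": ev.margin,
            "evaluable": ev.evaluable,
        }
        for cond, (imm, tol, amb) in ev.proportions.items():
            row[f"{cond}_immunogenic"] = imm
            row[f"{cond}_tolerogenic"] = tol
            row[f"{cond}_ambivalent"] = amb
        rows.append(row)
    return pd.DataFrame(rows)
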