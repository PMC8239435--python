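"""Per-cell signature z-scores and between-condition comparisons.

A signature score for a cell is the unweighted mean of per-gene z-scores
over the signature's genes: each gene's normalised expression is centred
on its mean across cells and divided by its population standard deviation
(ddof=0).  Genes absent from the matrix or constant across cells carry no
information for ranking cells and are dropped with a warning.

Because every gene is standardised independently, scores are invariant
under any per-gene positive-affine transform of the expression values —
the construction deliberately ignores absolute expression scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSignature

logger = logging.getLogger(__name__)

__all__ = ["score_signature", "compare_conditions", "ConditionComparison"]


def score_signature(matrix: ExpressionMatrix, signature: GeneSignature) -> pd.Series:
    """Mean per-gene z-score of ``signature`` for every cell.

    Parameters
    ----------
    matrix
        Normalised expression (``layer_tag == "normalized"``).
    signature
        Gene set defining one programme axis.

    Returns
    -------
    pandas.Series
        One score per cell, indexed by barcode, named after the signature.

    Raises
    ------
    ValueError
        If the matrix is not normalised, no signature gene is present, or
        every present gene is constant across cells.
    """
    if matrix.layer_tag != "normalized":
        raise ValueError("score_signature expects a normalized matrix")
    present = [g for g in signature.genes if g in set(matrix.gene_ids)]
    missing = [g for g in signature.genes if g not in set(matrix.gene_ids)]
    if missing:
        logger.warning("signature %s: genes absent from matrix: %s", signature.name, missing)
    if not present:
        raise ValueError(f"no gene of signature {signature.name!r} is present in the matrix")
    cols = matrix.gene_index(present)
    values = matrix.values[:, cols]
    means = values.mean(axis=0)
    sds = values.std(axis=0)  # population SD (ddof=0)
    informative = sds > 0
    if not informative.any():
        raise ValueError(
            f"all present genes of signature {signature.name!r} are constant across cells"
        )
    constant = [g for g, keep in zip(present, informative) if not keep]
    if constant:
        logger.warning("signature %s: zero-variance genes dropped: %s", signature.name, constant)
    z = (values[:, informative] - means[informative]) / sds[informative]
    return pd.Series(z.mean(axis=1), index=matrix.cell_ids, name=signature.name)


@dataclass(frozen=True)
class ConditionComparison:
    """Summary of a two-group comparison of per-cell signature scores."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    fold_change: float  # median_b / median_a, rounded to 2 decimals
    p_value: float  # two-sided Mann-Whitney U


def compare_conditions(
    scores: pd.Series,
    metadata: pd.DataFrame,
    group_a: str,
    group_b: str,
) -> ConditionComparison:
    """Compare raw signature scores between two condition labels.

    Medians are taken on the raw (unscaled) scores; the fold change is the
    ratio of group-b to group-a medians reported to two decimals, and the
    p-value comes from a two-sided Mann-Whitney rank test.
    """
    conditions = metadata.set_index("cell_id")["condition"].reindex(scores.index)
    groups = {}
    for label in (group_a, group_b):
        if label not in set(conditions.dropna()):
            raise ValueError(f"unknown condition label {label!r}")
        groups[label] = scores[conditions == label].to_numpy()
    a, b = groups[group_a], groups[group_b]
    median_a, median_b = float(np.median(a)), float(np.median(b))
    if np.array_equal(np.sort(a), np.sort(b)):
        p_value = 1.0
    else:
        p_value = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    fold = float("nan") if median_a == 0 else round(median_b / median_a, 2)
    return ConditionComparison(
        group_a=group_a,
        group_b=group_b,
        n_a=len(a),
        n_b=len(b),
        median_a=median_a,
        median_b=median_b,
        fold_change=fold,
        p_value=p_value,
    )
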