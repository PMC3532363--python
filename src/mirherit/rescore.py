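"""Regulatory-effect (RE) scores.

The RE-score of a miRNA in a sample is the mean expression rank of genes
that are *not* predicted targets of the miRNA minus the mean expression rank
of its predicted targets. Ranks are ascending (1 = lowest expression) with
ties sharing the average rank, so a miRNA whose targets are strongly
repressed (low expression, low ranks) gets a *positive* score. Because the
score is a rank statistic it is invariant to any strictly increasing
transformation of the per-sample expression values, which makes it robust to
normalization and technical scale differences between samples.

The per-sample mean RE-score (average over all scored miRNAs) is the global
quantitative trait used by the heritability and association stages; the
"subtracted" mean RE-score removes a focal miRNA's target genes from the
matrix before averaging the remaining miRNAs, to avoid self-overlap bias
when the focal miRNA's own score is regressed on the mean.
"""
from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix, REScoreMatrix, TargetSetCollection
from .exceptions import EmptyResultError, UndefinedScoreError

logger = logging.getLogger(__name__)

DEFAULT_MIN_TARGETS = 10


def re_score(expr_column: pd.Series, targets: Iterable[str], universe: Sequence[str] | None = None) -> float:
    """RE-score of one miRNA in one sample.

    Parameters
    ----------
    expr_column
        Expression values for one sample, indexed by gene id.
    targets
        Predicted target gene ids; genes absent from the expression column
        are ignored.
    universe
        Optional explicit ranking universe (defaults to all genes in
        ``expr_column``).

    Returns
    -------
    float
        mean rank of non-targets minus mean rank of targets.

    Raises
    ------
    UndefinedScoreError
        If no target, or no non-target, gene is measured.
    """
    if universe is not None:
        expr_column = expr_column.loc[expr_column.index.intersection(pd.Index(universe))]
    genes = expr_column.index
    target_mask = genes.isin(set(targets))
    n_t = int(target_mask.sum())
    n_nt = len(genes) - n_t
    if n_t == 0:
        raise UndefinedScoreError("no measured target gene; RE-score undefined")
    if n_nt == 0:
        raise UndefinedScoreError("no measured non-target gene; RE-score undefined")
    ranks = rankdata(expr_column.to_numpy(dtype=float), method="average")
    return float(ranks[~target_mask].mean() - ranks[target_mask].mean())


def _rank_columns(values: np.ndarray) -> np.ndarray:
    """Ascending average ranks per column (samples) of a genes x samples array."""
    return rankdata(values, method="average", axis=0)


def re_matrix(
    expr: ExpressionMatrix,
    targets: TargetSetCollection,
    min_targets: int = DEFAULT_MIN_TARGETS,
) -> REScoreMatrix:
    """Score every miRNA in every sample.

    miRNAs with fewer than ``min_targets`` measured target genes are dropped
    (and logged); an :class:`EmptyResultError` is raised if none survive.
    The per-sample ``mean_re`` is the arithmetic mean over surviving miRNAs.
    """
    gene_index = expr.gene_ids
    G = len(gene_index)
    if G < 2:
        raise EmptyResultError("need at least two genes to rank")
    ranks = _rank_columns(expr.values.to_numpy(dtype=float))
    total_rank = G * (G + 1) / 2.0  # per-column rank sum, conserved under ties

    rows = []
    kept_ids: list[str] = []
    n_used: dict[str, int] = {}
    pos = {g: i for i, g in enumerate(gene_index)}
    for ts in targets:
        idx = [pos[g] for g in ts.genes if g in pos]
        n_t = len(idx)
        if n_t < max(min_targets, 1) or n_t == G:
            logger.info(
                "dropping %s: %d measured targets (floor %d, universe %d)",
                ts.mirna_id, n_t, min_targets, G,
            )
            continue
        t_sum = ranks[idx, :].sum(axis=0)
        score = (total_rank - t_sum) / (G - n_t) - t_sum / n_t
        rows.append(score)
        kept_ids.append(ts.mirna_id)
        n_used[ts.mirna_id] = n_t
    if not rows:
        raise EmptyResultError("no miRNA passed the minimum-target floor")
    re = pd.DataFrame(np.vstack(rows), index=kept_ids, columns=expr.sample_ids)
    return REScoreMatrix(re=re, n_targets_used=pd.Series(n_used))


def conventional_mean_re(scores: REScoreMatrix, targets: TargetSetCollection) -> pd.Series:
    """Per-sample mean RE-score over conventional miRNAs only.

    This is the global quantitative trait used for genotype association:
    mirtrons are held out because they bypass DROSHA processing and serve
    as a negative-control class, so averaging them into the trait would
    dilute any biogenesis-pathway signal.
    """
    conventional = [m for m in scores.re.index if m in targets and
                    targets[m].mirna_class == "conventional"]
    if not conventional:
        raise EmptyResultError("no conventional miRNA present in the RE matrix")
    out = scores.re.loc[conventional].mean(axis=0)
    out.name = "mean_re"
    return out


def subtracted_mean_re(
    expr: ExpressionMatrix,
    targets: TargetSetCollection,
    focal_mirna: str,
    min_targets: int = DEFAULT_MIN_TARGETS,
) -> pd.Series:
    """Mean RE-score over all *other* miRNAs after deleting the focal
    miRNA's target genes from the expression matrix.

    Other miRNAs left with fewer than ``min_targets`` measured targets on the
    reduced universe are dropped and logged, not treated as an error; an
    :class:`EmptyResultError` is raised only if no other miRNA survives.
    """
    if focal_mirna not in targets:
        raise KeyError(f"unknown miRNA {focal_mirna!r}")
    reduced = expr.drop_genes(targets[focal_mirna].genes)
    if reduced.n_genes < 2:
        raise EmptyResultError("focal target set covers the whole universe")
    others = TargetSetCollection(ts for ts in targets if ts.mirna_id != focal_mirna)
    result = re_matrix(reduced, others, min_targets=min_targets)
    out = result.mean_re.copy()
    out.name = f"mean_re_minus_{focal_mirna}"
    return out
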