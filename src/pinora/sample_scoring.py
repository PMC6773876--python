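"""Per-sample pathway activity scores.

Given an experiment values matrix EM (genes x samples), each gene row is
standardized across samples,

    GS(g, s) = (EM(g, s) - mean_g) / sd_g,

with sd_g the sample (n-1) standard deviation; a zero-variance gene
scores 0 in every sample.  The activity of pathway P_i in sample j is
the mean gene score over the pathway's genes present in the matrix,

    PS(i, j) = (1/k) * sum_{g in P_i} GS(g, j).

Because each GS row has mean zero across samples, each PS row does too,
so positive values read as above-average pathway activity in a sample.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["gene_scores", "pathway_scores"]


def gene_scores(em: ExpressionMatrix, ddof: int = 1) -> pd.DataFrame:
    """Standardize each gene row across samples; zero-variance rows become 0."""
    if em.values.shape[1] < 2:
        raise ValueError("gene scoring needs at least 2 samples")
    values = em.values
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=ddof)
    scores = values.sub(means, axis=0).div(sds.where(sds != 0.0, np.inf), axis=0)
    return scores


def pathway_scores(
    gs: pd.DataFrame,
    pathways: GeneSetCollection,
    gene_selection: set[str] | None = None,
) -> pd.DataFrame:
    """Average gene scores per pathway and sample.

    ``gene_selection``, if given, restricts every pathway to that gene set
    (e.g. the enrichment run's significant input genes).  Pathways with no
    genes present in the matrix are dropped with a warning.
    """
    present = set(gs.index)
    rows = {}
    for sid in sorted(pathways.sets):
        genes = set(pathways[sid])
        if gene_selection is not None:
            genes &= set(gene_selection)
        genes &= present
        if not genes:
            logger.warning("pathway %s has no genes in the matrix; dropped", sid)
            continue
        rows[sid] = gs.loc[sorted(genes)].mean(axis=0)
    if not rows:
        raise ValueError("no pathway has any gene present in the expression matrix")
    return pd.DataFrame(rows).T[gs.columns]
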