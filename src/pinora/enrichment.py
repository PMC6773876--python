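"""Over-representation analysis over active subnetworks and aggregation
into the final per-pathway result table.

The identified subnetworks are first filtered: a subnetwork is carried
forward only if its calibrated score exceeds the empirical score
quantile for the run (default 0.80) and it contains at least a minimum
number of significant input genes (default 10).  Each surviving
subnetwork is then tested against every gene set by a one-sided
hypergeometric test with the PIN node set as the background pool —
active subnetworks can only ever contain PIN genes, so the PIN, not the
genome, is the correct universe.  P values are adjusted within each
subnetwork's family of tests (Bonferroni by default), sub-threshold
pathways are aggregated across subnetworks by lowest adjusted p, and the
whole search-and-test cycle is repeated for a number of iterations whose
per-pathway extremes and occurrence counts make up the result table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .input_processing import ProcessedInput
from .io_formats import GeneSetCollection, InteractionNetwork, RESULT_COLUMNS
from .scoring import CalibrationTable, build_zscore_map
from .search import SearchConfig, Subnetwork, run_search

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentRecord",
    "EnrichmentConfig",
    "filter_subnetworks",
    "hypergeometric_ora",
    "adjust_pvalues",
    "aggregate_subnetworks",
    "run_active_enrichment",
]


@dataclass(frozen=True)
class EnrichmentRecord:
    """One pathway's test result within one subnetwork."""

    pathway_id: str
    p: float
    adj_p: float
    fold_enrichment: float
    overlap_genes: frozenset[str]


@dataclass
class EnrichmentConfig:
    """Parameters of the iterated subnetwork-enrichment loop."""

    iterations: int = 10
    score_quantile: float = 0.80
    min_significant_genes: int = 10
    adjust_method: str = "bonferroni"  # bonferroni | bh
    enrichment_threshold: float = 0.05
    calibration_draws: int = 2000
    seed: int = 0


def filter_subnetworks(
    subnetworks: list[Subnetwork],
    score_quantile: float = 0.80,
    min_sig_genes: int = 10,
) -> list[Subnetwork]:
    """Keep subnetworks whose calibrated score strictly exceeds the empirical
    quantile of this run's scores and that contain at least ``min_sig_genes``
    significant input genes.

    With a single subnetwork the quantile criterion is vacuous (its score
    equals its own quantile), so only the gene-count criterion applies.
    """
    if not subnetworks:
        logger.warning("no subnetworks to filter")
        return []
    sizable = [s for s in subnetworks if s.n_significant >= min_sig_genes]
    if len(subnetworks) == 1:
        return sizable
    cutoff = float(np.quantile([s.score for s in subnetworks], score_quantile))
    return [s for s in sizable if s.score > cutoff]


def hypergeometric_ora(
    query_genes, pathway_genes, pool_genes
) -> tuple[float, float, frozenset[str]]:
    """One-sided hypergeometric over-representation test.

    With pool size N, pathway size K (within the pool), query size n
    (within the pool) and overlap x, the p value is the upper tail
    P(X >= x) of Hypergeometric(N, K, n); fold enrichment is
    (x/n) / (K/N).
    """
    pool = set(pool_genes)
    if not pool:
        raise ValueError("empty background pool")
    pathway = set(pathway_genes) & pool
    query = set(query_genes) & pool
    overlap = query & pathway
    big_n, big_k, n, x = len(pool), len(pathway), len(query), len(overlap)
    if x == 0:
        p = 1.0
    else:
        p = float(stats.hypergeom.sf(x - 1, big_n, big_k, n))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
    if n == 0 or big_k == 0:
        fold = 0.0
    else:
        fold = (x / n) / (big_k / big_n)
    return p, fold, frozenset(overlap)


def adjust_pvalues(ps, method: str = "bonferroni") -> list[float]:
    """Multiple-testing adjustment: Bonferroni min(1, p*m) or
    Benjamini-Hochberg step-up.  Output order matches input order."""
    ps = list(ps)
    if not ps:
        return []
    if any(p < 0 or p > 1 for p in ps):
        raise ValueError("p values must lie in [0, 1]")
    if method == "bonferroni":
        m = len(ps)
        return [min(1.0, p * m) for p in ps]
    if method == "bh":
        return list(multipletests(ps, method="fdr_bh")[1])
    raise ValueError(f"unknown adjustment method {method!r}")


def aggregate_subnetworks(
    records_per_subnetwork: list[list[EnrichmentRecord]],
    threshold: float = 0.05,
) -> dict[str, EnrichmentRecord]:
    """Collapse per-subnetwork enrichment records into one record per pathway.

    Records with adjusted p strictly greater than ``threshold`` are
    discarded; for pathways enriched in several subnetworks, the record
    with the lowest adjusted p wins (ties: larger fold enrichment, then
    pathway id).
    """
    best: dict[str, EnrichmentRecord] = {}
    for records in records_per_subnetwork:
        for rec in records:
            if rec.adj_p > threshold:
                continue
            cur = best.get(rec.pathway_id)
            if cur is None or (
                rec.adj_p,
                -rec.fold_enrichment,
                rec.pathway_id,
            ) < (cur.adj_p, -cur.fold_enrichment, cur.pathway_id):
                best[rec.pathway_id] = rec
    return best


def _enrich_subnetwork(
    sub: Subnetwork,
    gene_sets: GeneSetCollection,
    pool: set[str],
    method: str,
) -> list[EnrichmentRecord]:
    ids = sorted(gene_sets.sets)
    raw = []
    for sid in ids:
        p, fold, overlap = hypergeometric_ora(sub.genes, gene_sets[sid], pool)
        raw.append((sid, p, fold, overlap))
    adjusted = adjust_pvalues([r[1] for r in raw], method)
    return [
        EnrichmentRecord(sid, p, adj, fold, overlap)
        for (sid, p, fold, overlap), adj in zip(raw, adjusted)
    ]


def run_active_enrichment(
    processed: ProcessedInput,
    pin: InteractionNetwork,
    gene_sets: GeneSetCollection,
    search_config: SearchConfig,
    config: EnrichmentConfig,
) -> pd.DataFrame:
    """Iterated active-subnetwork search + enrichment, aggregated into the
    final result table.

    Each iteration runs the subnetwork search with its own RNG substream,
    filters subnetworks, tests each against every gene set, adjusts within
    the subnetwork's test family and keeps per-pathway minima.  Across
    iterations the table records the lowest and highest adjusted p, the
    number of iterations in which the pathway was significant, the fold
    enrichment of the lowest-p record, and the up-/down-regulated input
    genes in the pathway (split by the sign of the change value; a single
    combined column when change values are absent).
    """
    if not processed.significant_genes:
        raise ValueError("no significant input genes mapped to the PIN")
    zmap = build_zscore_map(processed.p_values)
    pool = pin.nodes
    calib = CalibrationTable(
        pin=pin, zmap=zmap, draws=config.calibration_draws, seed=config.seed
    )

    per_pathway: dict[str, dict] = {}
    for iteration in range(config.iterations):
        iter_config = SearchConfig(**{**search_config.__dict__})
        iter_config.seed = int(
            np.random.SeedSequence([config.seed, iteration]).generate_state(1)[0]
            % (2**31)
        )
        subnetworks = run_search(
            pin, zmap, processed.significant_genes, iter_config, calib
        )
        filtered = filter_subnetworks(
            subnetworks, config.score_quantile, config.min_significant_genes
        )
        logger.info(
            "iteration %d: %d subnetworks found, %d kept after filtering",
            iteration + 1,
            len(subnetworks),
            len(filtered),
        )
        records = [
            _enrich_subnetwork(sub, gene_sets, pool, config.adjust_method)
            for sub in filtered
        ]
        aggregated = aggregate_subnetworks(records, config.enrichment_threshold)
        for sid, rec in aggregated.items():
            entry = per_pathway.setdefault(
                sid,
                {
                    "lowest_p": rec.adj_p,
                    "highest_p": rec.adj_p,
                    "occurrence": 0,
                    "fold": rec.fold_enrichment,
                },
            )
            entry["occurrence"] += 1
            if rec.adj_p < entry["lowest_p"]:
                entry["lowest_p"] = rec.adj_p
                entry["fold"] = rec.fold_enrichment
            entry["highest_p"] = max(entry["highest_p"], rec.adj_p)

    if not per_pathway:
        logger.warning("no pathway was significantly enriched in any iteration")
        return pd.DataFrame(columns=RESULT_COLUMNS)

    rows = []
    changes = processed.change_values
    for sid, entry in per_pathway.items():
        members = set(gene_sets[sid]) & processed.significant_genes
        if processed.has_change:
            up = sorted(g for g in members if changes.get(g, 0.0) > 0)
            down = sorted(g for g in members if changes.get(g, 0.0) < 0)
            n_zero = sum(1 for g in members if changes.get(g, 0.0) == 0.0)
            if n_zero:
                logger.info(
                    "pathway %s: %d involved genes with change == 0 listed "
                    "under neither direction",
                    sid,
                    n_zero,
                )
        else:
            up, down = sorted(members), []
        rows.append(
            {
                "ID": sid,
                "Description": gene_sets.descriptions[sid],
                "Fold_Enrichment": entry["fold"],
                "occurrence": entry["occurrence"],
                "lowest_p": entry["lowest_p"],
                "highest_p": entry["highest_p"],
                "Up_regulated": up,
                "Down_regulated": down,
            }
        )
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return (
        table.sort_values(["lowest_p", "ID"], kind="stable")
        .reset_index(drop=True)
    )
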