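"""Significance filtering and reconciliation of input genes with the PIN.

The raw differential-expression table is first filtered so that every
retained gene has an adjusted p value at or below the significance
threshold (default 0.05).  Gene symbols absent from the PIN are then
either renamed through an optional alias map (when the canonical symbol
is a PIN node) or dropped; every drop is recorded with a reason code so
a run log can report how much of the input the network actually covers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io_formats import DegTable, InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = ["ProcessedInput", "filter_significant", "map_to_pin"]

REASON_NOT_SIGNIFICANT = "not-significant"
REASON_NOT_IN_PIN = "not-in-PIN"


@dataclass(frozen=True)
class ProcessedInput:
    """Significant input genes reconciled with the PIN.

    ``significant_genes`` are PIN nodes; ``p_values`` and ``change_values``
    are keyed by the (possibly alias-renamed) PIN symbol.  ``dropped``
    maps each discarded input symbol to its reason code.
    """

    significant_genes: frozenset[str]
    p_values: dict[str, float]
    change_values: dict[str, float] = field(default_factory=dict)
    dropped: dict[str, str] = field(default_factory=dict)

    @property
    def has_change(self) -> bool:
        return bool(self.change_values)

    def __len__(self) -> int:
        return len(self.significant_genes)


def filter_significant(deg: DegTable, threshold: float = 0.05) -> DegTable:
    """Keep rows with adjusted p <= threshold (boundary inclusive), preserving order."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    kept = deg.table[deg.table["adj_p"] <= threshold].reset_index(drop=True)
    if kept.empty:
        logger.warning(
            "no genes pass the significance threshold %.3g (input had %d rows)",
            threshold,
            len(deg),
        )
    return DegTable(kept)


def map_to_pin(
    deg: DegTable,
    pin: InteractionNetwork,
    aliases: dict[str, str] | None = None,
) -> ProcessedInput:
    """Reconcile a significance-filtered DEG table with the PIN.

    Symbols found in the PIN are kept as-is.  A symbol absent from the PIN
    whose alias-map image is a PIN node is renamed to that image; when a
    rename collides with an already-kept symbol, the record with the lower
    p value wins (the same rule used for duplicate probes).  Everything
    else is dropped with reason ``not-in-PIN``.
    """
    aliases = aliases or {}
    p_values: dict[str, float] = {}
    change_values: dict[str, float] = {}
    dropped: dict[str, str] = {}
    has_change = deg.has_change

    for row in deg.table.itertuples(index=False):
        gene = row.gene
        if gene in pin:
            target = gene
        elif aliases.get(gene) in pin:
            target = aliases[gene]
        else:
            dropped[gene] = REASON_NOT_IN_PIN
            continue
        if target in p_values and p_values[target] <= row.adj_p:
            continue  # existing record has the lower p
        p_values[target] = row.adj_p
        if has_change:
            change_values[target] = row.change

    n_renamed = sum(
        1
        for row in deg.table.itertuples(index=False)
        if row.gene not in pin and aliases.get(row.gene) in pin
    )
    logger.info(
        "mapped %d/%d significant genes to the PIN (%d via alias, %d dropped)",
        len(p_values),
        len(deg),
        n_renamed,
        len(dropped),
    )
    return ProcessedInput(
        significant_genes=frozenset(p_values),
        p_values=p_values,
        change_values=change_values,
        dropped=dropped,
    )
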