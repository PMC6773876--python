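"""Seedable synthetic data generators for every pipeline input.

The generators emulate the statistical structure the method assumes: a
PIN in which one connected module of genes is strongly significant (the
"planted" active subnetwork) against a background of genes with uniform
p values, a gene-set collection in which one "target" set contains the
planted module among decoy sets of random genes, and an expression
matrix in which the module genes are mean-shifted in cases.

All generators are pure functions of a :class:`FixtureSpec` and its
seed.  The default spec — a 300-node PIN of mean degree 4 with a
15-gene planted module whose p values are drawn from U(1e-6, 1e-3), and
50 decoy gene sets of 10-40 genes plus the target set — is sized so the
full pipeline runs in seconds.

:func:`permute_gene_labels` provides the matching negative control: it
reassigns a table's gene symbols to a random draw from a gene universe,
destroying the correspondence between significance and network
structure while preserving the p-value distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import DegTable, ExpressionMatrix, GeneSetCollection, InteractionNetwork

__all__ = [
    "FixtureSpec",
    "generate_pin",
    "generate_deg_table",
    "generate_gene_sets",
    "generate_expression_matrix",
    "permute_gene_labels",
    "generate_all",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study."""

    seed: int = 0
    n_genes: int = 300
    mean_degree: float = 4.0
    module_size: int = 15
    module_p_lo: float = 1e-6
    module_p_hi: float = 1e-3
    n_decoy_sets: int = 50
    set_size_min: int = 10
    set_size_max: int = 40
    target_set_size: int = 25
    n_cases: int = 10
    n_controls: int = 10
    effect_shift: float = 1.0  # mean shift of module genes in cases
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.module_size > self.n_genes:
            raise ValueError("module larger than the PIN")
        if not (0.0 < self.module_p_lo <= self.module_p_hi <= 1.0):
            raise ValueError("need 0 < module_p_lo <= module_p_hi <= 1")
        if self.target_set_size < self.module_size:
            raise ValueError("target set must be able to contain the module")

    @property
    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    @property
    def module_genes(self) -> list[str]:
        # the first module_size genes; generators plant structure on them
        return self.gene_names[: self.module_size]


def generate_pin(spec: FixtureSpec) -> InteractionNetwork:
    """Random PIN with a connected planted module.

    Background: an Erdos-Renyi-style graph with ``n_genes * mean_degree / 2``
    edges.  The module genes are then fully interconnected — a planted
    clique on a random background, the classic dense-module construct —
    so the module induces a connected (and locally dense) subgraph.
    Isolated nodes are wired to a random neighbor so every gene
    participates in the network.
    """
    rng = np.random.default_rng([spec.seed, 1])
    names = spec.gene_names
    n = spec.n_genes
    n_edges = int(round(n * spec.mean_degree / 2.0))
    g = nx.gnm_random_graph(n, n_edges, seed=int(rng.integers(2**31)))
    graph = nx.relabel_nodes(g, dict(enumerate(names)))

    module = list(spec.module_genes)
    for i, a in enumerate(module):
        for b in module[i + 1 :]:
            graph.add_edge(a, b)

    for node in list(nx.isolates(graph)):
        partner = names[rng.integers(n)]
        while partner == node:
            partner = names[rng.integers(n)]
        graph.add_edge(node, partner)
    graph.remove_edges_from(nx.selfloop_edges(graph))
    return InteractionNetwork(graph)


def generate_deg_table(spec: FixtureSpec) -> DegTable:
    """DEG table with the planted module significant.

    Module genes draw p from U(module_p_lo, module_p_hi) with positive
    change values; background genes draw p from U(0, 1) with signed
    changes.
    """
    rng = np.random.default_rng([spec.seed, 2])
    records = []
    module = set(spec.module_genes)
    for gene in spec.gene_names:
        if gene in module:
            p = float(rng.uniform(spec.module_p_lo, spec.module_p_hi))
            change = float(rng.uniform(0.5, 3.0))
        else:
            p = float(rng.uniform(0.0, 1.0))
            change = float(rng.normal(0.0, 1.5))
        records.append((gene, change, p))
    return DegTable.from_records(records)


def generate_gene_sets(spec: FixtureSpec) -> GeneSetCollection:
    """Decoy gene sets of random PIN genes plus one target set ⊇ the module."""
    rng = np.random.default_rng([spec.seed, 3])
    names = spec.gene_names
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}

    filler_pool = [g for g in names if g not in set(spec.module_genes)]
    n_filler = spec.target_set_size - spec.module_size
    filler = [str(g) for g in rng.choice(filler_pool, size=n_filler, replace=False)]
    sets["TARGET"] = frozenset(spec.module_genes) | frozenset(filler)
    descriptions["TARGET"] = "target pathway containing the planted module"

    width = len(str(spec.n_decoy_sets))
    for i in range(1, spec.n_decoy_sets + 1):
        size = int(rng.integers(spec.set_size_min, spec.set_size_max + 1))
        members = frozenset(
            str(g) for g in rng.choice(names, size=size, replace=False)
        )
        sid = f"DECOY{i:0{width}d}"
        sets[sid] = members
        descriptions[sid] = f"decoy pathway {i}"
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def generate_expression_matrix(spec: FixtureSpec) -> ExpressionMatrix:
    """Gaussian expression with module genes mean-shifted in cases."""
    rng = np.random.default_rng([spec.seed, 4])
    samples = [f"case_{i}" for i in range(1, spec.n_cases + 1)] + [
        f"ctrl_{i}" for i in range(1, spec.n_controls + 1)
    ]
    values = rng.normal(
        0.0, spec.noise_sd, size=(spec.n_genes, len(samples))
    )
    module_idx = [spec.gene_names.index(g) for g in spec.module_genes]
    values[np.ix_(module_idx, range(spec.n_cases))] += spec.effect_shift
    df = pd.DataFrame(values, index=spec.gene_names, columns=samples)
    groups = {
        s: ("case" if s.startswith("case") else "control") for s in samples
    }
    return ExpressionMatrix(values=df, groups=groups)


def permute_gene_labels(deg: DegTable, universe, rng_seed: int) -> DegTable:
    """Replace gene symbols by a uniform random sample from ``universe``.

    P values and change values stay attached to their rows, so the
    p-value distribution is preserved while any correspondence with the
    network is destroyed — the negative control for the whole pipeline.
    """
    universe = sorted(set(universe))
    if len(universe) < len(deg):
        raise ValueError(
            f"universe of {len(universe)} genes smaller than the table ({len(deg)})"
        )
    rng = np.random.default_rng(rng_seed)
    new_genes = [str(g) for g in rng.choice(universe, size=len(deg), replace=False)]
    table = deg.table.copy()
    table["gene"] = new_genes
    return DegTable(table)


def generate_all(spec: FixtureSpec):
    """Convenience: (pin, deg, gene_sets, expression) for one spec."""
    return (
        generate_pin(spec),
        generate_deg_table(spec),
        generate_gene_sets(spec),
        generate_expression_matrix(spec),
    )
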