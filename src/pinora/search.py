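"""Active-subnetwork search: greedy seed expansion, simulated annealing
and a genetic algorithm over the PIN.

An active subnetwork is a connected subgraph of the PIN that
predominantly consists of significant input genes, possibly bridged by
non-significant connector nodes.  All three algorithms optimize the
calibrated subnetwork score s_A (see :mod:`pinora.scoring`):

* **greedy** — every significant gene seeds an expansion; at each step
  the candidate node within graph distance ``depth`` of the current
  members (and within ``max_depth`` of the seed) whose addition most
  increases s_A is added, as long as the increase is strict.  Heavily
  overlapping subnetworks are then pruned, keeping higher scores.
* **simulated annealing** — a random on/off assignment over PIN nodes is
  perturbed one node at a time; worse solutions are accepted with
  probability exp(delta / T) under a geometrically cooled temperature.
* **genetic algorithm** — a population of on/off bit strings evolves by
  rank selection and uniform crossover, with elitism and periodic
  replacement of the worst 10% by random individuals.

For the annealing and genetic searches, a candidate solution may split
into several connected components; its scalar fitness is the maximum
calibrated component score (all components of the best solution are
returned).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import InteractionNetwork
from .scoring import CalibrationTable, subnetwork_raw_score

__all__ = [
    "Subnetwork",
    "SearchConfig",
    "connected_components",
    "greedy_search",
    "filter_overlapping",
    "sa_acceptance",
    "simulated_annealing_search",
    "genetic_search",
    "run_search",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class Subnetwork:
    """A connected gene set with its raw and calibrated scores."""

    genes: frozenset[str]
    raw_score: float
    score: float
    n_significant: int
    seed: str | None = None

    def __len__(self) -> int:
        return len(self.genes)

    def overlap(self, other: "Subnetwork") -> float:
        """|A ∩ B| / min(|A|, |B|)."""
        inter = len(self.genes & other.genes)
        return inter / min(len(self.genes), len(other.genes))

    def jaccard(self, other) -> float:
        other_genes = other.genes if isinstance(other, Subnetwork) else set(other)
        union = self.genes | other_genes
        return len(self.genes & other_genes) / len(union) if union else 0.0


@dataclass
class SearchConfig:
    """Tunable parameters for the three search algorithms."""

    algorithm: str = "greedy"  # greedy | sa | ga
    # greedy
    depth: int = 1  # candidate distance d from the current subnetwork
    max_depth: int = 1  # maximum distance from the seed
    overlap_threshold: float = 0.5
    # simulated annealing
    sa_iterations: int = 10_000
    sa_initial_temperature: float = 1.0
    sa_cooling: float = 0.995
    sa_on_probability: float = 0.1
    # genetic algorithm
    ga_population: int = 400
    ga_generations: int = 200
    ga_mutation_rate: float = 0.0
    ga_replacement_fraction: float = 0.10
    ga_replacement_period: int = 10
    ga_on_probability: float = 0.1
    # shared
    seed: int = 0
    fitness: str = "max"  # max | sum_positive

    def validate(self) -> list[str]:
        problems = []
        if self.algorithm not in ("greedy", "sa", "ga"):
            problems.append(f"unknown algorithm {self.algorithm!r}")
        if not (0.0 <= self.overlap_threshold <= 1.0):
            problems.append("overlap_threshold must be in [0, 1]")
        if not (0.0 < self.sa_cooling < 1.0):
            problems.append("sa_cooling must be in (0, 1)")
        if not (0.0 <= self.ga_mutation_rate <= 1.0):
            problems.append("ga_mutation_rate must be in [0, 1]")
        if self.depth < 1 or self.max_depth < 1:
            problems.append("depth and max_depth must be >= 1")
        if self.ga_population < 2:
            problems.append("ga_population must be >= 2")
        return problems


# ---------------------------------------------------------------------------
# components
# ---------------------------------------------------------------------------


def connected_components(
    pin: InteractionNetwork, on_genes, adjacency: dict[str, set[str]] | None = None
) -> list[set[str]]:
    """Partition ``on_genes`` into maximal connected sets of the induced subgraph.

    Returned in deterministic order: descending size, then by
    lexicographically smallest member.
    """
    on = set(on_genes)
    unknown = on - pin.nodes
    if unknown:
        raise ValueError(f"genes not in PIN: {sorted(unknown)[:5]}")
    adj = adjacency if adjacency is not None else pin.adjacency()
    seen: set[str] = set()
    comps: list[set[str]] = []
    for start in on:
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            node = stack.pop()
            for nbr in adj[node]:
                if nbr in on and nbr not in comp:
                    comp.add(nbr)
                    stack.append(nbr)
        seen |= comp
        comps.append(comp)
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


# ---------------------------------------------------------------------------
# greedy
# ---------------------------------------------------------------------------


def _bfs_within(adj: dict[str, set[str]], sources, cutoff: int) -> set[str]:
    """Nodes within graph distance <= cutoff of any source (sources excluded)."""
    dist = {s: 0 for s in sources}
    frontier = list(sources)
    reached: set[str] = set()
    for d in range(1, cutoff + 1):
        nxt = []
        for node in frontier:
            for nbr in adj[node]:
                if nbr not in dist:
                    dist[nbr] = d
                    nxt.append(nbr)
                    reached.add(nbr)
        frontier = nxt
        if not frontier:
            break
    return reached


def greedy_search(
    pin: InteractionNetwork,
    zmap: dict[str, float],
    significant_genes,
    config: SearchConfig,
    calib: CalibrationTable,
) -> list[Subnetwork]:
    """Expand one candidate subnetwork per significant seed, then prune overlaps.

    Seeds are tried in descending z order (ties alphabetical).  A node is
    added only if it lies within ``config.depth`` of the current members,
    within ``config.max_depth`` of the seed, and strictly increases the
    calibrated score; among equal-improvement candidates the
    alphabetically first wins.
    """
    sig = sorted(set(significant_genes) & pin.nodes)
    if not sig:
        raise ValueError("no seeds: no significant genes are PIN nodes")
    adj = pin.adjacency()
    sig_set = set(sig)
    seeds = sorted(sig, key=lambda g: (-zmap.get(g, 0.0), g))

    results: list[Subnetwork] = []
    for seed in seeds:
        allowed = _bfs_within(adj, [seed], config.max_depth) | {seed}
        members = {seed}
        raw = subnetwork_raw_score(members, zmap)
        score = calib.score(raw, 1)
        while True:
            candidates = (_bfs_within(adj, members, config.depth) - members) & allowed
            best_gene, best_raw, best_score = None, None, score
            for gene in sorted(candidates):
                trial = members | {gene}
                trial_raw = subnetwork_raw_score(trial, zmap)
                trial_score = calib.score(trial_raw, len(trial))
                if trial_score > best_score:
                    best_gene, best_raw, best_score = gene, trial_raw, trial_score
            if best_gene is None:
                break
            members.add(best_gene)
            raw, score = best_raw, best_score
        results.append(
            Subnetwork(
                genes=frozenset(members),
                raw_score=raw,
                score=score,
                n_significant=len(members & sig_set),
                seed=seed,
            )
        )
    return filter_overlapping(results, config.overlap_threshold)


def filter_overlapping(
    subnetworks: list[Subnetwork], threshold: float = 0.5
) -> list[Subnetwork]:
    """Discard subnetworks overlapping a higher-scoring one by more than
    ``threshold``, where overlap(A, B) = |A ∩ B| / min(|A|, |B|).

    The boundary is inclusive: an overlap exactly at the threshold is kept.
    """
    ordered = sorted(
        subnetworks, key=lambda s: (-s.score, tuple(sorted(s.genes)))
    )
    kept: list[Subnetwork] = []
    for sub in ordered:
        if all(sub.overlap(k) <= threshold for k in kept):
            kept.append(sub)
    return kept


# ---------------------------------------------------------------------------
# simulated annealing
# ---------------------------------------------------------------------------


def sa_acceptance(score_new: float, score_current: float, temperature: float) -> float:
    """Probability of accepting a move: 1 if it improves the score, else
    exp((score_new - score_current) / temperature)."""
    if temperature <= 0.0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    delta = score_new - score_current
    if delta > 0.0:
        return 1.0
    return math.exp(delta / temperature)


def _components_to_subnetworks(
    comps: list[set[str]],
    zmap: dict[str, float],
    calib: CalibrationTable,
    sig_set: set[str],
) -> list[Subnetwork]:
    subs = []
    for comp in comps:
        raw = subnetwork_raw_score(comp, zmap)
        subs.append(
            Subnetwork(
                genes=frozenset(comp),
                raw_score=raw,
                score=calib.score(raw, len(comp)),
                n_significant=len(comp & sig_set),
            )
        )
    subs.sort(key=lambda s: (-s.score, tuple(sorted(s.genes))))
    return subs


def _solution_fitness(
    comps: list[set[str]],
    zmap: dict[str, float],
    calib: CalibrationTable,
    mode: str,
) -> float:
    if not comps:
        return NEG_INF
    scores = [
        calib.score(subnetwork_raw_score(c, zmap), len(c)) for c in comps
    ]
    if mode == "sum_positive":
        positive = [s for s in scores if s > 0]
        return sum(positive) if positive else max(scores)
    return max(scores)


def simulated_annealing_search(
    pin: InteractionNetwork,
    zmap: dict[str, float],
    significant_genes,
    config: SearchConfig,
    calib: CalibrationTable,
) -> list[Subnetwork]:
    """Anneal an on/off node assignment toward a high-scoring solution.

    Starts with each node on with probability ``sa_on_probability``; each
    iteration toggles one uniformly random node and accepts the move per
    :func:`sa_acceptance` at a geometrically cooled temperature.  Returns
    the connected components of the best solution seen.
    """
    rng = np.random.default_rng(config.seed)
    nodes = sorted(pin.nodes)
    adj = pin.adjacency()
    sig_set = set(significant_genes) & pin.nodes

    on = set(
        node
        for node, r in zip(nodes, rng.random(len(nodes)))
        if r < config.sa_on_probability
    )
    comps = connected_components(pin, on, adjacency=adj)
    fitness = _solution_fitness(comps, zmap, calib, config.fitness)
    best_on, best_fitness = set(on), fitness

    temperature = config.sa_initial_temperature
    for _ in range(config.sa_iterations):
        node = nodes[rng.integers(len(nodes))]
        if node in on:
            on.discard(node)
        else:
            on.add(node)
        new_comps = connected_components(pin, on, adjacency=adj)
        new_fitness = _solution_fitness(new_comps, zmap, calib, config.fitness)
        if rng.random() < sa_acceptance(new_fitness, fitness, temperature):
            fitness = new_fitness
            if fitness > best_fitness:
                best_fitness, best_on = fitness, set(on)
        else:  # revert the toggle
            if node in on:
                on.discard(node)
            else:
                on.add(node)
        temperature *= config.sa_cooling

    best_comps = connected_components(pin, best_on, adjacency=adj)
    return _components_to_subnetworks(best_comps, zmap, calib, sig_set)


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------


def genetic_search(
    pin: InteractionNetwork,
    zmap: dict[str, float],
    significant_genes,
    config: SearchConfig,
    calib: CalibrationTable,
    return_trace: bool = False,
):
    """Evolve a population of on/off bit strings over the PIN nodes.

    Rank selection (selection probability proportional to fitness rank),
    uniform crossover (each bit from either parent with probability 1/2),
    optional per-bit mutation (off by default), elitism (the previous
    best individual is preserved whenever the new generation's best is
    worse) and, every ``ga_replacement_period`` generations, replacement
    of the worst ``ga_replacement_fraction`` of the population by fresh
    random individuals.

    Returns the components of the best individual; with
    ``return_trace=True`` also returns the best-so-far fitness per
    generation.
    """
    if config.ga_population < 2 or config.ga_generations < 1:
        raise ValueError("need ga_population >= 2 and ga_generations >= 1")
    rng = np.random.default_rng(config.seed)
    nodes = sorted(pin.nodes)
    n = len(nodes)
    adj = pin.adjacency()
    sig_set = set(significant_genes) & pin.nodes
    pop_size = config.ga_population

    def fitness_of(bits: np.ndarray) -> float:
        on = {nodes[i] for i in np.flatnonzero(bits)}
        comps = connected_components(pin, on, adjacency=adj)
        return _solution_fitness(comps, zmap, calib, config.fitness)

    population = rng.random((pop_size, n)) < config.ga_on_probability
    fitnesses = np.array([fitness_of(ind) for ind in population])

    trace: list[float] = []
    best_bits = population[int(np.argmax(fitnesses))].copy()
    best_fitness = float(np.max(fitnesses))

    for generation in range(1, config.ga_generations + 1):
        # rank selection: worst gets weight 1, best gets weight pop_size
        order = np.argsort(fitnesses, kind="stable")
        ranks = np.empty(pop_size)
        ranks[order] = np.arange(1, pop_size + 1)
        probs = ranks / ranks.sum()

        parents_a = rng.choice(pop_size, size=pop_size, p=probs)
        parents_b = rng.choice(pop_size, size=pop_size, p=probs)
        mask = rng.random((pop_size, n)) < 0.5
        offspring = np.where(mask, population[parents_a], population[parents_b])
        if config.ga_mutation_rate > 0.0:
            flips = rng.random((pop_size, n)) < config.ga_mutation_rate
            offspring ^= flips

        population = offspring
        fitnesses = np.array([fitness_of(ind) for ind in population])

        # elitism: restore the previous best if this generation regressed
        if float(np.max(fitnesses)) < best_fitness:
            worst = int(np.argmin(fitnesses))
            population[worst] = best_bits
            fitnesses[worst] = best_fitness

        # periodic diversification: worst 10% replaced by random solutions
        if config.ga_replacement_period > 0 and (
            generation % config.ga_replacement_period == 0
        ):
            n_replace = int(config.ga_replacement_fraction * pop_size)
            if n_replace > 0:
                worst_idx = np.argsort(fitnesses, kind="stable")[:n_replace]
                replacements = rng.random((n_replace, n)) < config.ga_on_probability
                population[worst_idx] = replacements
                fitnesses[worst_idx] = [fitness_of(ind) for ind in replacements]

        gen_best = int(np.argmax(fitnesses))
        if float(fitnesses[gen_best]) > best_fitness:
            best_fitness = float(fitnesses[gen_best])
            best_bits = population[gen_best].copy()
        trace.append(best_fitness)

    best_on = {nodes[i] for i in np.flatnonzero(best_bits)}
    comps = connected_components(pin, best_on, adjacency=adj)
    subs = _components_to_subnetworks(comps, zmap, calib, sig_set)
    if return_trace:
        return subs, trace
    return subs


def run_search(
    pin: InteractionNetwork,
    zmap: dict[str, float],
    significant_genes,
    config: SearchConfig,
    calib: CalibrationTable,
) -> list[Subnetwork]:
    """Dispatch to the configured search algorithm."""
    if config.algorithm == "greedy":
        return greedy_search(pin, zmap, significant_genes, config, calib)
    if config.algorithm == "sa":
        return simulated_annealing_search(pin, zmap, significant_genes, config, calib)
    if config.algorithm == "ga":
        return genetic_search(pin, zmap, significant_genes, config, calib)
    raise ValueError(f"unknown algorithm {config.algorithm!r}")
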