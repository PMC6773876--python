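"""Subnetwork scoring: gene-level z scores, aggregate scores and
Monte-Carlo background calibration.

Each significant gene's adjusted p value is converted to a z score

    z_i = Phi^-1(1 - p_i),

where Phi^-1 is the inverse standard-normal CDF, so small p values map to
large positive z.  A subnetwork A of k genes is scored by the
size-normalized aggregate

    z_A = (1 / sqrt(k)) * sum_{i in A} z_i,

the aggregate used by the jActiveModules scoring scheme of Ideker et al.
Because z_A still depends on the score distribution over the network, it
is calibrated against a Monte-Carlo background: for each size k, 2,000
uniformly random k-subsets of PIN nodes are scored, and

    s_A = (z_A - mu_k) / sigma_k

standardizes z_A against the sampled mean and standard deviation for
that size.  Nodes that are not significant input genes (connector nodes)
contribute z = 0, so they dilute a subnetwork's score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import InteractionNetwork

__all__ = [
    "P_FLOOR",
    "SIGMA_ZERO_SENTINEL",
    "p_to_z",
    "build_zscore_map",
    "subnetwork_raw_score",
    "CalibrationTable",
    "calibrate_background",
    "calibrated_score",
]

# p values are clamped away from {0, 1} before inversion; Phi^-1 diverges there
P_FLOOR = 1e-15
# stands in for +/- infinity when sigma_k == 0 so score comparisons stay total
SIGMA_ZERO_SENTINEL = 1e9


def p_to_z(p: float) -> float:
    """Convert an adjusted p value to z = Phi^-1(1 - p).

    Strictly decreasing in p; p is clamped to [P_FLOOR, 1 - P_FLOOR]
    before inversion so the result is always finite.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p value {p} outside [0, 1]")
    p = min(max(p, P_FLOOR), 1.0 - P_FLOOR)
    return float(stats.norm.isf(p))


def build_zscore_map(p_values: dict[str, float]) -> dict[str, float]:
    """z score per significant input gene (genes outside this map score 0)."""
    return {gene: p_to_z(p) for gene, p in p_values.items()}


def subnetwork_raw_score(genes, zmap: dict[str, float]) -> float:
    """Aggregate score z_A = k^(-1/2) * sum of member z scores.

    Genes absent from ``zmap`` (non-input connector nodes) contribute 0.
    """
    genes = list(genes)
    k = len(genes)
    if k == 0:
        raise ValueError("cannot score an empty subnetwork")
    return sum(zmap.get(g, 0.0) for g in genes) / np.sqrt(k)


@dataclass
class CalibrationTable:
    """Background mean and standard deviation of z_A per subnetwork size.

    Built lazily: ``mu_sigma(k)`` draws the background for size k on first
    use.  The same ``draws`` random node permutations back every size (the
    size-k subset of draw d is the first k elements of permutation d), a
    common-random-numbers scheme that keeps each subset an exact uniform
    k-subset while making mu_k and sigma_k vary smoothly in k, so score
    comparisons between adjacent sizes are not dominated by independent
    Monte-Carlo noise.  Deterministic given the seed, regardless of query
    order.
    """

    pin: InteractionNetwork
    zmap: dict[str, float]
    draws: int = 2000
    seed: int = 0
    connected: bool = False
    _table: dict[int, tuple[float, float]] = field(default_factory=dict, repr=False)
    _nodes: list[str] = field(default=None, repr=False)  # type: ignore[assignment]
    _z: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _perm: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.draws < 2:
            raise ValueError("need at least 2 background draws per size")
        self._nodes = sorted(self.pin.nodes)
        self._z = np.array([self.zmap.get(g, 0.0) for g in self._nodes])

    def _permutations(self) -> np.ndarray:
        if self._perm is None:
            rng = np.random.default_rng(self.seed)
            keys = rng.random((self.draws, len(self._nodes)))
            self._perm = np.argsort(keys, axis=1).astype(np.int32)
        return self._perm

    def sizes(self) -> list[int]:
        return sorted(self._table)

    def mu_sigma(self, k: int) -> tuple[float, float]:
        if k < 1 or k > len(self._nodes):
            raise KeyError(f"subnetwork size {k} outside 1..{len(self._nodes)}")
        if k not in self._table:
            self._table[k] = self._draw(k)
        return self._table[k]

    def _draw(self, k: int) -> tuple[float, float]:
        if self.connected:
            rng = np.random.default_rng([self.seed, k])
            scores = self._draw_connected(k, rng)
        else:
            idx = self._permutations()[:, :k]
            scores = self._z[idx].sum(axis=1) / np.sqrt(k)
        if np.ptp(scores) == 0.0:  # every draw identical, e.g. k == |PIN|
            return float(scores[0]), 0.0
        mu = float(np.mean(scores))
        sigma = float(np.std(scores, ddof=1))
        return mu, sigma

    def _draw_connected(self, k: int, rng: np.random.Generator) -> np.ndarray:
        """Random connected k-subsets grown by neighbor expansion."""
        adj = self.pin.adjacency()
        zlookup = self.zmap
        scores = np.empty(self.draws)
        for d in range(self.draws):
            start = self._nodes[rng.integers(len(self._nodes))]
            members = {start}
            frontier = set(adj[start])
            while len(members) < k and frontier:
                nxt = sorted(frontier)[rng.integers(len(frontier))]
                members.add(nxt)
                frontier |= adj[nxt]
                frontier -= members
            # a draw stuck in a small component is scored at its actual size
            scores[d] = sum(zlookup.get(g, 0.0) for g in members) / np.sqrt(
                len(members)
            )
        return scores

    def score(self, z_a: float, k: int) -> float:
        """Calibrated score s_A = (z_A - mu_k) / sigma_k."""
        mu, sigma = self.mu_sigma(k)
        if sigma == 0.0:
            if z_a == mu:
                return 0.0
            return SIGMA_ZERO_SENTINEL if z_a > mu else -SIGMA_ZERO_SENTINEL
        return (z_a - mu) / sigma

    def score_genes(self, genes) -> float:
        genes = list(genes)
        return self.score(subnetwork_raw_score(genes, self.zmap), len(genes))


def calibrate_background(
    pin: InteractionNetwork,
    zmap: dict[str, float],
    k_max: int,
    draws: int = 2000,
    rng_seed: int = 0,
    connected: bool = False,
) -> CalibrationTable:
    """Build a calibration table covering every size 1..k_max eagerly."""
    if k_max > pin.n_nodes:
        raise ValueError(f"k_max={k_max} exceeds PIN size {pin.n_nodes}")
    table = CalibrationTable(
        pin=pin, zmap=zmap, draws=draws, seed=rng_seed, connected=connected
    )
    for k in range(1, k_max + 1):
        table.mu_sigma(k)
    return table


def calibrated_score(z_a: float, k: int, calib: CalibrationTable) -> float:
    """Standardize a raw subnetwork score against the size-k background."""
    if k not in calib._table:
        raise KeyError(f"size {k} not present in calibration table")
    return calib.score(z_a, k)
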