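"""Small-world network metrics: edge count, clustering coefficient, path length.

Two clustering formulations are provided.  ``global_triplet`` is the
weighted-network generalization of transitivity (Opsahl-style): the total
*triplet value* of closed triplets divided by the total triplet value of all
triplets, where a triplet centered at node i with neighbours j, k carries a
value derived from the two edge weights w_ij, w_ik (arithmetic mean by
default; geometric mean, max and min are available).  On binary graphs every
triplet value is 1 and the measure reduces to classical transitivity.
``average_local`` is the Watts-Strogatz mean of per-node clustering on the
binary support, with degree < 2 nodes contributing 0.

Weighted shortest paths use edge cost (1/w)**alpha, so strong connections are
short; the characteristic path length L is the mean shortest-path distance
over node pairs.  Disconnected pairs are handled by an explicit policy;
the default averages over reachable pairs only and reports the reachable
fraction, so that sparse "no longer consistent" networks can be detected and
excluded downstream rather than silently averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

CLUSTERING_VARIANTS = ("global_triplet", "average_local")
TRIPLET_VALUES = ("arithmetic_mean", "geometric_mean", "max", "min")
UNREACHABLE_POLICIES = ("reachable_pairs_only", "harmonic", "error")


class NoTripletsWarning(UserWarning):
    """The graph has no connected triplets; clustering reported as 0."""


class UnreachablePairsError(ValueError):
    """Raised by the ``error`` unreachable policy when the graph is disconnected."""


@dataclass(frozen=True)
class MetricConfig:
    """How the three small-world parameters are computed.

    Attributes
    ----------
    weighted
        Use edge weights (tnet-style). ``False`` computes on the binary support.
    clustering_variant
        ``"global_triplet"`` (default) or ``"average_local"``.
    triplet_value
        Weight of a triplet in the global variant: ``"arithmetic_mean"``
        (default), ``"geometric_mean"``, ``"max"`` or ``"min"`` of its two
        edge weights.
    distance_alpha
        Exponent in the edge cost ``(1/w)**alpha`` for weighted paths;
        alpha=1 is the plain inverse-weight cost.
    unreachable_policy
        ``"reachable_pairs_only"`` (default), ``"harmonic"`` or ``"error"``.
    """

    weighted: bool = True
    clustering_variant: str = "global_triplet"
    triplet_value: str = "arithmetic_mean"
    distance_alpha: float = 1.0
    unreachable_policy: str = "reachable_pairs_only"

    def __post_init__(self) -> None:
        if self.clustering_variant not in CLUSTERING_VARIANTS:
            raise ValueError(f"unknown clustering variant {self.clustering_variant!r}")
        if self.triplet_value not in TRIPLET_VALUES:
            raise ValueError(f"unknown triplet value rule {self.triplet_value!r}")
        if not self.distance_alpha > 0:
            raise ValueError("distance_alpha must be > 0")
        if self.unreachable_policy not in UNREACHABLE_POLICIES:
            raise ValueError(f"unknown unreachable policy {self.unreachable_policy!r}")

    def to_dict(self) -> dict:
        return {
            "weighted": self.weighted,
            "clustering_variant": self.clustering_variant,
            "triplet_value": self.triplet_value,
            "distance_alpha": self.distance_alpha,
            "unreachable_policy": self.unreachable_policy,
        }


DEFAULT_CONFIG = MetricConfig()


@dataclass(frozen=True)
class NetworkMetrics:
    """The three small-world parameters of one network, with computation flags.

    ``consistent`` is True iff the graph has at least one edge and every node
    pair is mutually reachable; inconsistent networks are what the
    multiple-thresholds pipeline drops.
    """

    n_edges: int
    clustering: float
    path_length: float  # nan when no pair is reachable
    reachable_fraction: float
    consistent: bool
    clustering_defined: bool
    config_used: MetricConfig = field(default=DEFAULT_CONFIG)

    def to_dict(self) -> dict:
        return {
            "n_edges": self.n_edges,
            "clustering": self.clustering,
            "path_length": self.path_length,
            "reachable_fraction": self.reachable_fraction,
            "consistent": self.consistent,
            "clustering_defined": self.clustering_defined,
            "config": self.config_used.to_dict(),
        }


# ---------------------------------------------------------------------------
# Internal fast paths operating on raw weight matrices (zero diagonal,
# symmetric, non-negative).  The public API wraps these with validation.
# ---------------------------------------------------------------------------

def _edge_count(w: np.ndarray) -> int:
    return int(np.count_nonzero(np.triu(w, 1)))


def _clustering(w: np.ndarray, config: MetricConfig) -> tuple[float, float]:
    """Return (clustering value, total triplet mass).

    Zero triplet mass means the coefficient is undefined; 0.0 is returned
    with mass 0 so callers can flag it.
    """
    if np.any(w < 0):
        raise ValueError("clustering undefined for negative weights")
    a = (w > 0).astype(float)
    W = w if config.weighted else a

    if config.clustering_variant == "average_local":
        # Watts–Strogatz on the binary support: C_i = triangles_i / (k_i choose 2)
        k = a.sum(axis=1)
        tri2 = ((a @ a) * a).sum(axis=1)  # 2 * triangles through each node
        denom = k * (k - 1.0)
        n_triplets = float(denom.sum() / 2.0)
        local = np.zeros_like(k)
        pos = denom > 0
        local[pos] = tri2[pos] / denom[pos]
        return float(np.clip(local.mean(), 0.0, 1.0)), n_triplets

    tv = config.triplet_value
    if tv == "arithmetic_mean":
        s = W.sum(axis=1)
        k = a.sum(axis=1)
        total = float((s * (k - 1.0)).sum() / 2.0)
        closed = float((W * (a @ a)).sum() / 2.0)
    elif tv == "geometric_mean":
        S = np.sqrt(W)
        rs = S.sum(axis=1)
        total = float(((rs**2 - W.sum(axis=1))).sum() / 2.0)
        closed = float(((S @ a) * S).sum() / 2.0)
    else:  # max / min need explicit neighbour pairs
        op = np.maximum if tv == "max" else np.minimum
        total = 0.0
        closed = 0.0
        n = w.shape[0]
        for i in range(n):
            nb = np.flatnonzero(a[i])
            if nb.size < 2:
                continue
            wv = W[i, nb]
            pair = op.outer(wv, wv)
            iu = np.triu_indices(nb.size, 1)
            vals = pair[iu]
            total += float(vals.sum())
            closed += float((vals * a[np.ix_(nb, nb)][iu]).sum())
    if total <= 0.0:
        return 0.0, 0.0
    return float(np.clip(closed / total, 0.0, 1.0)), total


def _distances(w: np.ndarray, config: MetricConfig) -> np.ndarray:
    if np.any(w < 0):
        raise ValueError("shortest paths undefined for negative weights")
    if config.weighted:
        cost = np.zeros_like(w)
        nz = w > 0
        cost[nz] = (1.0 / w[nz]) ** config.distance_alpha
        d = shortest_path(csr_matrix(cost), method="D", directed=False)
    else:
        d = shortest_path(
            csr_matrix((w > 0).astype(np.int8)), method="D", directed=False, unweighted=True
        )
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def _path_length(d: np.ndarray, config: MetricConfig) -> tuple[float, float]:
    n = d.shape[0]
    iu = np.triu_indices(n, 1)
    vals = d[iu]
    finite = np.isfinite(vals)
    reachable_fraction = float(finite.mean()) if vals.size else 0.0
    if config.unreachable_policy == "error":
        if not finite.all():
            raise UnreachablePairsError(
                f"{int((~finite).sum())} of {vals.size} node pairs unreachable"
            )
        return float(vals.mean()), 1.0
    if config.unreachable_policy == "harmonic":
        with np.errstate(divide="ignore"):
            inv = np.where(finite & (vals > 0), 1.0 / vals, 0.0)
        total = float(inv.sum())
        return (float(vals.size) / total if total > 0 else float("inf")), reachable_fraction
    # reachable_pairs_only
    if not finite.any():
        return float("nan"), reachable_fraction
    return float(vals[finite].mean()), reachable_fraction


def _metrics_from_weights(
    w: np.ndarray, config: MetricConfig, include_edges: bool = True
) -> dict[str, float]:
    """Metric-name -> value dict on a raw weight matrix (permutation hot path)."""
    out: dict[str, float] = {}
    if include_edges:
        out["n_edges"] = float(_edge_count(w))
    out["clustering"] = _clustering(w, config)[0]
    out["path_length"] = _path_length(_distances(w, config), config)[0]
    return out


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def edge_count(matrix) -> int:
    """Number of unordered node pairs with a nonzero weight."""
    return _edge_count(matrix.weights)


def clustering_coefficient(matrix, config: MetricConfig = DEFAULT_CONFIG) -> float:
    """Clustering coefficient in [0, 1]; see module docstring for variants.

    Emits :class:`NoTripletsWarning` and returns 0.0 when the graph has no
    connected triplets (the coefficient is then undefined).
    """
    if matrix.n_nodes < 3:
        raise ValueError("clustering requires at least 3 nodes")
    value, mass = _clustering(matrix.weights, config)
    if mass == 0.0:
        warnings.warn("graph has no triplets; clustering reported as 0",
                      NoTripletsWarning, stacklevel=2)
    return value


def shortest_path_matrix(matrix, config: MetricConfig = DEFAULT_CONFIG) -> np.ndarray:
    """All-pairs shortest-path distances (np.inf for unreachable pairs).

    Binary mode gives hop counts; weighted mode minimizes the summed edge
    cost (1/w)**alpha along paths (Dijkstra).
    """
    return _distances(matrix.weights, config)


def characteristic_path_length(
    distances: np.ndarray, config: MetricConfig = DEFAULT_CONFIG
) -> tuple[float, float]:
    """(L, reachable_fraction) from a distance matrix.

    ``reachable_pairs_only``: mean of finite off-diagonal distances over
    unordered pairs (nan if none).  ``harmonic``: number of pairs divided by
    the summed reciprocal distances, unreachable pairs contributing 0.
    ``error``: raise on any unreachable pair.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    return _path_length(d, config)


def network_metrics(matrix, config: MetricConfig = DEFAULT_CONFIG) -> NetworkMetrics:
    """Bundle edge count, clustering and path length with consistency flags."""
    w = matrix.weights
    e = _edge_count(w)
    c, mass = _clustering(w, config)
    length, reachable = _path_length(_distances(w, config), config)
    return NetworkMetrics(
        n_edges=e,
        clustering=c,
        path_length=length,
        reachable_fraction=reachable,
        consistent=bool(e >= 1 and reachable >= 1.0 - 1e-12),
        clustering_defined=bool(mass > 0.0),
        config_used=config,
    )
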