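"""Time-specific directed network construction.

The undirected backbone is a soft-power co-expression adjacency
``a_ij = |PCC(g_i, g_j)|^power`` thresholded at ``cutoff``, built from the
reference and case samples pooled at one time point. Each backbone edge is
then oriented by the direction-determination index

    omega_{i,j} = I((U+V)/2 ; Y) - I(U ; Y)

where U, V are the expression profiles of g_i, g_j over those samples, Y is
the binary reference/case phenotype, and I(.;.) is mutual information of the
equal-frequency-discretized profile with the labels. A directed edge
g_i -> g_j is emitted when omega_{i,j} > 0: averaging in g_j's profile
improved how well g_i's profile separates reference from case, i.e. g_j adds
phenotype-relevant information downstream of g_i. Both orientations may
coexist; omega = 0 yields no edge.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import networkx as nx

from .data_io import ExpressionMatrix

__all__ = [
    "default_bins",
    "mutual_information",
    "direction_index",
    "build_backbone",
    "orient_edges",
]


def default_bins(n_samples: int) -> int:
    """Equal-frequency bin count B = max(2, ceil(sqrt(n)))."""
    return max(2, int(np.ceil(np.sqrt(n_samples))))


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency bin assignment, invariant under strictly monotone maps.

    Bin edges are interior quantiles; a value equal to an edge joins the
    upper bin, so tied values always share a bin.
    """
    edges = np.quantile(x, np.arange(1, bins) / bins)
    return np.searchsorted(edges, x, side="right")


def mutual_information(x: Sequence[float], y: Sequence[int], bins: int) -> float:
    """Mutual information (nats) between a discretized profile and binary labels.

    The continuous profile is cut into ``bins`` equal-frequency bins and the
    plug-in estimate ``sum p(x,y) log[p(x,y) / (p(x) p(y))]`` is taken over
    the joint count table, with 0 log 0 := 0. A constant profile occupies a
    single bin and returns exactly 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: x has {x.size}, y has {y.size}")
    if x.size < 4:
        raise ValueError("need at least 4 samples to estimate mutual information")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if np.ptp(x) == 0:
        warnings.warn("constant profile: mutual information degenerate, returning 0")
        return 0.0
    return _mi_from_codes(_discretize(x, bins), y)


def _mi_from_codes(codes: np.ndarray, y: np.ndarray) -> float:
    n = codes.size
    n_codes = int(codes.max()) + 1
    joint = np.bincount(codes * 2 + y, minlength=n_codes * 2).reshape(n_codes, 2)
    joint = joint / n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (px * py))
    return float(np.nansum(terms))


def direction_index(U: Sequence[float], V: Sequence[float],
                    y: Sequence[int], bins: int) -> float:
    """omega_{i,j}: mutual-information gain of the averaged pair profile.

    ``omega = I((U+V)/2 ; y) - I(U ; y)``. The average is taken on the
    expression scale supplied by the caller (raw or log), before
    discretization; equal weighting keeps the crossover profile on the same
    scale as the inputs.
    """
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    y = np.asarray(y, dtype=int)
    if not (U.shape == V.shape == y.shape):
        raise ValueError("U, V and y must share one sample axis")
    if np.ptp(y) == 0:
        return 0.0
    crossover = 0.5 * (U + V)
    if np.ptp(crossover) == 0:
        mi_cross = 0.0
    else:
        mi_cross = _mi_from_codes(_discretize(crossover, bins), y)
    if np.ptp(U) == 0:
        mi_u = 0.0
    else:
        mi_u = _mi_from_codes(_discretize(U, bins), y)
    return mi_cross - mi_u


def build_backbone(expr: ExpressionMatrix, power: float = 6.0,
                   cutoff: float = 0.3) -> nx.Graph:
    """Soft-power co-expression backbone over the pooled samples.

    ``a_ij = |PCC|^power``; the undirected edge {i, j} is kept iff
    ``a_ij >= cutoff``. Genes that are constant across the pooled samples
    have no defined correlation and are excluded (kept out of the node set)
    with a warning.
    """
    if expr.n_samples < 4:
        raise ValueError("need >= 4 pooled samples to build a backbone")
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    constant = expr.zero_variance_genes()
    if constant:
        warnings.warn(
            f"excluding {len(constant)} zero-variance gene(s) from the backbone"
        )
        keep = [g for g in expr.gene_ids if g not in set(constant)]
        expr = expr.subset_genes(keep)
    graph = nx.Graph()
    graph.add_nodes_from(expr.gene_ids)
    if expr.n_genes < 2:
        return graph
    adjacency = np.abs(np.corrcoef(expr.values)) ** power
    np.fill_diagonal(adjacency, 0.0)
    ii, jj = np.nonzero(np.triu(adjacency >= cutoff, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        graph.add_edge(expr.gene_ids[i], expr.gene_ids[j],
                       weight=float(adjacency[i, j]))
    return graph


def orient_edges(backbone: nx.Graph, expr: ExpressionMatrix,
                 y: Sequence[int], bins: int | None = None) -> nx.DiGraph:
    """Orient every backbone edge with the direction index.

    For each undirected edge {i, j}, omega_{i,j} and omega_{j,i} are
    evaluated independently and each directed edge with omega > 0 is
    emitted (both may survive). Nodes losing all incident edges stay in the
    graph as isolated nodes; they later receive a local score of 0.
    """
    y = np.asarray(y, dtype=int)
    if y.size != expr.n_samples:
        raise ValueError("phenotype length must match sample count")
    if bins is None:
        bins = default_bins(expr.n_samples)
    net = nx.DiGraph()
    net.add_nodes_from(backbone.nodes)
    if backbone.number_of_edges() == 0 or np.ptp(y) == 0:
        return net
    pos = {g: k for k, g in enumerate(expr.gene_ids)}
    values = expr.values
    # Per-gene MI with the phenotype is shared by every incident edge.
    mi_single: dict[str, float] = {}
    codes_cache: dict[str, np.ndarray] = {}
    for g in backbone.nodes:
        row = values[pos[g]]
        if np.ptp(row) == 0:
            mi_single[g] = 0.0
        else:
            codes_cache[g] = _discretize(row, bins)
            mi_single[g] = _mi_from_codes(codes_cache[g], y)
    for gi, gj in backbone.edges:
        crossover = 0.5 * (values[pos[gi]] + values[pos[gj]])
        if np.ptp(crossover) == 0:
            mi_cross = 0.0
        else:
            mi_cross = _mi_from_codes(_discretize(crossover, bins), y)
        omega_ij = mi_cross - mi_single[gi]
        omega_ji = mi_cross - mi_single[gj]
        if omega_ij > 0:
            net.add_edge(gi, gj, omega=float(omega_ij))
        if omega_ji > 0:
            net.add_edge(gj, gi, omega=float(omega_ji))
    return net
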