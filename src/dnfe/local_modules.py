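"""Local gene modules and top-l local network selection.

Every gene g_k in the directed network defines a local module: its
first-order out-neighbors and in-neighbors, and for each first-order
neighbor g_j its own (second-order) out- and in-neighbor lists. First-order
neighbors are ranked by crossover strength

    D_j = lambda * D_j_in + (1 - lambda) * D_j_out

where D_j_in (resp. D_j_out) sums g_j's second-order in-edge (out-edge)
weights after normalizing each directional weight set to total 1. The edge
weights are single-sample perturbation statistics

    W_ij = (n - 1) |PCC_{n+1} - PCC_n| / (1 - PCC_n^2)

comparing the gene-pair correlation over the n reference samples with the
correlation after appending one case sample. The top-l neighbors by D (ties
broken by gene ID) plus the center form the local network scored by the
flow entropy.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
import networkx as nx

from .data_io import ExpressionMatrix

__all__ = [
    "LocalModule",
    "NeighborScore",
    "LocalNetwork",
    "extract_module",
    "perturbed_pcc_weight",
    "crossover_strength",
    "select_local_network",
]

PCC_DENOM_FLOOR = 1e-6


@dataclasses.dataclass
class LocalModule:
    """First- and second-order neighborhood of a center gene."""

    center: str
    out_neighbors: list[str]
    in_neighbors: list[str]
    #: per first-order neighbor: its out-neighbor list (second order)
    second_order_out: dict[str, list[str]]
    #: per first-order neighbor: its in-neighbor list (second order)
    second_order_in: dict[str, list[str]]

    @property
    def first_order(self) -> list[str]:
        """All first-order neighbors (union of the two roles), deduplicated."""
        return list(dict.fromkeys(self.out_neighbors + self.in_neighbors))


@dataclasses.dataclass(frozen=True)
class NeighborScore:
    neighbor: str
    D_in: float
    D_out: float
    lam: float

    @property
    def D(self) -> float:
        return self.lam * self.D_in + (1.0 - self.lam) * self.D_out


@dataclasses.dataclass
class LocalNetwork:
    """Center gene with its selected out/in neighbors (a_k + b_k <= l)."""

    center: str
    out_selected: list[str]
    in_selected: list[str]
    l: int

    @property
    def a_k(self) -> int:
        return len(self.out_selected)

    @property
    def b_k(self) -> int:
        return len(self.in_selected)


def extract_module(net: nx.DiGraph, center: str) -> LocalModule:
    """Breadth-2 neighborhood of ``center`` in the directed network.

    The center itself never appears in any neighbor list. An isolated
    center yields empty lists — a valid module whose local score is 0.
    """
    if center not in net:
        raise KeyError(f"gene {center!r} not in network")
    out_nb = [g for g in net.successors(center) if g != center]
    in_nb = [g for g in net.predecessors(center) if g != center]
    second_out: dict[str, list[str]] = {}
    second_in: dict[str, list[str]] = {}
    for g in dict.fromkeys(out_nb + in_nb):
        second_out[g] = [h for h in net.successors(g) if h != center]
        second_in[g] = [h for h in net.predecessors(g) if h != center]
    return LocalModule(center, out_nb, in_nb, second_out, second_in)


def perturbed_pcc_weight(gi: str, gj: str, ref: ExpressionMatrix,
                         case_sample: Mapping[str, float] | Sequence[float]) -> float:
    """Single-sample perturbation weight of the edge (g_i, g_j).

    ``W = (n-1) |PCC_{n+1} - PCC_n| / (1 - PCC_n^2)`` where PCC_n uses the n
    reference samples and PCC_{n+1} additionally includes the one case
    sample. The denominator is floored at 1e-6 so that perfectly collinear
    reference profiles give a large finite weight rather than infinity.
    """
    n = ref.n_samples
    if n < 3:
        raise ValueError("need >= 3 reference samples")
    xi = ref.values[ref.gene_ids.index(gi)]
    xj = ref.values[ref.gene_ids.index(gj)]
    if np.ptp(xi) == 0 or np.ptp(xj) == 0:
        raise ValueError(f"gene {gi!r} or {gj!r} constant on reference samples")
    if isinstance(case_sample, Mapping):
        ci, cj = float(case_sample[gi]), float(case_sample[gj])
    else:
        case_sample = np.asarray(case_sample, dtype=float)
        ci = float(case_sample[ref.gene_ids.index(gi)])
        cj = float(case_sample[ref.gene_ids.index(gj)])
    pcc_n = _pearson(xi, xj)
    pcc_n1 = _pearson(np.append(xi, ci), np.append(xj, cj))
    denom = 1.0 - pcc_n ** 2
    if denom < PCC_DENOM_FLOOR:
        warnings.warn(
            f"|PCC| ~ 1 for pair ({gi}, {gj}); denominator clamped to {PCC_DENOM_FLOOR}"
        )
        denom = PCC_DENOM_FLOOR
    return (n - 1) * abs(pcc_n1 - pcc_n) / denom


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


WeightFn = Callable[[str, str], float]


def crossover_strength(module: LocalModule, neighbor: str,
                       weights: Mapping[tuple[str, str], float] | WeightFn,
                       lam: float = 0.2) -> NeighborScore:
    """Crossover strength of one first-order neighbor.

    The neighbor's second-order in-edge weights are normalized to sum to 1
    (likewise its out-edge weights); D_in and D_out are the normalized sums
    and ``D = lam * D_in + (1 - lam) * D_out``. A neighbor with no
    second-order edges in a direction contributes 0 on that side, so
    D always lies in [0, 1].
    """
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must lie strictly inside (0, 1)")
    if neighbor not in module.first_order:
        raise KeyError(f"{neighbor!r} is not a first-order neighbor of {module.center!r}")
    getw = weights.__getitem__ if isinstance(weights, Mapping) else weights
    in_w = np.array([getw((src, neighbor)) if isinstance(weights, Mapping)
                     else weights(src, neighbor)
                     for src in module.second_order_in.get(neighbor, [])])
    out_w = np.array([getw((neighbor, tgt)) if isinstance(weights, Mapping)
                      else weights(neighbor, tgt)
                      for tgt in module.second_order_out.get(neighbor, [])])
    return NeighborScore(neighbor, _normalized_sum(in_w), _normalized_sum(out_w), lam)


def _normalized_sum(w: np.ndarray) -> float:
    if w.size == 0:
        return 0.0
    total = float(w.sum())
    if total <= 0.0:
        return 0.0
    # sum of w_i / total, evaluated as one quotient so the telescoped
    # value is exactly 1 and never perturbs downstream tie-breaking
    return float(w.sum() / total)


def select_local_network(module: LocalModule, scores: Sequence[NeighborScore],
                         l: int = 10) -> LocalNetwork:
    """Keep the top-l first-order neighbors by crossover strength.

    A gene adjacent to the center in both directions occupies one selection
    slot per role, so a_k + b_k = min(l, m_k + n_k). Ranking is by D
    descending with ties broken by gene ID (then role, out before in) so
    the selection is deterministic and independent of input order.
    """
    if l < 1:
        raise ValueError("l must be positive")
    d_of = {s.neighbor: s.D for s in scores}
    missing = [g for g in module.first_order if g not in d_of]
    if missing:
        raise ValueError(f"no crossover score for neighbor(s) {missing[:5]}")
    candidates = [(g, "out") for g in module.out_neighbors] + \
                 [(g, "in") for g in module.in_neighbors]
    candidates.sort(key=lambda gr: (-d_of[gr[0]], gr[0], gr[1] == "in"))
    chosen = candidates[:l]
    return LocalNetwork(
        center=module.center,
        out_selected=sorted(g for g, role in chosen if role == "out"),
        in_selected=sorted(g for g, role in chosen if role == "in"),
        l=l,
    )
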