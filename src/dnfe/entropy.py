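"""Directed network flow entropy (DNFE) scores.

For a local network centered on g_k with a_k selected out-neighbors and b_k
selected in-neighbors, each side contributes a flow entropy

    NFE = -(1/n)(1/a_k) sum_j sum_r  x_rj P_r log(x_rj P_r)

where j runs over the n reference samples, x_rj is neighbor r's expression
normalized to sum to 1 across those samples, and P_r is the perturbation
distribution over neighbors: P_r = dW_r / sum dW_r with

    W_r  = (1 + PCC(g_k, g_r)) / 2          (transformed correlation)
    dW_r = |W_r^(n) - W_r^(n+1)|            (reference vs reference + one case sample)

falling back to the uniform 1/a_k when no neighbor correlation moved. The
local score is NFE_out + NFE_in and the global score for one case sample is
the mean of local scores over all m center genes. Both the expression
normalization and the correlation transform keep every summand of the form
-u log u with u in [0, 1], so scores are non-negative and invariant to a
global positive rescaling of the expression matrix.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .data_io import ExpressionMatrix
from .local_modules import LocalNetwork, _pearson

__all__ = [
    "LOG_EPS",
    "LocalScore",
    "normalize_neighbor_expression",
    "entropy_weights",
    "directional_entropy",
    "local_dnfe",
    "global_dnfe",
]

LOG_EPS = 1e-12


@dataclasses.dataclass(frozen=True)
class LocalScore:
    center: str
    nfe_out: float
    nfe_in: float

    @property
    def dnfe_local(self) -> float:
        return self.nfe_out + self.nfe_in


def normalize_neighbor_expression(x: Sequence[float]) -> np.ndarray:
    """Scale a neighbor's reference profile to a probability-like vector.

    Negative values (possible for simulated concentrations) are first
    shifted so the minimum is 0, then the vector is scaled to sum to 1.
    An all-zero (or constant-negative-shifted) profile falls back to the
    uniform 1/n.
    """
    x = np.asarray(x, dtype=float)
    if x.min() < 0:
        x = x - x.min()
    total = x.sum()
    if total <= 0:
        return np.full(x.size, 1.0 / x.size)
    return x / total


def entropy_weights(delta_w: Sequence[float]) -> np.ndarray:
    """P_r = dW_r / sum dW_r, or the uniform distribution when all dW_r = 0."""
    delta_w = np.asarray(delta_w, dtype=float)
    total = delta_w.sum()
    if total <= 0:
        return np.full(delta_w.size, 1.0 / delta_w.size)
    return delta_w / total


def _nfe(xnorm: np.ndarray, p: np.ndarray) -> float:
    """-(1/n)(1/a) sum_j sum_r u log(u + eps) with u = xnorm[r, j] * p[r]."""
    a, n = xnorm.shape
    u = xnorm * p[:, None]
    return float(-(u * np.log(u + LOG_EPS)).sum() / (n * a))


def directional_entropy(center: str, neighbors: Sequence[str],
                        ref: ExpressionMatrix,
                        case_sample: Mapping[str, float] | Sequence[float]) -> float:
    """Flow entropy of one side (the given neighbors) of a local network.

    ``ref`` holds the n reference samples only; the case sample enters
    solely through the perturbed correlations.
    """
    if len(neighbors) == 0:
        return 0.0
    gene_pos = {g: i for i, g in enumerate(ref.gene_ids)}
    if isinstance(case_sample, Mapping):
        case_of = lambda g: float(case_sample[g])  # noqa: E731
    else:
        case_arr = np.asarray(case_sample, dtype=float)
        case_of = lambda g: float(case_arr[gene_pos[g]])  # noqa: E731
    xc = ref.values[gene_pos[center]]
    cc = case_of(center)
    delta_w = np.empty(len(neighbors))
    xnorm = np.empty((len(neighbors), ref.n_samples))
    for r, g in enumerate(neighbors):
        xr = ref.values[gene_pos[g]]
        w_n = 0.5 * (1.0 + _pearson(xc, xr))
        w_n1 = 0.5 * (1.0 + _pearson(np.append(xc, cc), np.append(xr, case_of(g))))
        delta_w[r] = abs(w_n - w_n1)
        xnorm[r] = normalize_neighbor_expression(xr)
    return _nfe(xnorm, entropy_weights(delta_w))


def local_dnfe(localnet: LocalNetwork, ref: ExpressionMatrix,
               case_sample: Mapping[str, float] | Sequence[float]) -> LocalScore:
    """Local DNFE score of one center gene for one perturbing case sample."""
    nfe_out = directional_entropy(localnet.center, localnet.out_selected, ref, case_sample)
    nfe_in = directional_entropy(localnet.center, localnet.in_selected, ref, case_sample)
    return LocalScore(localnet.center, nfe_out, nfe_in)


def global_dnfe(local_scores: Sequence[LocalScore] | Sequence[float]) -> float:
    """Global DNFE score: mean of the m local scores for one case sample."""
    if len(local_scores) == 0:
        raise ValueError("no scorable center genes (m = 0)")
    values = [
        s.dnfe_local if isinstance(s, LocalScore) else float(s) for s in local_scores
    ]
    return float(np.mean(values))
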