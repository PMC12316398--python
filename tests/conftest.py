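"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive every statistic from first principles
(explicit loops, textbook formulas) so they share no code path with the
package implementation they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from dnfe.data_io import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_expression(rng, n_genes=6, n_samples=10, prefix="g"):
    return ExpressionMatrix(
        [f"{prefix}{i}" for i in range(n_genes)],
        [f"s{j}" for j in range(n_samples)],
        rng.uniform(0.5, 3.0, (n_genes, n_samples)),
    )


# ---------------------------------------------------------------------------
# oracles


def equal_frequency_codes(x, bins):
    """Quantile binning re-derived independently: a value equal to an
    interior quantile edge joins the upper bin."""
    x = np.asarray(x, dtype=float)
    edges = [np.quantile(x, k / bins) for k in range(1, bins)]
    codes = []
    for v in x:
        code = 0
        for e in edges:
            if v >= e:
                code += 1
        codes.append(code)
    return codes


def mi_bruteforce(x, y, bins):
    """Plug-in MI from an exhaustively tabulated joint count table."""
    codes = equal_frequency_codes(x, bins)
    n = len(codes)
    total = 0.0
    for b in sorted(set(codes)):
        for lab in (0, 1):
            nxy = sum(1 for c, l in zip(codes, y) if c == b and l == lab)
            if nxy == 0:
                continue
            nx = sum(1 for c in codes if c == b)
            ny = sum(1 for l in y if l == lab)
            pxy = nxy / n
            total += pxy * math.log(pxy / ((nx / n) * (ny / n)))
    return total


def pearson_bruteforce(a, b):
    a, b = list(map(float, a)), list(map(float, b))
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = sum((x - ma) ** 2 for x in a)
    vb = sum((y - mb) ** 2 for y in b)
    return cov / math.sqrt(va * vb)


def eq4_weight_bruteforce(xi_ref, xj_ref, xi_case, xj_case):
    n = len(xi_ref)
    pcc_n = pearson_bruteforce(xi_ref, xj_ref)
    pcc_n1 = pearson_bruteforce(list(xi_ref) + [xi_case], list(xj_ref) + [xj_case])
    return (n - 1) * abs(pcc_n1 - pcc_n) / max(1 - pcc_n ** 2, 1e-6)


def directional_entropy_bruteforce(center_ref, center_case, neighbor_rows,
                                   neighbor_cases):
    """Explicit double sum over reference samples and neighbors."""
    a_k = len(neighbor_rows)
    n = len(center_ref)
    delta_w = []
    xnorm_rows = []
    for row, case_val in zip(neighbor_rows, neighbor_cases):
        w_n = 0.5 * (1 + pearson_bruteforce(center_ref, row))
        w_n1 = 0.5 * (1 + pearson_bruteforce(
            list(center_ref) + [center_case], list(row) + [case_val]))
        delta_w.append(abs(w_n - w_n1))
        shifted = [v - min(min(row), 0.0) for v in row]
        total = sum(shifted)
        xnorm_rows.append([v / total if total > 0 else 1 / n for v in shifted])
    s = sum(delta_w)
    p = [d / s for d in delta_w] if s > 0 else [1 / a_k] * a_k
    acc = 0.0
    for j in range(n):
        for r in range(a_k):
            u = xnorm_rows[r][j] * p[r]
            acc += u * math.log(u + 1e-12)
    return -acc / (n * a_k)


def planted_dark_gene_benchmark(rng, n_dark=20, n_de=20, n_ref=20, n_case=20):
    """DNB set with planted dark genes (no expression change, DNFE jump)
    and differentially expressed genes (10-sigma shift, DNFE jump).

    Dark genes' case expression is a permutation of the reference values,
    so the two groups have identical empirical distributions — the
    generator's definition of 'not differentially expressed'.
    """
    from dnfe.detection import DNBSet

    genes = [f"dark{i:02d}" for i in range(n_dark)] + \
            [f"de{i:02d}" for i in range(n_de)]
    ref_vals, case_vals = [], []
    for i, g in enumerate(genes):
        base = rng.normal(5.0, 1.0, n_ref)
        ref_vals.append(base)
        if g.startswith("dark"):
            case_vals.append(rng.permutation(base)[:n_case])
        else:
            case_vals.append(rng.normal(15.0, 1.0, n_case))
    ref = ExpressionMatrix(genes, [f"r{j}" for j in range(n_ref)], np.array(ref_vals))
    case = ExpressionMatrix(genes, [f"c{j}" for j in range(n_case)], np.array(case_vals))
    dnfe_prev = pd.DataFrame(rng.normal(1.0, 0.1, (len(genes), n_case)), index=genes)
    dnfe_at = pd.DataFrame(rng.normal(3.0, 0.1, (len(genes), n_case)), index=genes)
    dnbs = DNBSet("T", list(genes), 0.05)
    expected_dark = sorted(g for g in genes if g.startswith("dark"))
    return dnbs, case, ref, dnfe_at, dnfe_prev, expected_dark
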