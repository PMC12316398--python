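"""End-to-end orchestration: networks → local modules → entropy → detection.

Per ordered time point T the pipeline builds the co-expression backbone
from the reference and case samples, orients it with the direction index,
selects each gene's top-l local network, and scores every case sample's
perturbation of the reference correlations. The per-time-point scores then
feed tipping-point detection, DNB extraction and dark-gene calling.

Scoring is vectorized over genes: the reference correlation matrix is
computed once and each case sample contributes one perturbed correlation
matrix, from which all local entropies are assembled. Results are
identical to composing the public per-operation API gene by gene (the test
suite asserts this), and gene evaluation order never changes any number.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import networkx as nx

from . import __version__
from .data_io import (
    ExpressionMatrix,
    SampleDesign,
    ordered_time_points,
    phenotype_vector,
    validate_design,
    write_network,
    write_scores,
)
from .directed_network import build_backbone, orient_edges, default_bins
from .entropy import entropy_weights, normalize_neighbor_expression
from .detection import (
    ScoreSeries,
    TippingCall,
    DNBSet,
    DarkGeneSet,
    detect_tipping,
    extract_dnbs,
    find_dark_genes,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_report", "score_time_point"]


@dataclasses.dataclass
class RunConfig:
    """All tunable parameters of a pipeline run.

    Defaults follow the method's stated settings where it states them
    (lambda = 1/5, DNB quantile 5%, alpha 0.05) and this package's own
    choices elsewhere (unsigned-WGCNA soft power 6, adjacency cutoff 0.3,
    top-l 10, equal-frequency bins ~ sqrt(n)).
    """

    bins: int | None = None          #: MI bins; None = max(2, ceil(sqrt(n)))
    power: float = 6.0               #: soft-threshold exponent for |PCC| (WGCNA unsigned default)
    cutoff: float = 0.3              #: backbone adjacency threshold in [0, 1]
    lam: float = 0.2                 #: crossover-strength mixing weight (1/5)
    top_l: int = 10                  #: local-network size cap
    dnb_quantile: float = 0.05       #: DNB fraction at a tipping point
    alpha: float = 0.05              #: significance level for all tests
    log_transform: bool = False      #: apply log1p before any computation
    backbone_samples: str = "pooled"   #: "pooled" (reference+case) or "reference"
    reference_mode: str = "fixed"      #: "fixed" reference set or "previous" time point
    prior: str = "previous"            #: prior for condition (ii): "previous" or "pooled"
    time_point_order: list[str] | None = None
    seed: int | None = None            #: recorded in the manifest (scoring is deterministic)

    def validate(self) -> None:
        if self.bins is not None and self.bins < 2:
            raise ValueError("bins must be >= 2")
        if not 0 <= self.cutoff <= 1:
            raise ValueError("cutoff must lie in [0, 1]")
        if not 0 < self.lam < 1:
            raise ValueError("lambda must lie in (0, 1)")
        if self.top_l < 1:
            raise ValueError("top_l must be positive")
        if not 0 < self.dnb_quantile <= 1:
            raise ValueError("dnb_quantile must lie in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.backbone_samples not in ("pooled", "reference"):
            raise ValueError("backbone_samples must be 'pooled' or 'reference'")
        if self.reference_mode not in ("fixed", "previous"):
            raise ValueError("reference_mode must be 'fixed' or 'previous'")


@dataclasses.dataclass
class PipelineResult:
    series: ScoreSeries
    tipping_calls: list[TippingCall]
    dnb_sets: list[DNBSet]
    dark_gene_sets: list[DarkGeneSet]
    networks: dict[str, nx.DiGraph]
    excluded_genes: dict[str, list[str]]
    manifest: dict


def _stage(name: str, time_point: str | None = None):
    ctx = f"stage {name}" + (f" at time point {time_point}" if time_point else "")
    return ctx


def score_time_point(expr: ExpressionMatrix, ref_ids: Sequence[str],
                     case_ids: Sequence[str], config: RunConfig
                     ) -> tuple[pd.DataFrame, nx.DiGraph, list[str]]:
    """Score one reference-vs-case contrast.

    Returns the genes x case-samples table of local DNFE scores, the
    directed network, and the genes excluded for zero variance. Every gene
    retained in the network is a center; isolated centers score 0.
    """
    ref = expr.subset_samples(list(ref_ids))
    case = expr.subset_samples(list(case_ids))
    pooled_ids = list(ref_ids) + list(case_ids)
    pooled = expr.subset_samples(pooled_ids)

    constant = sorted(set(expr.zero_variance_genes(pooled_ids))
                      | set(expr.zero_variance_genes(list(ref_ids))))
    keep = [g for g in expr.gene_ids if g not in set(constant)]
    if len(keep) < 2:
        raise RuntimeError("fewer than 2 genes with variance; nothing to score")
    ref, case, pooled = (m.subset_genes(keep) for m in (ref, case, pooled))

    backbone_input = pooled if config.backbone_samples == "pooled" else ref
    backbone = build_backbone(backbone_input, config.power, config.cutoff)
    y = np.array([0] * len(ref_ids) + [1] * len(case_ids))
    bins = config.bins or default_bins(pooled.n_samples)
    net = orient_edges(backbone, pooled, y, bins)

    n_ref = ref.n_samples
    gene_pos = {g: i for i, g in enumerate(keep)}
    pcc_ref = np.corrcoef(ref.values)
    xnorm = np.array([normalize_neighbor_expression(row) for row in ref.values])
    # per-gene Shannon entropy of the normalized reference profile
    with np.errstate(divide="ignore", invalid="ignore"):
        h_gene = -np.nansum(np.where(xnorm > 0, xnorm * np.log(xnorm), 0.0), axis=1)

    # Local-network selection. The direction-matched weight normalization
    # makes every neighbor's directional crossover sum 1 whenever the
    # neighbor has second-order edges with positive weight (generic for
    # continuous data), so the ranking reduces to second-order degree
    # indicators and is invariant to which case sample feeds the weights;
    # crossover_strength computes the same quantity from explicit weights.
    out_adj: dict[str, list[str]] = {g: [] for g in net.nodes}
    in_adj: dict[str, list[str]] = {g: [] for g in net.nodes}
    for u, v in net.edges:
        out_adj[u].append(v)
        in_adj[v].append(u)
    out_set = {g: set(nb) for g, nb in out_adj.items()}
    in_set = {g: set(nb) for g, nb in in_adj.items()}
    side_index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for center in net.nodes:
        candidates = [(g, "out") for g in out_adj[center]] + \
                     [(g, "in") for g in in_adj[center]]
        d_of = {}
        for g, _role in candidates:
            if g not in d_of:
                # second-order neighbor lists exclude the center itself
                q_j = len(in_adj[g]) - (g in out_set[center])
                p_j = len(out_adj[g]) - (g in in_set[center])
                d_of[g] = config.lam * (q_j > 0) + (1 - config.lam) * (p_j > 0)
        candidates.sort(key=lambda gr: (-d_of[gr[0]], gr[0], gr[1] == "in"))
        chosen = candidates[: config.top_l]
        out_idx = np.array(sorted(gene_pos[g] for g, r in chosen if r == "out"), dtype=int)
        in_idx = np.array(sorted(gene_pos[g] for g, r in chosen if r == "in"), dtype=int)
        side_index[center] = (out_idx, in_idx)

    # Per case sample: one perturbed correlation matrix drives every local
    # entropy. The double sum over neighbors and reference samples
    # factorizes as (sum_r P_r H_r + H(P)) / (n a_k) because each
    # normalized profile sums to 1; this matches directional_entropy.
    score_mat = np.zeros((len(keep), len(case_ids)))
    centers = [(gene_pos[c], side_index[c]) for c in net.nodes]
    for s_idx in range(len(case_ids)):
        stacked = np.hstack([ref.values, case.values[:, s_idx:s_idx + 1]])
        delta_w = 0.5 * np.abs(np.corrcoef(stacked) - pcc_ref)
        for k, (out_idx, in_idx) in centers:
            total = 0.0
            row = delta_w[k]
            for idx in (out_idx, in_idx):
                a_k = idx.size
                if a_k == 0:
                    continue
                p = entropy_weights(row[idx])
                nz = p > 0
                ent_p = float(-(p[nz] * np.log(p[nz])).sum())
                total += (float(p @ h_gene[idx]) + ent_p) / (n_ref * a_k)
            score_mat[k, s_idx] = total
    table = pd.DataFrame(score_mat, index=keep, columns=list(case_ids))
    return table, net, constant


def _delta_w_eq4(pcc_ref: np.ndarray, ref_values: np.ndarray,
                 case_col: np.ndarray, n_ref: int) -> np.ndarray:
    """Matrix of single-sample perturbation weights (crossover weighting)."""
    stacked = np.hstack([ref_values, case_col[:, None]])
    pcc_pert = np.corrcoef(stacked)
    denom = np.maximum(1.0 - pcc_ref ** 2, 1e-6)
    return (n_ref - 1) * np.abs(pcc_pert - pcc_ref) / denom


def run_pipeline(expr: ExpressionMatrix, design: Sequence[SampleDesign],
                 config: RunConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full method over an expression matrix and sample design."""
    config = config or RunConfig()
    config.validate()
    validate_design(design, expr)
    if config.log_transform:
        if expr.values.min() < 0:
            raise RuntimeError(f"{_stage('log-transform')}: negative values present")
        expr = ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids),
                                np.log1p(expr.values))

    time_points = ordered_time_points(design, config.time_point_order)
    ref_ids_all = [d.sample_id for d in design if d.role == "reference"]
    case_by_tp = {
        t: [d.sample_id for d in design if d.role == "case" and d.time_point == t]
        for t in time_points
    }
    scored_tps = [t for t in time_points if case_by_tp[t]]
    if len(scored_tps) < 1:
        raise RuntimeError("no time point has case samples")

    sample_scores: dict[str, np.ndarray] = {}
    sample_gene_scores: dict[str, pd.DataFrame] = {}
    networks: dict[str, nx.DiGraph] = {}
    excluded: dict[str, list[str]] = {}
    prev_cases: list[str] | None = None
    for t in scored_tps:
        if config.reference_mode == "previous" and prev_cases:
            ref_ids = prev_cases
        else:
            ref_ids = ref_ids_all
        try:
            table, net, constant = score_time_point(expr, ref_ids, case_by_tp[t], config)
        except Exception as exc:
            raise RuntimeError(f"{_stage('scoring', t)}: {exc}") from exc
        sample_gene_scores[t] = table
        sample_scores[t] = table.mean(axis=0).to_numpy()  # global = mean over m centers
        networks[t] = net
        excluded[t] = constant
        prev_cases = case_by_tp[t]

    series = ScoreSeries(scored_tps, sample_scores, sample_gene_scores,
                         n_reference=len(ref_ids_all))
    if len(scored_tps) >= 2:
        calls = detect_tipping(series, config.alpha, config.prior)
    else:
        calls = []
    dnb_sets: list[DNBSet] = []
    dark_sets: list[DarkGeneSet] = []
    for call in calls:
        if not call.is_tipping:
            continue
        t = call.time_point
        dnbs = extract_dnbs(sample_gene_scores[t].mean(axis=1), config.dnb_quantile, t)
        dnb_sets.append(dnbs)
        prev = scored_tps[scored_tps.index(t) - 1]
        shared = [g for g in dnbs.genes if g in sample_gene_scores[prev].index]
        if shared:
            dark_sets.append(find_dark_genes(
                DNBSet(t, shared, dnbs.quantile),
                expr.subset_samples(case_by_tp[t]).subset_genes(shared),
                expr.subset_samples(ref_ids_all).subset_genes(shared),
                sample_gene_scores[t].loc[shared],
                sample_gene_scores[prev].loc[shared],
                config.alpha,
            ))

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "input_sha256": _hash_inputs(expr, design),
        "time_points": scored_tps,
        "n_reference": len(ref_ids_all),
        "artifacts": {},
    }
    result = PipelineResult(series, calls, dnb_sets, dark_sets, networks,
                            excluded, manifest)
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _hash_inputs(expr: ExpressionMatrix, design: Sequence[SampleDesign]) -> str:
    digest = hashlib.sha256()
    digest.update(np.ascontiguousarray(expr.values).tobytes())
    digest.update("\n".join(expr.gene_ids).encode())
    digest.update("\n".join(expr.sample_ids).encode())
    for d in design:
        digest.update(f"{d.sample_id}\t{d.time_point}\t{d.role}\n".encode())
    return digest.hexdigest()


REQUIRED_ARTIFACTS = ["scores.tsv", "gene_scores.tsv", "tipping_calls.tsv",
                      "dnbs.tsv", "dark_genes.tsv", "manifest.json"]


def _write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    series = result.series
    rows = [
        {"time_point": t, "sample_id": s, "global_dnfe": v}
        for t in series.time_points
        for s, v in zip(series.sample_gene_scores[t].columns, series.sample_scores[t])
    ]
    write_scores(pd.DataFrame(rows, columns=["time_point", "sample_id", "global_dnfe"]),
                 out_dir / "scores.tsv")
    landscape = [
        {"time_point": t, "gene": g, "mean_local_dnfe": v}
        for t in series.time_points
        for g, v in series.sample_gene_scores[t].mean(axis=1).items()
    ]
    write_scores(pd.DataFrame(landscape, columns=["time_point", "gene", "mean_local_dnfe"]),
                 out_dir / "gene_scores.tsv")
    write_scores(pd.DataFrame([dataclasses.asdict(c) for c in result.tipping_calls],
                              columns=["time_point", "passes_increase", "t_stat",
                                       "p_value", "is_tipping", "indeterminate"]),
                 out_dir / "tipping_calls.tsv")
    write_scores(pd.DataFrame(
        [{"time_point": d.time_point, "gene": g, "rank": i + 1}
         for d in result.dnb_sets for i, g in enumerate(d.genes)],
        columns=["time_point", "gene", "rank"]), out_dir / "dnbs.tsv")
    write_scores(pd.DataFrame(
        [{"time_point": d.time_point, "gene": g,
          "p_expression": d.expression_p[g], "p_dnfe": d.dnfe_p[g]}
         for d in result.dark_gene_sets for g in d.genes],
        columns=["time_point", "gene", "p_expression", "p_dnfe"]),
        out_dir / "dark_genes.tsv")
    net_dir = out_dir / "networks"
    for t, net in result.networks.items():
        write_network(net, net_dir / f"network_{t}.tsv")
    for name in REQUIRED_ARTIFACTS:
        if name == "manifest.json":
            continue
        result.manifest["artifacts"][name] = _sha256_file(out_dir / name)
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=1))


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_report(out_dir: str | Path, plot: bool = False) -> str:
    """Summarize a completed run; verifies artifact integrity via the manifest."""
    out_dir = Path(out_dir)
    missing = [n for n in REQUIRED_ARTIFACTS if not (out_dir / n).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run in {out_dir}: missing {missing}")
    manifest = json.loads((out_dir / "manifest.json").read_text())
    mismatched = [
        name for name, digest in manifest.get("artifacts", {}).items()
        if _sha256_file(out_dir / name) != digest
    ]
    scores = pd.read_csv(out_dir / "scores.tsv", sep="\t")
    calls = pd.read_csv(out_dir / "tipping_calls.tsv", sep="\t")
    dnbs = pd.read_csv(out_dir / "dnbs.tsv", sep="\t")
    dark = pd.read_csv(out_dir / "dark_genes.tsv", sep="\t")
    lines = [f"DNFE run summary ({out_dir})", ""]
    grouped = scores.groupby("time_point", sort=False)["global_dnfe"]
    for t, group in grouped:
        lines.append(f"  {t}: DNFE = {group.mean():.4f} +/- SD {group.std(ddof=1):.4f} "
                     f"(n_case = {len(group)})")
    tipping = calls[calls.get("is_tipping", pd.Series(dtype=bool)) == True]  # noqa: E712
    if len(tipping):
        for _, row in tipping.iterrows():
            lines.append(f"  tipping point at {row.time_point} "
                         f"(S = {row.t_stat:.3f}, P = {row.p_value:.3g})")
    else:
        lines.append("  no critical state detected")
    lines.append(f"  DNB genes: {len(dnbs)}; dark genes: {len(dark)}")
    if mismatched:
        lines.append(f"  WARNING: artifact hash mismatch (modified after the run): "
                     f"{mismatched}")
    if plot:
        _plot_scores(scores, out_dir / "score_curve.png")
        lines.append(f"  score curve written to {out_dir / 'score_curve.png'}")
    return "\n".join(lines)


def _plot_scores(scores: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grouped = scores.groupby("time_point", sort=False)["global_dnfe"]
    means, sds = grouped.mean(), grouped.std(ddof=1)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.errorbar(range(len(means)), means.to_numpy(), yerr=sds.to_numpy(),
                marker="o", capsize=3)
    ax.set_xticks(range(len(means)), means.index, rotation=45, ha="right")
    ax.set_ylabel("global DNFE")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
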