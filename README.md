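# dnfe — directed network flow entropy for tipping-point detection

Many biological processes — cell differentiation, tumor progression,
disease onset — evolve gradually and then shift abruptly between stable
states. Immediately before such a shift the system passes through a
*critical state* (tipping point) in which a group of genes, the **dynamic
network biomarkers (DNBs)**, fluctuates collectively while mean expression
still looks unremarkable. `dnfe` implements the **directed network flow
entropy** method for detecting these critical states from time-course or
stage-course omics data (bulk or single-cell), and for extracting DNBs and
the non-differential **"dark genes"** that change at the network level
without changing expression.

## Method

At each time point *T*, with *n* reference samples and a set of case
samples:

1. **Directed network.** A co-expression backbone is built from the pooled
   samples (soft-power adjacency `a_ij = |PCC(g_i, g_j)|^β`, kept when
   `a_ij ≥ cutoff`). Each backbone pair is oriented with the direction
   determination index

   `ω_ij = I((U+V)/2 ; Y) − I(U ; Y)`,

   the mutual-information gain of the averaged pair profile over gene
   *g_i*'s own profile with respect to the binary reference/case phenotype
   *Y*; a directed edge *g_i → g_j* exists iff `ω_ij > 0`.
2. **Local networks.** For each center gene *g_k*, first-order neighbors
   are ranked by crossover strength `D_j = λ D_j^in + (1−λ) D_j^out`
   (λ = 1/5) over their second-order edges, whose weights are the
   single-sample perturbation statistic
   `W_ij = (n−1)|PCC_{n+1} − PCC_n| / (1 − PCC_n²)`; the top-*l* neighbors
   form the local network *N_k*.
3. **Flow entropy.** Each side of *N_k* contributes
   `NFE = −(1/n)(1/a_k) Σ_j Σ_r x̃_rj P_r log(x̃_rj P_r)`, where `x̃_r` is
   neighbor *r*'s reference profile normalized to sum 1 and
   `P_r ∝ |W_r^(n) − W_r^(n+1)|` with `W = (1+PCC)/2` — the distribution of
   correlation perturbation caused by one case sample. The local score is
   `DNFE_T^k = NFE_out + NFE_in`; the global score is the mean over all
   *m* centers.
4. **Detection.** *T* is a tipping point when (i) the mean score increases
   over *T−1* and (ii) the one-sample t-test
   `S = √n̄ (mean(X) − x) / SD(X)` of the per-case-sample scores against
   the previous mean reaches P < 0.05. At a called tipping point the top
   5% of genes by local score are the DNBs; DNB members with no
   expression change (Welch P ≥ 0.05) but a significant DNFE change
   (P < 0.05) are the dark genes.

A stochastic Hill-kinetics GRN simulator with a controlled bifurcation
(`dnfe.grn_simulator`) generates validation data: the deterministic drift
loses stability exactly at the control value p = 0, so the score's abrupt
increase can be checked against a known tipping point.

## Worked example

Sweep the packaged 11-gene regulatory network across its control
parameter and run the full pipeline (about a minute on one CPU):

```python
from dnfe import make_eleven_node_model, sweep, run_pipeline, run_report, RunConfig

model = make_eleven_node_model()                       # bifurcates at p = 0
grid = [round(-0.5 + 0.05 * k, 2) for k in range(15)]  # -0.50 ... 0.20
data = sweep(model, grid, sigma=0.01, n_ref=20, n_case=20, seed=7)
run_pipeline(data.expression, data.design, RunConfig(), out_dir="demo_out")
print(run_report("demo_out"))
```

```
DNFE run summary (demo_out)

  -0.5: DNFE = 0.0000 +/- SD 0.0000 (n_case = 20)
  ...
  -0.1: DNFE = 0.0000 +/- SD 0.0000 (n_case = 20)
  -0.05: DNFE = 0.0626 +/- SD 0.0004 (n_case = 20)
  0.0: DNFE = 0.0742 +/- SD 0.0001 (n_case = 20)
  0.05: DNFE = 0.0785 +/- SD 0.0007 (n_case = 20)
  0.1: DNFE = 0.0813 +/- SD 0.0003 (n_case = 20)
  0.15: DNFE = 0.0000 +/- SD 0.0000 (n_case = 20)
  0.2: DNFE = 0.0000 +/- SD 0.0000 (n_case = 20)
  tipping point at -0.05 (S = 779.486, P = 2.89e-44)
  tipping point at 0.0 (S = 347.809, P = 1.32e-37)
  tipping point at 0.05 (S = 28.225, P = 5.63e-17)
  tipping point at 0.1 (S = 37.970, P = 2.21e-19)
  DNB genes: 4; dark genes: 4
```

The score is flat while the system is far from the transition, surges at
the grid point adjacent to the constructed bifurcation (p = 0) — the first
tipping call — and collapses once the system has settled in the
post-transition attractor (case samples then separate perfectly from the
reference, and the direction index orients no edges). The same workflow
runs from the shell:

```bash
dnfe simulate --model 11node --sigma 0.01 --seed 7 --grid-step 0.05 --out sim/
dnfe run --expression sim/expression.tsv --design sim/design.tsv --out out/
dnfe report out/
```

For real data, provide a genes × samples TSV/CSV (or MatrixMarket `.mtx`
with `genes.txt`/`samples.txt` sidecars) and a design table with columns
`sample_id`, `time_point`, `role` (`reference`/`case`).

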