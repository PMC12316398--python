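# Methods

This note documents how `dnfe` implements the directed-network
flow-entropy method: the statistical model, the defaults and why they were
chosen, what the bundled simulator does and does not emulate, and the
numerical conventions.

## The score and its ingredients

**Phenotype and samples.** Every computation at a time point *T* contrasts
*n* reference samples (a designated control set, by default the
reference-role samples of the design; configurable to the previous time
point's case samples) with the case samples observed at *T*. The phenotype
vector *Y* is 0 for reference and 1 for case.

**Mutual information.** The direction index needs the mutual information
between a continuous expression profile and the binary phenotype. We use
the plug-in histogram estimator on equal-frequency bins,
`B = max(2, ⌈√n_samples⌉)` by default (`bins` in `RunConfig`), natural
logarithm. Equal-frequency binning is parameter-light, robust at the small
sample sizes typical for this method, and makes the estimator invariant
under strictly monotone transformations of the profile. Values equal to a
bin edge join the upper bin, so ties never straddle bins. A constant
profile has zero mutual information by construction. The averaged pair
profile (U+V)/2 is formed on the data scale (raw, or log1p when
`log_transform` is set) before discretization.

**Backbone.** The undirected skeleton is the soft-threshold co-expression
adjacency `a_ij = |PCC|^β` with a hard cutoff (default 0.3), computed on
the pooled reference + case samples (configurable to reference-only). The
default soft power is β = 6, the canonical unsigned-WGCNA choice. This
default matters: at, say, 20 pooled samples, β = 2 with cutoff 0.3 admits
every pair with |PCC| ≥ 0.55, which a null pair attains with probability
≈ 1%. In a 1000-gene data set that is thousands of spurious edges — enough
to make nearly every gene "scorable" at baseline, saturating the global
score before anything biological happens and masking the surge at a
critical transition. β = 6 (|PCC| ≥ 0.82 at the same cutoff) keeps the
null backbone essentially empty while the strong correlations that emerge
near a critical transition still pass. Full WGCNA machinery (TOM, module
detection) is intentionally not reproduced; the backbone is pluggable.

**Direction index.** For each backbone pair, `ω_ij = I((U+V)/2; Y) −
I(U; Y)` and `ω_ji` are evaluated independently; each directed edge with
ω > 0 is kept, so bidirectional pairs are allowed and an exact tie (ω = 0,
which happens systematically when both profiles separate the phenotype
perfectly — the histogram estimator then returns identical count tables)
yields no edge. One consequence worth knowing: once a transition is
complete and every case sample is far from the reference attractor, most
genes separate the phenotype perfectly, the index ties at zero everywhere,
and the directed network — hence the score — collapses. The score is
therefore a *pre-transition* early-warning signal, high near the critical
state and low on both sides of it.

**Local-network selection.** First-order neighbors of each center are
ranked by crossover strength `D_j = λ D_j^in + (1−λ) D_j^out` with
λ = 1/5, where each directional term sums the neighbor's second-order
edge weights after normalizing them to total 1 within that direction
(direction-matched reading of the weight normalization). Because the
normalized weights telescope, each directional term is exactly 1 whenever
the neighbor has any second-order edge with positive weight and 0
otherwise, so D takes values in {0, λ, 1−λ, 1} and the ranking reduces to
second-order degree indicators, independent of the perturbing sample.
Ties are broken by gene ID (then out before in) so selection is
deterministic and order-invariant. The pipeline exploits the invariance
and selects once per time point; `crossover_strength` itself computes the
sums from explicit weights so an alternative normalization would flow
through unchanged. The local network keeps the top `l` (default 10)
neighbor slots; a gene adjacent in both directions occupies one slot per
role.

**Entropy.** Each neighbor's reference profile is normalized to sum to 1
across the n reference samples (shifting by the minimum first if negative
values are present; uniform fallback for an all-zero profile), and the
perturbation distribution P is the normalized |ΔW| over the side's
neighbors, with W = (1+PCC)/2 computed on the reference samples and on
reference + the one case sample. When no correlation moved at all, P
falls back to uniform. The flow entropy
`−(1/n)(1/a_k) Σ_j Σ_r x̃_rj P_r log(x̃_rj P_r + ε)` with ε = 1e−12 is
then a sum of valid −u log u terms, so every local score is non-negative
and invariant to a global positive rescaling of the expression matrix.
The index j runs over the reference samples only; the case sample enters
solely through the perturbed correlations. Because both x̃ and P sum to
one, the double sum factorizes as `(Σ_r P_r H_r + H(P)) / (n a_k)`
(profile entropy plus perturbation entropy); the pipeline evaluates this
factorized form, which agrees with the direct double sum to ~1e−10
relative.

**Global score and aggregation.** Every gene retained in the network is a
center (isolated centers score 0); the global score for one case sample
is the mean of the m local scores. Per time point we report the mean and
SD over case samples — each case sample perturbs the reference set
independently.

**Detection.** A time point is a tipping point when the mean score
increased over the previous time point and a one-sample t-test of the
per-case-sample scores against the previous mean (or, optionally, the
pooled mean of all earlier time points) reaches P < alpha (default 0.05,
two-sided; no multiple-testing correction across time points). Note the
test treats the previous mean as a fixed constant although it is itself a
sample mean; under an i.i.d. null this inflates the statistic by about
√2, giving a per-time-point false-call rate of roughly 7% at alpha = 5%
(small-sample t critical values pull it back toward nominal; at 10 case
samples the rate is ≈ 0.07). Time points with a single case sample have
no within-point SD and are marked indeterminate. DNBs are the top
⌈5%·m⌉ genes by mean local score at a called tipping point; dark genes
are DNB members with Welch expression P ≥ alpha (a gene constant in both
groups counts as non-differential, P := 1) and Welch local-DNFE P < alpha
versus the previous time point.

## The simulator

`grn_simulator` generates expression data from Hill-kinetics SDEs

dx_i = [ Σ_j A_ij h_act(x_j) + Σ_j R_ij h_rep(x_j) − (d0 − p) x_i + b_i(p) ] dt + σ dB_i

with h = 2, K = 3, unit (or gain-scaled) edge weights, integrated by
Euler–Maruyama. The basal term b(p) pins a fixed operating point x* for
every control value p, so the Jacobian at x* is J_P(x*) − (d0 − p)I; with
d0 set to the largest real part of J_P's spectrum the leading eigenvalue
is exactly p and the branch destabilizes at the constructed critical
value p = 0 — a fold-type loss of stability under the Hill nonlinearity.
Each sample is the end state of an independent replicate trajectory
(default dt = 0.02, 7500 steps, i.e. 150 time units), so samples are
independent draws; the horizon is long enough that one grid step past the
bifurcation (p ≈ +0.03…0.05) the escape from the operating point is
complete, keeping the transition sharp on the sweep grid.

`make_random_model` builds an Erdős–Rényi signed background (expected
in-degree 4, 60% activations) plus planted positively coupled regulator
modules: rings of 10 genes, each activating the next 5, covering ≈ 30% of
the genes, receiving no outside regulation, with internal gains
normalized so every module's Perron eigenvalue equals the shared
degradation baseline. The modules therefore carry the critical mode
collectively — the canonical dynamic-network-biomarker scenario: far from
the transition all genes fluctuate independently around x*; approaching
p = 0 the module genes' variance and mutual correlations surge; past it
they escape to a distant attractor. A gapless pure-ER Jacobian, by
contrast, spreads its leading mode diffusely, producing a slow correlation
ramp with no abrupt surge — not the phenomenon a tipping-point detector
is validated against. The operating point is drawn from U(1.5, 4.5) with
K = 3 so that the noise sweep σ ∈ {0.01, 0.02, 0.04} stays well inside
the attractor basin (at smaller concentration scales, 4× noise causes
premature noise-induced escape). `make_eleven_node_model` packages a
fixed 11-gene instance of the same design (4-gene positive ring plus 7
mixed-sign background genes, critical value p = 0) in
`models/eleven_node.json`.

**Sweep design.** Reference samples are drawn at the grid minimum — the
most stable, pre-transition condition — and case samples at each grid
value; each grid value then plays the role of a "time point" for the
pipeline, matching the method's reference-vs-case design.

**What the simulator does not emulate.** Real single-cell data have
dropout, count noise, library-size variation and non-stationary cell-type
mixtures; bulk data have batch effects. Passing the simulation benchmarks
shows that the pipeline recovers a genuine bifurcation from clean
SDE samples at realistic sample sizes; it does not by itself establish
robustness to those technical artifacts.

**Problem sizes used in the shipped experiments.** 100 genes with a
15-point grid on [−0.5, 0.2] and 20+20 samples (10 seeds), and 1000 genes
with a 7-point grid on [−0.3, 0.1] and 10+10 samples — the second
deliberately exercises the large-network, small-sample regime.

## Synthetic statistical benchmarks

The null calibration of the tipping test uses i.i.d. standard-normal
score series with 10 case samples per time point (the large-network
experiment's sample size). The planted dark-gene benchmark defines "not
differentially expressed" constructively: a dark gene's case values are a
permutation of its reference values, so the two groups have identical
empirical distributions and the Welch statistic is exactly 0. With
independent null draws instead, a 5%-level test would flag some planted
dark gene in most repetitions and exact recovery would be impossible by
construction; the permutation design tests the selection logic, not the
t-test's type-I error (which the null calibration covers).

## Numerical conventions and edge cases

- Genes with zero variance across the reference (or pooled) samples have
  undefined correlations; they are excluded from network construction for
  that time point and reported, never silently dropped or imputed. Any NA
  in the input aborts.
- The perturbation-weight denominator 1 − PCC² is floored at 1e−6
  (collinear toy data would otherwise produce infinities).
- ε = 1e−12 inside the entropy logarithm guards exact zeros of the
  normalized profile.
- Directional normalized-weight sums are evaluated as a single quotient so
  the telescoped value is exactly 1 and cannot perturb tie-breaking.
- All tie-breaks (neighbor selection, DNB ranking) are lexicographic by
  gene ID, making every output invariant to gene and sample input order.
- Dense TSV/CSV output uses `%.17g` and reading uses round-trip float
  parsing, so write-then-read is bit-exact.
- Simulated trajectories exceeding |x| = 1e6 raise an error naming the
  node and control value rather than returning garbage.

## Known limitations

- The 1/a_k prefactor in the flow entropy means denser local networks get
  *smaller* per-gene scores; the global signal near a transition comes
  mainly from genes becoming scorable and from the perturbation-entropy
  term, and the score collapses after a completed transition (see the
  direction-index tie discussion above). The method flags the approach to
  a transition, not its aftermath.
- The tipping t-test is anti-conservative by about √2 under the null (see
  Detection); p-values are reported raw.
- The crossover-strength ranking is effectively topological under the
  direction-matched normalization; with sparse directed networks the
  top-l truncation rarely binds.
- Detection requires at least 2 case samples per time point and 3 (in
  practice ≥ 10 for stable results) reference samples.
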