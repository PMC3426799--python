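# Methods

## Model and problem

A discrete Bayesian network is a DAG G over variables X_1..X_n plus one
conditional probability table (CPT) per variable; the joint distribution
is ∏_i P(X_i | U_i) with U_i the parents of X_i. Structure learning is
posed as score maximization over DAGs given an N×n table of complete
categorical data. All methods here assume complete data (missing values
are rejected at load time) and uniform structure priors.

Parent configurations are indexed by the mixed-radix encoding of parent
states in ascending parent-index order, last parent varying fastest; the
CPTs, the BIF writer, and the scoring sufficient statistics all share
this one convention. State indices are 0-based; external labels map to
indices by declaration order.

## Scoring

Every metric is decomposable — a sum over families of a function of the
weighted counts N_ijk — and every metric accepts fractional case
weights, so the same code path scores the original data (unit weights),
ordinary bootstrap resamples (multinomial integer weights), and Bayesian
bootstrap resamples (continuous Dirichlet weights). Both bootstrap
schemes normalize total weight mass to N so that the penalty terms of
BIC/MDL and the prior-versus-data balance of the Dirichlet metrics are
comparable across bootstrap types.

Dirichlet-family metrics (K2, DPSM(λ), BDe) use the log-gamma form of
the family marginal likelihood; with unit weights and integer counts
this agrees with the factorial form to 1e-9 relative (tested). DPSM with
λ=1 *is* K2, bitwise. BDe uses the likelihood-equivalent prior counts
α_ijk = N′/(r_i q_i); N′ defaults to 1. λ defaults to 0.1, a
deliberately promiscuous choice intended for use inside bagging.

BIC is the maximized log-likelihood minus (d/2)·ln N with
d = Σ_i (r_i−1) q_i. The MDL score is the negated description length

    DL(G) = Σ_i |U_i|·log₂ n        (parent lists)
    DL(Θ) = ½·log₂ N · d            (parameters)
    DL(D|G,Θ) = −Σ N_ijk log₂(N_ijk/N_ij)

a standard encoding chosen because it reduces to BIC (up to the
ln↔log₂ constant and the graph term) and penalizes parent-heavy graphs.
Zero counts contribute 0 to likelihood sums (the x→0 limit of x ln x).

## Search

Sparse-candidate greedy hill-climbing with randomized restarts:
candidate parents are the k best single-edge gains per node; moves are
edge addition (parent must be a candidate of the child, child stays
within k parents), deletion, and reversal; only strictly improving moves
are taken, ties preferring the incumbent and then the first move in the
deterministic enumeration order (child index, then add < delete <
reverse, then parent index). After each climb the candidate sets are
re-estimated from the family-score gain of each prospective parent given
the node's current parents; current parents are always retained, which
keeps the incumbent feasible and the score monotone across rounds.
Rounds stop at a candidate-set fixpoint or after c_rounds. Restarts: m1
from random structures with ≤ 2 candidate-respecting edges (sampled, not
materialized — the explicit list is infeasible for large n), then m2
from structures drawn uniformly from everything visited during the first
phase. A run-wide cache keyed by the canonical parent-set tuple ensures
no structure is ever scored twice.

Defaults follow the full-scale protocol: k=6, c_rounds=10, m1=m2=25,
retaining the 10 best distinct structures. The test suite and the
acceptance script run a scaled-down configuration (k=3, c_rounds=2,
m1=4, m2=2) suited to the 3–8-node problems they use; on 3-node
problems the search provably attains the enumeration optimum for every
metric (tested against brute force over all 25 DAGs).

## Resampling and bagging

Ordinary bootstrap weights are Multinomial(N, 1/N) occurrence counts;
about 1/e ≈ 37% of cases get weight zero per resample. Bayesian
bootstrap weights are N·Dirichlet(1,…,1): continuous, almost surely
positive, avoiding the discreteness bias of dropped cases.

Per resample, edge features are either the indicators of the single best
structure, the unweighted mean over the top_m distinct structures
(double simple), or the mean weighted by normalized exp(score−max)
over the retained structures (double Bayesian; normalization is over the
retained set). Frequencies are averaged over B resamples; per-direction
frequencies are kept for reporting but all thresholding and evaluation
use the undirected sum (directions are mutually exclusive within one
DAG, so the sum stays in [0,1]). Each resample runs on a child seed
spawned from the root seed, so results are independent of execution
order and of serial/parallel scheduling.

Modeling per-resample indicators as Bernoulli(p) gives the bagged
frequency variance p(1−p)/B, maximal 0.25/B, whence
required_resamples(p, σ) = ⌈p(1−p)/σ²⌉. The default B=2500 corresponds
to σ=0.01 at p=0.5.

## Permutation threshold selection

The null model permutes each column independently: marginals are exactly
preserved, all dependence is destroyed. The observed curve t_f counts
undirected edges with bagged frequency ≥ f on a grid (step 0.01); p_f is
the mean of the same count over n_perm permuted replicates (default 60;
the replicates may run at a reduced resample budget as a cost knob).

Edge confidence at f is raw L_f = 1 − Δp_f/Δt_f — the fraction of edges
arriving at frequency f not attributable to the null — with slopes
averaged over centered finite differences of widths {0.02, 0.04, 0.06,
0.08, 0.10}. Three numerical details matter:

- **Top-of-grid padding.** Curves are treated as 0 beyond f=1 when
  differencing, because no frequency can exceed 1; a cluster of edges
  saturated at frequency exactly 1.0 (common at moderate B on strong
  edges) then contributes its arrival slope at the top grid point
  instead of being invisible to finite differences.
- **Excess-count guard.** Confidence is forced to 0 wherever
  t_f − p_f ≤ 0: there the null already accounts for every edge above f,
  so no marginal edge can be credited regardless of local slope noise.
  On structured data the excess is large in the region of interest and
  the guard is inactive; on null data it suppresses spurious slope-ratio
  spikes that the small number of permutations would otherwise produce.
- **Monotone envelope.** The clipped raw values are replaced by their
  running maximum in ascending f, the minimal upper envelope under which
  confidence never increases as the threshold decreases.

The selected threshold is the smallest grid value with L_f ≥ the target
(default 0.9); consensus edges are those with positive bagged frequency
at or above it, each annotated with the confidence at its own frequency.
Where no grid point reaches the target, an empty consensus set is
returned with a diagnostic.

## Evaluation

Against a known reference, an unordered pair is a false positive when
its undirected bagged frequency is ≥ t but absent from the reference
skeleton, and a false negative when a reference pair falls below t; the
≥ convention is fixed globally. The experiment driver samples
independent datasets from a ground-truth network, runs the full pipeline
on each, and averages confusion curves pointwise, emitting a seed
manifest so any replicate can be reproduced alone.

## Synthetic generators

Random ground-truth networks draw a uniform topological order, add the
requested number of edges uniformly over admissible slots (respecting a
parent budget), assign arities uniformly in 2–4 (the range typical of
the classic medical-diagnosis benchmarks), and fill CPT rows with
symmetric Dirichlet(0.5) draws — skewed enough that most edges carry
learnable signal while some remain weak, as in real benchmark networks.
Named fixtures ship as BIF files regenerable bit-exactly from their
seeds: a 4-node noisy-copy chain, an 8-node noisy-copy tree, and a
37-node/46-edge look-alike of a classic benchmark's dimensions (its
actual published CPTs are deliberately not bundled; users can supply any
real network as BIF). A 4-node fixture with heterogeneous edge
strengths (copy fidelities 0.95/0.72/0.62) exists specifically for rank
comparisons, where near-tied probabilities would make rank agreement
meaningless.

What the generators do not emulate: real benchmark CPTs'
near-deterministic logic structure, latent confounding, selection bias,
or measurement noise. Passing tests therefore demonstrate correctness of
the machinery and of the method's statistical behavior on faithful
in-model data, not performance on any particular published benchmark.

## Problem sizes used by the tests and the acceptance script

Simulation checks run on seeded networks of 3–8 nodes with datasets of
60–400 cases, B=100–200 resamples and 5–8 permutations, sizes chosen so
the whole suite completes on a single CPU in minutes. Noteworthy
measured behaviors at this scale:

- Bagged (Bayesian-averaged) edge frequencies rank edges in close
  agreement with exact enumeration posteriors on 4-node instances
  (Spearman ≈ 0.98 pooled).
- Across-run scatter of a bagged frequency matches p(1−p)/B well within
  a factor of 2.
- The bagged FP/FN tradeoff weakly dominates the single-best-network
  tradeoff, and the permutation-selected consensus recovers all edges of
  a 6-node network at N=400 with no false positives while returning an
  empty consensus on independence-model data in 18 of 20 runs.
- Among scoring metrics at this scale, DPSM(λ=1) attains the smallest
  minimum structural error, with DPSM(λ=0.1) close behind and MDL
  clearly worst. The advantage of λ<1 reported for 37-node benchmarks
  did not reproduce on 8-node suites: with far fewer families, the
  overfitting that small λ buys is not needed to avoid false negatives,
  so its extra false positives dominate. The best λ (and metric) is
  evidently problem-dependent, which is consistent with different
  benchmarks preferring different metrics at full scale; λ=0.1 remains
  the package default for the limited-data, larger-network regime the
  method targets.

## Known limitations

- Complete data only; no missing-data EM, no continuous variables.
- Inference beyond exhaustive enumeration (≤ 4096 joint states) is out
  of scope; enumeration exists for validation.
- The permutation null is conservative on structured data (it
  overestimates incorrect edges), so selected thresholds err toward
  fewer, higher-confidence edges.
- Edge confidence is a curve-level construction, not a per-edge p-value;
  no familywise-error or FDR guarantee is claimed.
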