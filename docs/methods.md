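# Methods

`gatimc` predicts lncRNA–disease associations in three stages: multi-source
similarity networks, a graph-attention node encoder with multiple-operator
head aggregation, and inductive matrix completion (IMC) trained end-to-end.
This note records the model as implemented, the numerical choices, and the
known limitations.

## 1. Similarity networks

**Disease semantic similarity (DS).** Each disease `d` is expanded into the
DAG of its ontology ancestors. The decayed contribution of node `t` to `d`
is 1 if `t = d`, otherwise `γ · max` over `t`'s children inside the DAG
(default `γ = 0.5`); equivalently `γ^k` for an ancestor whose closest
descent path has `k` edges. The semantic value `S(d)` is the sum of all
contributions, and

```
DS(di, dj) = Σ_{m ∈ shared nodes} (D_di(m) + D_dj(m)) / (S(di) + S(dj)),
```

so `DS(d, d) = 1` exactly. Cycles in the ontology raise an error.

**lncRNA functional similarity (FS).** Best-match average over the two
associated-disease sets `D1` (size `m`) and `D2` (size `n`):
`FS = (Σ_{d∈D1} max_{d'∈D2} DS(d,d') + Σ_{d∈D2} max_{d'∈D1} DS(d,d')) / (m+n)`.
lncRNAs with no known associations get an all-zero row/column (flagged with
a warning); the Gaussian kernel fills those entries during integration.

**Gaussian interaction-profile (GIP) kernels GD / GL.** The interaction
profile of a node is its binary row/column of the association matrix `A`.
The bandwidth is the reciprocal of the mean squared profile norm, and
`K(i,j) = exp(−bandwidth · ‖IP(i) − IP(j)‖²)`. An all-zero profile *set*
is rejected (bandwidth undefined).

**Integration.** Disease side: `DS + GD` where `DS ≠ 0`, else `GD` — the
sum is kept literal, so integrated values may exceed 1 (an
`average_integration` config flag averages instead; off by default).
lncRNA side: `FS` where nonzero, else `GL` (no sum — the two rules are
deliberately asymmetric). The heterogeneous feature matrix is
block-anti-diagonal, diseases first:

```
X = [[0,      DS(I)],
     [FS(I),  0    ]]           shape (nd+nl) × (nl+nd).
```

## 2. Attention encoder

The graph joins diseases and lncRNAs: a disease's neighbors are its
associated lncRNAs plus diseases with nonzero integrated similarity
(symmetrically for lncRNAs), and every node has a self-loop. Per head:

- edge score `e_ij = LeakyReLU(a · [W∘h_i ‖ W∘h_j])` with an elementwise
  scaling vector `W` and a learned scoring vector `a` (slope 0.2);
- coefficients `α_ij` by masked softmax over each neighborhood
  (they sum to 1 within 1e-9, asserted on every forward pass);
- neighborhood feature `h_Ni = Σ_t α_it h_t`;
- multiple-operator output `M^k = s + c + s⊙c` with the sum branch
  `s = LeakyReLU((h_i + h_Ni) W1_sum)` and the concatenation branch
  `c = LeakyReLU([h_i ‖ h_Ni] W1_cat)`.

A single `W1` cannot multiply both a `d`-vector and a `2d`-vector, so the
two branches carry separate projections `W1_sum (d×k)` and `W1_cat (2d×k)`.
Head outputs are concatenated, giving embeddings with `n_heads × neurons`
columns, split into the disease block `Md` (first `nd` rows) and lncRNA
block `Ml`.

## 3. Inductive matrix completion

The reconstruction is `logits = (Ml·Pl)(Md·Pd)ᵀ` with learned low-rank
projections `Pd, Pl` (rank defaults to `n_heads × neurons`). Reported
scores are `sigmoid(logits)`, a monotone map keeping scores in [0,1]
without changing rankings or AUC. Because the parameters depend only on
features, a disease column that is all-zero in training still receives
informative, non-constant scores (the cold-start property).

**Loss and optimizer.** Training minimizes the squared Frobenius error of
the *linear* reconstruction against the (train-masked) binary matrix, plus
an L2 penalty `λ Σ‖·‖²` (λ = 1) on all projection weights (`W1_sum`,
`W1_cat`, `Pd`, `Pl`), with Adam (lr 0.01 by default) and weight decay
`γ = 5e-2` added to the gradient. Every matrix entry participates; unknown
pairs act as weak negatives. Passing the reconstruction through the sigmoid
*inside* the squared loss was tested and rejected: Adam's scale-invariant
steps drive the logits into deep saturation (≈ −10³) from which gradients
cannot recover, collapsing ranking quality to chance.

**Numerical conditioning.** Two documented choices stabilize training:

1. *Embedding centering* (`center_embeddings`, default on): LeakyReLU head
   outputs share a large positive offset — a near rank-1 component of `M` —
   that dominates the bilinear fit and stalls optimization for hundreds of
   epochs. Each embedding column is mean-centered over nodes before the
   projections; this is one standard feature-normalization step on top of
   the plain `(Ml·Pl)(Md·Pd)ᵀ` form and cuts convergence roughly 4×.
2. *Small projection init* (`proj_init_scale = 0.05`): Glorot-initialized
   projections are shrunk so the initial reconstruction starts near zero
   rather than at large random logits.

Autodiff is a small in-package reverse-mode engine on dense numpy arrays
(`gatimc._autodiff`); gradients are verified against central finite
differences to ≤1e-4 relative error in the test suite.

## 4. Evaluation protocol

k-fold cross-validation (default 5 folds, 10 repeats): positives are
partitioned into folds; each fold's positives are masked from training and
scored against an equal-sized sample of unknown pairs, drawn uniformly
without replacement and re-sampled per repeat. FS and both GIP kernels are
recomputed from the fold's training matrix so no test information leaks
into the features. AUC uses the Mann–Whitney statistic with ties counted
½; AUPR is the step-wise (non-interpolated) precision–recall area. Both
are also checked against independent brute-force oracles in the tests.

**Ablations** run under the otherwise-identical protocol: `no_gaussian`
zeroes GD/GL before integration, `plain_gat` keeps only the concatenation
branch of the head combiner, `plain_mc` learns factor matrices `U·Vᵀ`
directly without node features. `run_cv(train_model=False)` scores with
freshly initialized, untrained parameters — the frozen-random-projection
baseline.

## 5. Synthetic fixtures

All tests and the acceptance script run on self-contained generators:
random rooted ontology DAGs (acyclic by construction, occasional second
parents for genuine DAG shapes) and planted stochastic-block association
matrices (matched lncRNA/disease groups, within-block density `density_in`,
elsewhere `density_out`). Defaults emulate the scale of the curated human
dataset the method targets (156×190, ≈350 positives). Generators are
deterministic given spec + seed.

Note a structural ceiling of this design: with balanced negatives sampled
uniformly from unknown pairs, a share of the negatives falls inside planted
blocks and is statistically exchangeable with masked positives. On the
60×80 fixture with densities 0.3/0.01, scoring with the *true* planted
probabilities — the Bayes-optimal scorer — achieves only ≈0.77 mean AUC
under the exact CV protocol. Measured model AUCs on that fixture must be
read against this ceiling, not against 1.0; the acceptance script reports
the ceiling alongside the model numbers.

## 6. Parameters

| name | default | origin |
|---|---|---|
| `n_heads` | 6 | model-selection study |
| `neurons` | 16 | model-selection study |
| `leaky_slope` | 0.2 | standard attention slope |
| `weight_decay` (γ) | 5e-2 | model-selection study |
| `lam` (λ) | 1.0 | loss equilibrium factor |
| `gamma` (semantic decay) | 0.5 | stated optimal value |
| `folds` / `repeats` | 5 / 10 | protocol |
| `lr` / `epochs` | 0.01 / 200 | package choice (no established default) |
| `rank` | `n_heads × neurons` | package choice |
| `center_embeddings` | on | conditioning (see §3) |
| `proj_init_scale` | 0.05 | conditioning (see §3) |
| `average_integration` | off | literal integration rule kept |

Tests and the acceptance script use a scaled-down configuration (2 heads,
8 neurons, rank 16, lr 0.02) so the full protocol fits desk-scale runtimes;
this is a size choice, not a different model.

## 7. Limitations

- Single attention layer, dense matrices: intended scale is ≤ ~10³ nodes.
- No native MeSH/OBO ontology parsing; inputs are plain edge-list TSVs.
- The training objective treats all unknown pairs as weak negatives; no
  importance weighting of the observed positives is implemented.
- At desk scale the three-operator head combiner does not dominate the
  concatenation-only ablation; see the measured ablation numbers shipped
  with the acceptance results.
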