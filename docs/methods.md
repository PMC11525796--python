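# Methods

## Model

The simulator is a causal implicit generative model over a bipartite
regulatory graph. Writing `E` for expression, `N` for exogenous noise and
`f` for learned functions, TF expressions are generated as
`E_TFi = f_TFi(N_TFi)` and each target gene as
`E_Gj = f_Gj(E_TF1, …, E_TFn, N_Gj)`, with all noise variables jointly
independent (causal sufficiency). The functional forms are unconstrained
feed-forward networks, so co-regulation patterns are learned rather than
assumed.

Training is two-stage:

1. **Controller pre-training.** A WGAN-GP learns the full reference
   distribution over genes *and* TFs; training over all features is what
   makes the library-size normalization meaningful. The generator maps a
   128-dimensional i.i.d. standard-Gaussian noise vector through three
   hidden layers (ReLU, batch norm) to a ReLU output, which the LSN layer
   scales to the configured library size before the critic sees it. After
   training, the critic and LSN layer are discarded and the generator is
   frozen. Only its raw, pre-LSN TF columns are consumed by stage 2; its
   gene columns are discarded.
2. **Target-generator training.** Per-gene generators receive one
   standard-Gaussian noise scalar plus the raw parent-TF values. They are
   realized as one block-sparse masked network (see "Masking"). Their
   outputs and the TF values are reassembled in the reference feature order,
   LSN-normalized, and scored by a fresh critic. The generator loss is the
   adversarial term plus the labeler and anti-labeler losses (unit weights
   by default); both auxiliary losses are minimized from the first step.

The critic objective is the Wasserstein loss `mean(fake) − mean(real)` plus
the gradient penalty `λ·mean((‖∇_x̂ C(x̂)‖₂ − 1)²)` on uniform interpolates,
λ = 10. Five critic updates per generator update. All optimizers are the
AMSGrad variant with β₁ = 0.5, β₂ = 0.9 and a step-wise exponential
learning-rate decay (×0.99 every 1000 updates by default). Weights use He
initialization into ReLU activations and Xavier elsewhere; batch
normalization is applied to generator and labeler hidden layers and never to
the critic, where it would couple per-sample gradients and defeat the
penalty.

### Masking

All per-gene generators live in one sparse network. The input layout is
`[TF values | per-gene noise]`; gene *j*'s hidden block connects only to its
parent TFs and its own noise slot, hidden-to-hidden and hidden-to-output
connections are block diagonal, and masks multiply the weights in the
forward pass. By the chain rule masked weights receive exactly zero
gradient, and since they are initialized at zero they remain exactly zero
after any number of optimizer steps — gene outputs are *structurally*
(not approximately) independent of non-parent TFs. Hidden width per gene is
`2·(|parents|+1)` at depth 3; graphs with more than 5000 edges switch to
depth 2 with width multiplier 1 to bound the parameter count. Batch
normalization acts per hidden unit and therefore preserves the block
structure.

### Labeler and anti-labeler

Both are fully connected networks (default width 2000, depth 3, ReLU +
batch norm except the output layer) mapping gene expressions to TF-value
estimates, trained with the batch-mean squared L2 loss
`(1/N) Σᵢ ‖ŷᵢ − yᵢ‖₂²`. The anti-labeler trains on generated cells only
(targets: the controller's raw TF values); the labeler additionally trains
on real cells (targets: the reference TF columns), with the two losses
summed in each update. Their purpose is to prevent the degenerate solution
in which target generators ignore their TF inputs and model the marginal
from noise alone. Generated gene expressions are presented to both networks
post-LSN so real and generated inputs share a scale. Disabling both is a
single config flag (`use_labelers=False`), which supports ablation studies.

### Deterministic replay and knockout

`generate` saves the controller noise, the per-gene generator noise, the raw
TF matrix and the per-cell LSN scaling factors. `replay` re-runs the forward
pass from the saved arrays and is bit-identical. `knockout` zeroes the named
TFs in the *saved* TF matrix, re-runs only the target generators with the
saved noises and re-applies the *saved* LSN scales. Reusing the saved scales
(rather than recomputing row sums) is what makes genes outside the knocked
TF's children bit-identical between case and control; the intervention is
exactly local by construction. Batch normalization runs in evaluation mode
(frozen running statistics) at generation time, so outputs are per-sample
deterministic and independent of batch composition. Knockout effects are
tested per imposed edge with a two-sided Wilcoxon signed-rank test on paired
expressions (all-zero difference vectors are assigned p = 1, zero pairs
dropped per the standard convention) and Benjamini–Hochberg adjustment
pooled across all edges of the experiment.

## Parameters that matter

| Parameter | Default | Meaning |
| --- | --- | --- |
| library size | 20,000 counts | LSN target; every generated cell sums to it |
| noise_dim | 128 | controller input noise length |
| n_critic | 5 | critic updates per generator update |
| (β₁, β₂) | (0.5, 0.9) | AMSGrad moment decay |
| gp_lambda | 10 | gradient-penalty weight |
| labeler/anti-labeler weight | 1.0 each | auxiliary terms in the generator loss |
| hidden widths | max(256, 2·features) | controller/critic layers; configurable |
| cell filter | ≥ 10 expressed genes | preprocessing |
| gene filter | ≥ 3 expressing cells | preprocessing |
| HVG | top 1000, 20 bins | binned-dispersion selection |

Exact layer widths, learning rates and batch sizes are deliberately
configurable: defaults are conventional values chosen once, and nothing in
the package's guarantees (masking, LSN, replay) depends on them.

## Synthetic reference generator

The fixture is an explicit structural causal model, not a trained network,
so every downstream claim about interventions can be checked against exact
ground truth. It emulates: heavy-tailed positive TF expression (lognormal
with per-TF location), genes as weighted sums of saturating Hill activations
(activating or repressing, h = 2, half-saturation near each TF's population
median) with an optional pairwise-product interaction family and an additive
Gaussian biological-noise term scaled to each gene's expression scale, a
multiplicative lognormal per-cell library factor, and Bernoulli dropout.
Defaults (2000 cells, 30 genes, 10 TFs, 3 parents per gene, Hill regulation,
noise 0.1, dropout 0.2, library sigma 0.25) were chosen once as a
representative small scRNA-seq-like regime.

It does **not** emulate: transcriptional bursting or kinetic dynamics,
UMI-count discreteness (counts stay continuous unless the optional Poisson
layer is enabled), cell-cycle or batch structure, TF–TF regulation
(the graph is bipartite by design), or ambient RNA. Passing tests on this
fixture therefore demonstrates the *mechanics* of the tool — causal masking,
replay, intervention locality, metric correctness, GRN recoverability — not
that generated data matches any particular experimental platform.

## Numerical choices

- All computation is float64 numpy on a single thread; training is
  bit-reproducible for a fixed seed on one machine.
- The tensor engine builds backward passes out of differentiable operations,
  so the gradient penalty's gradient-of-gradient exists exactly; ReLU's
  second derivative is zero almost everywhere and is treated as such.
- LSN refuses rows with total below 1e-12 instead of renormalizing — during
  training this signals a dead generator. ReLU output layers are initialized
  with a small positive bias (0.1) so fresh generators emit strictly
  positive cells.
- The MMD kernel is a sum of three *Gaussian* kernels
  `exp(−d²/σᵢ²)`; the bandwidth rule divides the pooled 25-NN median
  distance by 0.5, 1 and 2 (direction recorded in the report and
  configurable). The biased V-statistic (diagonal kept) makes
  `mmd(X, X) = 0` exact. Degenerate geometries (zero median NN distance)
  require explicit bandwidths.
- LISI calibrates Gaussian neighborhood weights over 3×perplexity nearest
  neighbors by binary search on the entropy; the point itself counts in its
  own neighborhood, which makes the perfectly-mixed co-location case
  evaluate to exactly 2.
- The RF realism score uses pooled-fit PCA (components capped at the data
  rank), 1000 trees, Gini impurity, and stratified 5-fold cross-validated
  probabilities; the fold scheme is seed-controlled since no canonical split
  exists.
- AUPRC uses step-wise (average-precision) integration with tied scores
  grouped into one threshold; ranking ties elsewhere break by score
  descending then name ascending, for cross-platform determinism.
- Control-graph construction takes odd ranks (1st, 3rd, 5th, 7th, 9th) of
  each gene's top-10 ranked TFs as the positive set and even ranks as the
  negative set; densities are equal by construction, and TF-set equality —
  which the rankings may or may not allow — is reported rather than forced.
- Duplicate edges in input lists collapse keeping the maximum score; a name
  appearing as both regulator and target is rejected, not silently resolved.

## Problem sizes

Demonstration and test runs use the toy regime: 2000 reference cells,
40 features, batch 64, 128-wide hidden layers, a few hundred controller
updates and 200–800 target-generator updates; labeler width 128 in the toy
configuration (the 2000-wide default is sized for 1000-gene data). These
sizes were chosen as the package's standard small-scale benchmark; the
causal guarantees (masking, locality, replay) are architectural and hold at
any scale, while resemblance metrics and GRN-recovery margins improve with
longer training and wider networks.

## Known limitations

- Only bipartite TF → gene graphs can be imposed; multi-layer regulation
  (TF → TF cascades) is out of scope.
- Only zeroing knockouts are provided; dosage or overexpression
  interventions are not.
- The built-in edge scorers (absolute Spearman correlation and
  ridge-regularized partial correlation) are baselines for the benchmarking
  harness, not substitutes for dedicated GRN inference methods; external
  tools plug in through the (tf, gene, score) table adapter.
- Training on CPU limits practical scale to thousands of cells and tens to
  hundreds of features per run.
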