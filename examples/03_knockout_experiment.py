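"""In-silico TF knockout with deterministic replay.

Generation saves the controller noise, per-gene noise, TF matrix and LSN
scaling factors, so a knockout re-runs the *same* batch of cells with one TF
zeroed: a matched case/control experiment.  A paired Wilcoxon signed-rank
test per imposed edge (BH-adjusted across all edges) quantifies how many
regulatory edges visibly respond.
"""

import numpy as np

from scgrnsim import (
    ControllerConfig,
    GanConfig,
    SyntheticConfig,
    pretrain,
    preprocess_pipeline,
    simulate_reference,
    train,
)
from scgrnsim.simulate import (
    generate,
    knockout,
    knockout_experiment,
    significant_edge_fraction,
)

em, graph = simulate_reference(SyntheticConfig(seed=0))
data = preprocess_pipeline(em, tf_list=em.tf_names, n_hvg=None)
ctrl, _ = pretrain(data, ControllerConfig(
    steps=200, batch_size=64, hidden_layers=(128,) * 3,
    critic_layers=(128,) * 3, seed=0))
model = train(data, ctrl, graph, GanConfig(
    steps=400, batch_size=64, labeler_width=128,
    critic_layers=(128,) * 3, seed=0))

batch = generate(model, 1000, seed=2)
tf = graph.tfs[0]
case = knockout(model, batch, [tf])

children = set(graph.children(tf))
unchanged = [g for g in graph.genes if g not in children
             if np.array_equal(case.column(g), batch.expression.column(g))]
print(f"knocked out {tf}: {len(children)} regulated genes")
print(f"unregulated genes bit-identical: {len(unchanged)} / "
      f"{len(graph.genes) - len(children)}")

de = knockout_experiment(model, batch)
frac = significant_edge_fraction(de, alpha=0.05)
print(f"edges with BH-adjusted p < 0.05 across all TF knockouts: {frac:.1%}")
print("Unregulated genes never move (the intervention is local); a high "
      "significant fraction shows the imposed edges causally drive targets.")
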