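"""Shared fixtures: synthetic reference data and trained toy models.

The session-scoped ``toy`` fixture trains the full two-stage model once on
the standard synthetic benchmark (2000 cells, 30 genes, 10 TFs, 3 parents
per gene) imposing a positive-control graph derived from the reference data;
several test modules reuse it.  ``quick_model`` is a much smaller/shorter
run for mechanics (replay, knockout plumbing) where model quality is
irrelevant.
"""

from types import SimpleNamespace

import numpy as np
import pytest

from scgrnsim import (
    ControllerConfig,
    GanConfig,
    SyntheticConfig,
    make_control_grns,
    pretrain,
    preprocess_pipeline,
    score_edges_corr,
    simulate_reference,
    train,
)


@pytest.fixture(scope="session")
def toy():
    cfg = SyntheticConfig(seed=1)  # 2000 cells, 30 genes, 10 TFs, k=3, hill
    em, scm_graph = simulate_reference(cfg)
    data = preprocess_pipeline(em, tf_list=em.tf_names, n_hvg=None)
    ranked = score_edges_corr(data).ranked_tfs_per_gene()
    positive, negative = make_control_grns(ranked, top_n=10)
    ctrl, ctrl_history = pretrain(
        data,
        ControllerConfig(
            steps=300, batch_size=64, hidden_layers=(128, 128, 128),
            critic_layers=(128, 128, 128), seed=0,
        ),
    )
    model = train(
        data,
        ctrl,
        positive,
        GanConfig(
            steps=800, batch_size=64, labeler_width=128,
            critic_layers=(128, 128, 128), seed=0,
        ),
    )
    return SimpleNamespace(
        cfg=cfg,
        data=data,
        scm_graph=scm_graph,
        positive=positive,
        negative=negative,
        controller=ctrl,
        controller_history=ctrl_history,
        model=model,
    )


@pytest.fixture(scope="session")
def quick_model():
    cfg = SyntheticConfig(n_cells=500, seed=3)
    em, graph = simulate_reference(cfg)
    data = preprocess_pipeline(em, tf_list=em.tf_names, n_hvg=None)
    ctrl, _ = pretrain(
        data,
        ControllerConfig(
            steps=40, batch_size=32, hidden_layers=(64, 64, 64),
            critic_layers=(64, 64, 64), seed=0,
        ),
    )
    model = train(
        data,
        ctrl,
        graph,
        GanConfig(
            steps=40, batch_size=32, labeler_width=64,
            critic_layers=(64, 64, 64), seed=0,
        ),
    )
    return SimpleNamespace(cfg=cfg, data=data, graph=graph, model=model)
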