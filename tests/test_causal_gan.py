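"""Target-generator masking, architecture rules, and the training loop."""

import numpy as np
import pytest

from scgrnsim import GanConfig, train
from scgrnsim import nn
from scgrnsim.causal_gan import TargetGeneratorNet, build_target_generators
from scgrnsim.grn import from_edges, random_grn
from scgrnsim.nn import Tensor


class TestArchitectureRules:
    def test_width_is_twice_regulators_at_depth_three(self):
        tfs = [f"T{i}" for i in range(15)]
        g = from_edges([(t, "G1") for t in tfs])
        net = build_target_generators(g, tfs, seed=0)
        # 15 parents + 1 noise -> per-gene input 16, hidden width 32
        assert net.depth == 3
        assert net.hidden_widths == [2 * (15 + 1)]

    def test_dense_graph_switches_to_depth_two_width_one(self):
        genes = [f"G{i}" for i in range(501)]
        tfs = [f"T{i}" for i in range(20)]
        g = random_grn(genes, tfs, k=11, seed=0)   # 5511 edges > 5000
        net = build_target_generators(g, tfs, seed=0)
        assert net.depth == 2
        assert net.hidden_widths[0] == 11 + 1

    def test_unknown_tf_rejected(self):
        g = from_edges([("T1", "G1")])
        with pytest.raises(ValueError, match="controller"):
            build_target_generators(g, ["T2"], seed=0)


class TestMaskStructure:
    @pytest.fixture(scope="class")
    def net_and_graph(self):
        tfs = [f"T{i}" for i in range(6)]
        genes = [f"G{i}" for i in range(8)]
        g = random_grn(genes, tfs, k=2, seed=1)
        net = build_target_generators(g, tfs, seed=2)
        for m in net.modules():
            m.training = False  # per-sample determinism for finite differences
        return net, g, tfs

    def test_non_parent_tfs_have_exactly_zero_influence(self, net_and_graph):
        # finite-difference over every (TF, gene) pair at random weights
        net, g, tfs = net_and_graph
        rng = np.random.default_rng(3)
        tf_vals = rng.gamma(2.0, 1.0, size=(4, 6))
        noise = rng.standard_normal((4, len(net.gene_order)))
        base = net(Tensor(tf_vals), Tensor(noise)).data
        for i, tf in enumerate(tfs):
            bumped = tf_vals.copy()
            bumped[:, i] += 1.0
            delta = net(Tensor(bumped), Tensor(noise)).data - base
            for j, gene in enumerate(net.gene_order):
                if tf not in g.parents(gene):
                    assert np.all(delta[:, j] == 0.0), (tf, gene)

    def test_own_noise_only(self, net_and_graph):
        net, _, _ = net_and_graph
        rng = np.random.default_rng(4)
        tf_vals = rng.gamma(2.0, 1.0, size=(3, 6))
        noise = rng.standard_normal((3, len(net.gene_order)))
        base = net(Tensor(tf_vals), Tensor(noise)).data
        bumped = noise.copy()
        bumped[:, 0] += 1.0  # gene 0's noise slot
        delta = net(Tensor(tf_vals), Tensor(bumped)).data - base
        assert np.all(delta[:, 1:] == 0.0)


@pytest.fixture(scope="module")
def tiny_setup():
    from scgrnsim import ControllerConfig, pretrain, preprocess_pipeline
    from scgrnsim.synthetic import SyntheticConfig, simulate_reference

    em, graph = simulate_reference(
        SyntheticConfig(n_cells=200, n_genes=8, n_tfs=4, k_parents=2, seed=6)
    )
    data = preprocess_pipeline(em, tf_list=em.tf_names, n_hvg=None)
    ctrl, _ = pretrain(
        data,
        ControllerConfig(steps=10, batch_size=16, hidden_layers=(32, 32, 32),
                         critic_layers=(32, 32, 32), seed=0),
    )
    return data, ctrl, graph


TINY_GAN = dict(batch_size=16, labeler_width=32, critic_layers=(32, 32, 32),
                seed=0)


class TestTrainingLoop:
    def test_missing_grn_features_rejected(self, tiny_setup):
        data, ctrl, _ = tiny_setup
        bad = from_edges([("TF001", "NOT_A_GENE")])
        with pytest.raises(ValueError, match="NOT_A_GENE"):
            train(data, ctrl, bad, GanConfig(steps=1, **TINY_GAN))

    def test_counters_and_mask_invariance(self, tiny_setup):
        data, ctrl, graph = tiny_setup
        model = train(data, ctrl, graph, GanConfig(steps=8, **TINY_GAN))
        c = model.history["counters"]
        assert c["critic_updates"] == 5 * c["generator_updates"]
        for m in model.target_net.modules():
            if isinstance(m, nn.MaskedLinear):
                assert np.all(m.weight.data[m.mask.data == 0] == 0.0)

    def test_fixed_seed_bit_identical_weights(self, tiny_setup):
        data, ctrl, graph = tiny_setup
        cfg = GanConfig(steps=5, **TINY_GAN)
        a = train(data, ctrl, graph, cfg)
        b = train(data, ctrl, graph, cfg)
        for pa, pb in zip(a.target_net.state_arrays(), b.target_net.state_arrays()):
            assert np.array_equal(pa, pb)
        for pa, pb in zip(a.critic.state_arrays(), b.critic.state_arrays()):
            assert np.array_equal(pa, pb)

    def test_labeler_ablation_flag(self, tiny_setup):
        data, ctrl, graph = tiny_setup
        model = train(data, ctrl, graph,
                      GanConfig(steps=3, use_labelers=False, **TINY_GAN))
        assert model.labeler is None and model.anti_labeler is None
        assert np.all(np.isfinite(model.history["gen_loss"]))

    def test_training_history_finite(self, tiny_setup):
        data, ctrl, graph = tiny_setup
        model = train(data, ctrl, graph, GanConfig(steps=6, **TINY_GAN))
        for key in ("critic_loss", "gen_loss", "labeler_loss", "antilabeler_loss"):
            assert np.all(np.isfinite(model.history[key]))


class TestTrainedModelQuality:
    def test_training_improves_over_initialization(self, toy):
        # RF discriminability of generated vs held-out real cells must drop
        # relative to an untrained target-generator stack
        from scgrnsim.causal_gan import GanBundle, make_labeler
        from scgrnsim.controller import make_critic, _auto_widths
        from scgrnsim.metrics import rf_auroc
        from scgrnsim.simulate import generate

        rng = np.random.default_rng(0)
        init_net = TargetGeneratorNet(toy.positive, toy.controller.tf_names, rng)
        init_model = GanBundle(
            controller=toy.controller,
            target_net=init_net,
            critic=make_critic(toy.data.n_features,
                               _auto_widths(None, toy.data.n_features), rng),
            labeler=None, anti_labeler=None,
            grn=toy.positive,
            feature_ids=list(toy.data.feature_ids),
            is_tf=toy.data.is_tf.copy(),
            library_size=20_000.0,
            config=GanConfig(steps=1),
        )
        init_model.eval()
        held_out = toy.data.subset_cells(np.arange(1000, 2000))
        auroc_init = rf_auroc(
            held_out, generate(init_model, 500, seed=11).expression,
            trees=100, seed=0,
        )
        auroc_trained = rf_auroc(
            held_out, generate(toy.model, 500, seed=11).expression,
            trees=100, seed=0,
        )
        assert auroc_trained < auroc_init
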