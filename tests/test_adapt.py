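"""Training-procedure contracts: pair combinatorics, determinism, gradient
flow, and the small-scale behavior of each stage."""

import math

import numpy as np
import pytest

from seadapt import (
    TrainConfig,
    adapt_conditional,
    adapt_marginal,
    sample_pairs,
    select_shots,
    train_source,
)
from seadapt.adapt import run_method, prepare_scenario
from seadapt.errors import ConfigurationError, ValidationError
from seadapt.msio import PatchSet

from conftest import labeled_patchset


def _params(model):
    return [p.value.copy() for p in model.net.params()]


def _identical(a, b):
    return all(np.array_equal(x, y) for x, y in zip(a, b))


class TestTrainConfig:
    def test_defaults_match_reference_operating_point(self):
        cfg = TrainConfig()
        assert (cfg.source_epochs, cfg.batch_size) == (50, 128)
        assert (cfg.adversarial_epochs, cfg.ccsa_epochs) == (300, 240)
        assert cfg.learning_rate == pytest.approx(2e-4)
        assert cfg.pairs_per_class == 400 and cfg.margin == 1.0

    def test_scaled_schedule(self):
        cfg = TrainConfig().scaled(10)
        assert (cfg.adversarial_epochs, cfg.ccsa_epochs) == (30, 24)

    def test_round_trip_through_dict_and_yaml(self, tmp_path):
        cfg = TrainConfig(seed=7, shots=3, loss_weights=(1, 2, 3))
        assert TrainConfig.from_dict(cfg.to_dict()) == cfg
        path = tmp_path / "cfg.yaml"
        import yaml

        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert TrainConfig.from_file(path) == cfg

    def test_invalid_values_rejected(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ConfigurationError):
            TrainConfig(shots=0)
        with pytest.raises(ConfigurationError):
            TrainConfig.from_dict({"not_a_key": 1})


class TestTrainSource:
    def test_separable_data_reaches_high_accuracy(self, rng):
        ps = labeled_patchset(rng, n_per_class=60, n_classes=3, bands=4)
        cfg = TrainConfig(source_epochs=10, batch_size=32, seed=7)
        _, _, hist = train_source(ps, cfg)
        assert hist["train_accuracy"] >= 0.99
        assert len(hist["classification"]) == 10

    def test_constant_inputs_plateau_at_log_nclasses(self, rng):
        n = 40
        patches = np.zeros((3 * n, 5, 5, 2))
        labels = np.repeat([0, 1, 2], n)
        ps = PatchSet(patches, labels, np.zeros((3 * n, 2), int), 5,
                      class_names=("a", "b", "c"))
        cfg = TrainConfig(source_epochs=6, batch_size=64, seed=1, normalize=False)
        _, _, hist = train_source(ps, cfg)
        assert hist["classification"][-1] == pytest.approx(math.log(3), abs=0.05)

    def test_seeded_determinism(self, rng):
        ps = labeled_patchset(rng, n_per_class=20)
        cfg = TrainConfig(source_epochs=2, batch_size=32, seed=3)
        G1, C1, _ = train_source(ps, cfg)
        G2, C2, _ = train_source(ps, cfg)
        assert _identical(_params(G1), _params(G2))
        assert _identical(_params(C1), _params(C2))

    def test_missing_class_rejected(self, rng):
        ps = labeled_patchset(rng, n_per_class=10, n_classes=2)
        ps = PatchSet(ps.patches, ps.labels, ps.centers, 5, class_names=("a", "b", "c"))
        with pytest.raises(ValidationError, match="class"):
            train_source(ps, TrainConfig(source_epochs=1, seed=0))


class TestAdaptMarginal:
    def test_zero_epochs_is_identity(self, rng, tiny_config):
        ps = labeled_patchset(rng, n_per_class=15)
        G, _, _ = train_source(ps, tiny_config)
        from dataclasses import replace

        G_t, _, hist = adapt_marginal(G, ps, ps, replace(tiny_config, adversarial_epochs=0))
        assert _identical(_params(G), _params(G_t))
        assert hist["discriminator"] == []

    def test_source_embedding_frozen_bit_exact(self, rng, tiny_config):
        ps = labeled_patchset(rng, n_per_class=15)
        G, _, _ = train_source(ps, tiny_config)
        before = _params(G)
        adapt_marginal(G, ps, ps, tiny_config)
        assert _identical(before, _params(G))

    def test_history_lengths_match_epochs(self, rng, tiny_config):
        ps = labeled_patchset(rng, n_per_class=15)
        G, _, _ = train_source(ps, tiny_config)
        _, _, hist = adapt_marginal(G, ps, ps, tiny_config)
        assert len(hist["discriminator"]) == tiny_config.adversarial_epochs
        assert len(hist["generator"]) == tiny_config.adversarial_epochs

    def test_empty_domain_rejected(self, rng, tiny_config):
        ps = labeled_patchset(rng, n_per_class=5)
        empty = ps.subset([])
        G, _, _ = train_source(ps, tiny_config)
        with pytest.raises(ValidationError):
            adapt_marginal(G, ps, empty, tiny_config)

    def test_identical_domains_reach_discriminator_equilibrium(self):
        """With source = target distribution the trained discriminator stays
        near chance on held-out balanced batches (mean over 3 seeds).

        Uses fresh scene realizations of the same zero-shift world as the
        held-out probes; the equilibrium claim is about distributions, so the
        probes must not be the training patches."""
        from seadapt import synthdata
        from seadapt.evaluation import discriminator_accuracy

        cfg_gen = synthdata.benchmark_suite(seed=1)["none"].config
        train_pair = synthdata.generate_scene_pair(cfg_gen)
        held_pair = synthdata.generate_scene_pair(synthdata.with_seed(cfg_gen, 999))
        accs = []
        for seed in range(3):
            cfg = TrainConfig(source_epochs=6, adversarial_epochs=30, batch_size=128,
                              seed=seed)
            data = prepare_scenario(train_pair[0], train_pair[1], train_pair[2],
                                    train_pair[3], cfg, max_per_class=200,
                                    max_unlabeled=1200, seed=seed)
            held = prepare_scenario(held_pair[0], held_pair[1], held_pair[2],
                                    held_pair[3], cfg, max_per_class=200,
                                    max_unlabeled=600, seed=seed)
            G, _, _ = train_source(data.source_labeled, cfg, data.n_classes)
            G_t, D, _ = adapt_marginal(G, data.source_unlabeled, data.target_unlabeled, cfg)
            accs.append(discriminator_accuracy(D, G, G_t,
                                               held.source_unlabeled, held.target_unlabeled))
        assert 0.4 <= np.mean(accs) <= 0.6

    def test_adaptation_fools_discriminator_on_shifted_domains(self, rng):
        """After adversarial adaptation, a fresh discriminator separates the
        domains worse than one trained against a frozen (unadapted) G_t."""
        from seadapt.evaluation import discriminator_accuracy

        src = labeled_patchset(rng, n_per_class=60, n_classes=3, bands=4)
        tgt = labeled_patchset(rng, n_per_class=60, n_classes=3, bands=4)
        tgt.patches[...] = tgt.patches * 1.5 + 0.8  # strong affine shift
        cfg = TrainConfig(source_epochs=4, adversarial_epochs=12, batch_size=64, seed=0)
        G_s, _, _ = train_source(src, cfg)
        G_t, D_adapted, _ = adapt_marginal(G_s, src, tgt, cfg)
        # control: discriminator trained directly against the frozen G_s
        # embeddings of both domains (G_t never updated)
        from seadapt._nn import Adam
        from seadapt.models import build_discriminator

        D_frozen = build_discriminator(G_s.embed_dim, seed=1)
        opt = Adam(D_frozen.net.params(), lr=cfg.learning_rate, beta1=0.5)
        es_all, et_all = G_s.forward(src.patches), G_s.forward(tgt.patches)
        r = np.random.default_rng(0)
        for _ in range(200):
            si = r.choice(len(es_all), 64)
            ti = r.choice(len(et_all), 64)
            D_frozen.net.zero_grad()
            zs = D_frozen.net.forward(es_all[si])[:, 0]
            D_frozen.net.backward(((1 / (1 + np.exp(-zs)) - 1) / 64)[:, None])
            zt = D_frozen.net.forward(et_all[ti])[:, 0]
            D_frozen.net.backward(((1 / (1 + np.exp(-zt))) / 64)[:, None])
            opt.step()
        acc_adapted = discriminator_accuracy(D_adapted, G_s, G_t, src, tgt)
        acc_frozen = discriminator_accuracy(D_frozen, G_s, G_s, src, tgt)
        assert acc_adapted < acc_frozen


class TestSamplePairs:
    def test_pair_counts_for_five_class_one_shot(self, rng):
        src = labeled_patchset(rng, n_per_class=450, n_classes=5, bands=2)
        shots = src.subset(select_shots(src, 1, seed=0, n_classes=5))
        pairs = sample_pairs(src, shots, pairs_per_class=400, seed=0)
        assert len(pairs.positives) == 2000
        assert len(pairs.negatives) == 8000

    def test_tiny_exhaustive_case(self, rng):
        src = labeled_patchset(rng, n_per_class=1, n_classes=2, bands=2)
        pairs = sample_pairs(src, src, pairs_per_class=1, seed=0)
        assert len(pairs.positives) == 2
        assert len(pairs.negatives) == 2

    def test_label_relations_hold(self, rng):
        src = labeled_patchset(rng, n_per_class=30, n_classes=3, bands=2)
        shots = src.subset(select_shots(src, 2, seed=1, n_classes=3))
        pairs = sample_pairs(src, shots, pairs_per_class=10, seed=1)
        for i, j in pairs.positives:
            assert src.labels[i] == shots.labels[j]
        for i, j in pairs.negatives:
            assert src.labels[i] != shots.labels[j]
        # every shot appears in at least one positive and one negative pair
        assert set(pairs.positives[:, 1]) == set(range(len(shots)))
        assert set(pairs.negatives[:, 1]) == set(range(len(shots)))

    def test_seeded_determinism(self, rng):
        src = labeled_patchset(rng, n_per_class=30, n_classes=3, bands=2)
        shots = src.subset(select_shots(src, 1, seed=2, n_classes=3))
        a = sample_pairs(src, shots, pairs_per_class=8, seed=5)
        b = sample_pairs(src, shots, pairs_per_class=8, seed=5)
        np.testing.assert_array_equal(a.positives, b.positives)
        np.testing.assert_array_equal(a.negatives, b.negatives)

    def test_class_missing_in_source_rejected(self, rng):
        src = labeled_patchset(rng, n_per_class=10, n_classes=2, bands=2)
        shots = labeled_patchset(rng, n_per_class=1, n_classes=3, bands=2)
        with pytest.raises(ValidationError):
            sample_pairs(src, shots, pairs_per_class=4, seed=0)


class TestAdaptConditional:
    @pytest.fixture
    def setup(self, rng):
        src = labeled_patchset(rng, n_per_class=40, n_classes=3, bands=4)
        tgt = labeled_patchset(rng, n_per_class=40, n_classes=3, bands=4)
        cfg = TrainConfig(source_epochs=3, ccsa_epochs=3, batch_size=64,
                          pairs_per_class=20, shots=2, seed=0)
        G_s, C_s, _ = train_source(src, cfg)
        shots = tgt.subset(select_shots(tgt, 2, seed=0, n_classes=3))
        pairs = sample_pairs(src, shots, 20, seed=0)
        return src, tgt, shots, pairs, G_s, C_s, cfg

    def test_joint_updates_both_embeddings(self, setup):
        src, tgt, shots, pairs, G_s, C_s, cfg = setup
        before = _params(G_s)
        G_s2, G_t2, C_t, hist = adapt_conditional(G_s, G_s.copy(), C_s, src, shots, pairs, cfg)
        assert _identical(before, _params(G_s))       # input never mutated
        assert not _identical(before, _params(G_s2))  # joint copy updated
        assert not _identical(before, _params(G_t2))
        assert len(hist["semantic_alignment"]) == cfg.ccsa_epochs

    def test_joint_false_freezes_source_side(self, setup):
        from dataclasses import replace

        src, tgt, shots, pairs, G_s, C_s, cfg = setup
        before = _params(G_s)
        G_s2, _, _, _ = adapt_conditional(G_s, G_s.copy(), C_s, src, shots, pairs,
                                          replace(cfg, joint=False))
        assert _identical(before, _params(G_s2))

    def test_alignment_loss_decreases_on_identical_domains(self, rng):
        src = labeled_patchset(rng, n_per_class=50, n_classes=3, bands=4)
        cfg = TrainConfig(source_epochs=4, ccsa_epochs=10, batch_size=64,
                          pairs_per_class=30, shots=3, seed=1)
        G_s, C_s, _ = train_source(src, cfg)
        shots = src.subset(select_shots(src, 3, seed=1, n_classes=3))
        pairs = sample_pairs(src, shots, 30, seed=1)
        _, _, _, hist = adapt_conditional(G_s, G_s.copy(), C_s, src, shots, pairs, cfg)
        sa = hist["semantic_alignment"]
        assert np.mean(sa[-3:]) <= np.mean(sa[:3])

    def test_empty_pairs_rejected(self, setup):
        from seadapt.adapt import PairSet

        src, tgt, shots, pairs, G_s, C_s, cfg = setup
        empty = PairSet(np.empty((0, 2), int), np.empty((0, 2), int))
        with pytest.raises(ValidationError):
            adapt_conditional(G_s, G_s.copy(), C_s, src, shots, empty, cfg)

    def test_cross_class_exceed_within_class_distances_after_adaptation(self, setup):
        src, tgt, shots, pairs, G_s, C_s, cfg = setup
        G_s2, G_t2, _, _ = adapt_conditional(G_s, G_s.copy(), C_s, src, shots, pairs, cfg)
        es, et = G_s2.forward(src.patches), G_t2.forward(tgt.patches)
        from scipy.spatial.distance import cdist

        d = cdist(et, es)
        same = tgt.labels[:, None] == src.labels[None, :]
        assert d[~same].mean() > d[same].mean()


class TestEndToEndProtocol:
    def test_run_method_deterministic(self, tiny_scene_pair):
        src, sm, tgt, tm, _ = tiny_scene_pair
        cfg = TrainConfig(source_epochs=2, adversarial_epochs=2, ccsa_epochs=2,
                          pairs_per_class=20, shots=1, seed=5, max_pair_batches=10)
        data = prepare_scenario(src, sm, tgt, tm, cfg, max_per_class=80,
                                max_unlabeled=200, seed=0)
        a = run_method(data, "proposed", cfg)
        b = run_method(data, "proposed", cfg)
        assert a.target_accuracy == b.target_accuracy

    def test_insufficient_shots_error_names_class(self, tiny_scene_pair):
        src, sm, tgt, tm, _ = tiny_scene_pair
        cfg = TrainConfig(source_epochs=1, shots=10_000, seed=0)
        data = prepare_scenario(src, sm, tgt, tm, cfg, seed=0)
        with pytest.raises(ValidationError, match="sea|sand|seagrass"):
            run_method(data, "ccsa", cfg)

    def test_exactly_n_shots_visible_to_adaptation(self, tiny_scene_pair, monkeypatch):
        """Spy on the adaptation stages: the only labeled target data they
        receive is the n-shot set (n per class), and the adversarial stage
        receives no target labels at all."""
        import seadapt.adapt as adapt_mod

        src, sm, tgt, tm, _ = tiny_scene_pair
        n = 2
        cfg = TrainConfig(source_epochs=2, adversarial_epochs=1, ccsa_epochs=1,
                          pairs_per_class=10, shots=n, seed=3, max_pair_batches=5)
        data = prepare_scenario(src, sm, tgt, tm, cfg, max_per_class=60,
                                max_unlabeled=100, seed=0)
        seen = {}
        real_pairs, real_cond, real_marg = (adapt_mod.sample_pairs,
                                            adapt_mod.adapt_conditional,
                                            adapt_mod.adapt_marginal)

        def spy_pairs(source, target_shots, *a, **k):
            seen["pairs_shots"] = np.bincount(target_shots.labels, minlength=3)
            return real_pairs(source, target_shots, *a, **k)

        def spy_cond(G_s, G_t, C_s, source, target_shots, pairs, config, **k):
            seen["cond_shots"] = np.bincount(target_shots.labels, minlength=3)
            return real_cond(G_s, G_t, C_s, source, target_shots, pairs, config, **k)

        def spy_marg(G_s, source_patches, target_patches, config):
            seen["marginal_target_labels"] = target_patches.labels
            return real_marg(G_s, source_patches, target_patches, config)

        monkeypatch.setattr(adapt_mod, "sample_pairs", spy_pairs)
        monkeypatch.setattr(adapt_mod, "adapt_conditional", spy_cond)
        monkeypatch.setattr(adapt_mod, "adapt_marginal", spy_marg)
        run_method(data, "proposed", cfg)
        assert seen["marginal_target_labels"] is None
        np.testing.assert_array_equal(seen["pairs_shots"], [n, n, n])
        np.testing.assert_array_equal(seen["cond_shots"], [n, n, n])

    def test_all_five_methods_run_from_one_config(self, tiny_scene_pair):
        src, sm, tgt, tm, _ = tiny_scene_pair
        cfg = TrainConfig(source_epochs=2, adversarial_epochs=1, ccsa_epochs=1,
                          pairs_per_class=10, shots=1, seed=2, max_pair_batches=5)
        data = prepare_scenario(src, sm, tgt, tm, cfg, max_per_class=60,
                                max_unlabeled=100, seed=0)
        src_model = train_source(data.source_labeled, cfg, data.n_classes)
        for method in ("source-only", "adda", "finetune", "ccsa", "proposed"):
            res = run_method(data, method, cfg, source_model=src_model)
            assert res.method == method
            assert 0.0 <= res.target_accuracy <= 1.0
            assert res.n_eval > 0
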