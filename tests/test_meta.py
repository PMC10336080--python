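import dataclasses

import numpy as np
import pandas as pd
import pytest

from fluxmeta.errors import ConfigurationError, DivergenceError
from fluxmeta.learners import LearnerConfig, build_learner
from fluxmeta.meta import (
    EnsembleModel,
    MetaConfig,
    _member_seed,
    baseline_train,
    build_eval_arrays,
    build_task_arrays,
    fit_training_stats,
    kfold_select,
    meta_train,
    predict_ensemble,
)
from fluxmeta.synthetic import GeneratorParams, gen_network
from fluxmeta.tasks import MetaSplit, baseline_datasets, split_tasks

LCFG = LearnerConfig(arch="mlp", hidden_size=4, input_dim=5, seed=0)


def constant_learner(value, cfg=LCFG):
    lrn = build_learner(cfg)
    theta = np.zeros(lrn.n_params)
    theta[-1] = value
    lrn.set_params(theta)
    return lrn


def make_ensemble(values):
    members = [constant_learner(v) for v in values]
    from fluxmeta.station_data import FEATURES, NormStats

    stats = NormStats(
        mean=pd.Series(0.0, index=FEATURES), sd=pd.Series(1.0, index=FEATURES)
    )
    return EnsembleModel(
        members=members,
        train_history=pd.DataFrame(columns=["epoch", "member", "split", "rmse"]),
        norm_stats=stats,
        target="GPP",
        lcfg=LCFG,
        mcfg=MetaConfig(),
    )


@pytest.fixture(scope="module")
def network_and_split():
    params = GeneratorParams(
        n_stations_per_zone={"temperate": 4, "continental": 2, "tropics": 2,
                             "semi-arid": 2},
        years=1, zone_shift={"tropics": 1.3, "semi-arid": 1.3},
        seed=21, noise_sd=0.2,
    )
    net = gen_network(params)
    return net, split_tasks(net.stations, seed=21)


class TestMetaTrain:
    def test_epochs_zero_members_equal_initialization(self, network_and_split):
        net, split = network_and_split
        mcfg = MetaConfig(epochs=0, ensemble_size=2, seed=5)
        model = meta_train(split, net.stations, LCFG, mcfg)
        for m, member in enumerate(model.members):
            ref = build_learner(
                dataclasses.replace(LCFG, seed=_member_seed(mcfg.seed, LCFG.seed, m))
            )
            np.testing.assert_array_equal(member.get_params(), ref.get_params())

    def test_reduction_to_plain_gradient_descent(self, network_and_split):
        # inner_steps = 0 with an SGD outer step must follow the plain
        # gradient-descent trajectory on the meta-objective data
        net, split = network_and_split
        mcfg = MetaConfig(
            epochs=10, ensemble_size=1, seed=3, inner_steps=0,
            outer_opt="sgd", outer_lr=1e-3, grad_clip=0.0,
            meta_objective="target_train", tasks_per_meta_batch=1,
            batch_size=10**6, lr_schedule="constant",
        )
        model = meta_train(split, net.stations, LCFG, mcfg)

        # independent oracle: full-batch gradient descent from the same init
        init = meta_train(split, net.stations, LCFG,
                          dataclasses.replace(mcfg, epochs=0))
        theta = init.members[0].get_params()
        stats = fit_training_stats(
            net.stations, {**split.base_train, **split.target_train}
        )
        tasks = build_task_arrays(net.stations, split.base_train, stats, LCFG, "GPP")
        X, y, _, _ = build_eval_arrays(
            net.stations, split.target_train, stats, LCFG, "GPP"
        )
        probe = build_learner(LCFG)
        steps_per_epoch = len(tasks)  # each base task yields one outer step
        for _ in range(mcfg.epochs * steps_per_epoch):
            probe.set_params(theta)
            _, g = probe.loss_and_grad(X, y)
            theta = theta - mcfg.outer_lr * g
        assert np.max(np.abs(model.members[0].get_params() - theta)) <= 1e-8

    def test_seeded_determinism(self, network_and_split):
        net, split = network_and_split
        mcfg = MetaConfig(epochs=2, ensemble_size=1, seed=4)
        a = meta_train(split, net.stations, LCFG, mcfg)
        b = meta_train(split, net.stations, LCFG, mcfg)
        np.testing.assert_array_equal(
            a.members[0].get_params(), b.members[0].get_params()
        )

    def test_second_order_runs_and_differs(self, network_and_split):
        net, split = network_and_split
        fo = MetaConfig(epochs=1, ensemble_size=1, seed=4, inner_lr=1e-2)
        so = dataclasses.replace(fo, first_order=False)
        a = meta_train(split, net.stations, LCFG, fo)
        b = meta_train(split, net.stations, LCFG, so)
        assert not np.allclose(
            a.members[0].get_params(), b.members[0].get_params()
        )

    def test_empty_base_errors(self, network_and_split):
        net, _ = network_and_split
        refs = {s.station_id: (0, len(s)) for s in net.stations[:2]}
        test_refs = {sid: (r[1], r[1]) for sid, r in refs.items()}
        split = MetaSplit(base_train={}, base_test={},
                          target_train=refs, target_test=test_refs, seed=0)
        with pytest.raises(ConfigurationError):
            meta_train(split, net.stations, LCFG, MetaConfig(epochs=1))

    def test_validation_history_recorded(self, network_and_split):
        net, split = network_and_split
        mcfg = MetaConfig(epochs=3, ensemble_size=2, seed=1)
        model = meta_train(split, net.stations, LCFG, mcfg)
        assert len(model.train_history) == 3 * 2
        assert (model.train_history["split"] == "target_test").all()
        assert np.isfinite(model.train_history["rmse"]).all()


class TestBaselineTrain:
    def test_epochs_zero_equals_init(self, network_and_split):
        net, split = network_and_split
        train, test = baseline_datasets(split)
        mcfg = MetaConfig(epochs=0, ensemble_size=1, seed=8)
        model = baseline_train(train, test, net.stations, LCFG, mcfg)
        ref = build_learner(
            dataclasses.replace(LCFG, seed=_member_seed(8, LCFG.seed, 0))
        )
        np.testing.assert_array_equal(
            model.members[0].get_params(), ref.get_params()
        )

    def test_descent_sanity(self, network_and_split):
        net, split = network_and_split
        train, test = baseline_datasets(split)
        mcfg = MetaConfig(epochs=5, ensemble_size=1, seed=0, outer_lr=1e-2)
        model = baseline_train(train, test, net.stations, LCFG, mcfg)
        hist = model.train_history
        assert hist["rmse"].iloc[-1] < hist["rmse"].iloc[0]

    def test_fixed_seed_reproducible(self, network_and_split):
        net, split = network_and_split
        train, test = baseline_datasets(split)
        mcfg = MetaConfig(epochs=2, ensemble_size=1, seed=9)
        a = baseline_train(train, test, net.stations, LCFG, mcfg)
        b = baseline_train(train, test, net.stations, LCFG, mcfg)
        np.testing.assert_array_equal(
            a.members[0].get_params(), b.members[0].get_params()
        )

    def test_divergence_raises(self, network_and_split):
        net, split = network_and_split
        train, test = baseline_datasets(split)
        mcfg = MetaConfig(epochs=3, ensemble_size=1, seed=0, outer_opt="sgd",
                          outer_lr=1e8, grad_clip=0.0)
        with pytest.raises(DivergenceError), np.errstate(all="ignore"):
            baseline_train(train, test, net.stations, LCFG, mcfg)


class TestPredictEnsemble:
    def test_single_member_zero_std(self):
        model = make_ensemble([2.0])
        X = np.zeros((5, 5))
        mean, std = predict_ensemble(model, X)
        np.testing.assert_allclose(std, 0.0)

    def test_two_member_population_std(self):
        model = make_ensemble([1.0, 3.0])
        mean, std = predict_ensemble(model, np.zeros((4, 5)))
        np.testing.assert_allclose(mean, 2.0)
        np.testing.assert_allclose(std, 1.0)  # population sd of {1, 3}

    def test_identical_members_zero_std(self):
        model = make_ensemble([1.5, 1.5, 1.5])
        _, std = predict_ensemble(model, np.zeros((3, 5)))
        np.testing.assert_allclose(std, 0.0)

    def test_member_order_invariance(self):
        a = make_ensemble([1.0, 2.0, 4.0])
        b = make_ensemble([4.0, 1.0, 2.0])
        X = np.zeros((3, 5))
        np.testing.assert_allclose(
            predict_ensemble(a, X)[1], predict_ensemble(b, X)[1]
        )

    def test_empty_ensemble_errors(self):
        model = make_ensemble([1.0])
        model.members = []
        with pytest.raises(ConfigurationError):
            predict_ensemble(model, np.zeros((2, 5)))


@pytest.fixture(scope="module")
def train_pool():
    params = GeneratorParams(
        n_stations_per_zone={"temperate": 6}, years=1, seed=2, noise_sd=0.1
    )
    net = gen_network(params)
    refs = {s.station_id: (0, len(s)) for s in net.stations}
    return net, refs


class TestKFoldSelect:
    def test_single_candidate_returned(self, train_pool):
        net, refs = train_pool
        cand = (LCFG, MetaConfig(epochs=1, ensemble_size=1))
        result = kfold_select([cand], net.stations, refs, k=3, seed=0)
        assert result.best == cand
        assert len(result.scores) == 3

    def test_capacity_selection(self, train_pool):
        net, refs = train_pool
        mcfg = MetaConfig(epochs=8, ensemble_size=1, outer_lr=1e-2,
                          lr_schedule="cosine")
        rich = (dataclasses.replace(LCFG, hidden_size=16), mcfg)
        poor = (dataclasses.replace(LCFG, hidden_size=1), mcfg)
        result = kfold_select([poor, rich], net.stations, refs, k=3, seed=0)
        assert result.best_index == 1

    def test_folds_partition_stations(self, train_pool):
        net, refs = train_pool
        with pytest.raises(ConfigurationError):
            kfold_select(
                [(LCFG, MetaConfig(epochs=1))], net.stations, refs, k=7, seed=0
            )


class TestEnsemblePersistence:
    def test_save_load_round_trip(self, tmp_path, network_and_split):
        net, split = network_and_split
        model = meta_train(split, net.stations, LCFG,
                           MetaConfig(epochs=1, ensemble_size=2, seed=0))
        path = tmp_path / "ens.npz"
        model.save(path)
        back = EnsembleModel.load(path)
        assert back.lcfg == model.lcfg and back.mcfg == model.mcfg
        for a, b in zip(model.members, back.members):
            np.testing.assert_array_equal(a.get_params(), b.get_params())
        X = np.zeros((3, 5))
        np.testing.assert_allclose(
            predict_ensemble(model, X)[0], predict_ensemble(back, X)[0]
        )
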