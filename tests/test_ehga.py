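"""Network forward pass, EHO/GA operators, and training contracts."""

import numpy as np
import pytest

from securedx import ehga
from securedx.ehga import (
    EHGAClassifier,
    NetworkParams,
    TrainConfig,
    clan_update,
    crossover_points,
    forward,
    genome_length,
    loss,
    mutate,
    pack_genome,
    predict,
    separation,
    train,
    two_point_crossover,
    unpack_genome,
)
from securedx.errors import ConfigurationError, ValidationError

BOUNDS = (-5.0, 5.0)


def zero_params(layer_sizes, bias=0.0):
    return unpack_genome(
        np.concatenate(
            [
                np.concatenate([np.zeros(a * b), np.full(b, bias)])
                for a, b in zip(layer_sizes[:-1], layer_sizes[1:])
            ]
        ),
        layer_sizes,
    )


class TestForward:
    def test_zero_weights_give_sigmoid_of_bias(self):
        params = zero_params((3, 2), bias=1.5)
        out = forward(params, np.zeros(3))
        np.testing.assert_allclose(out, 1 / (1 + np.exp(-1.5)))

    def test_zero_everything_gives_half(self):
        params = zero_params((4, 3, 2))
        out = forward(params, np.zeros(4))
        # hidden outputs 0.5, but output layer weights are 0 -> sigmoid(0)
        np.testing.assert_allclose(out, 0.5)

    def test_deterministic_and_batch_consistent(self):
        rng = np.random.default_rng(0)
        sizes = (5, 16, 1)
        params = unpack_genome(
            rng.uniform(-2, 2, genome_length(sizes)), sizes
        )
        X = rng.normal(size=(10, 5))
        out1 = forward(params, X)
        out2 = forward(params, X)
        np.testing.assert_array_equal(out1, out2)
        np.testing.assert_allclose(out1[3], forward(params, X[3]))

    def test_shape_mismatch_rejected(self):
        params = zero_params((3, 1))
        with pytest.raises(ValidationError):
            forward(params, np.zeros(4))

    def test_genome_pack_unpack_round_trip(self):
        rng = np.random.default_rng(1)
        sizes = (4, 7, 3)
        genome = rng.normal(size=genome_length(sizes))
        np.testing.assert_array_equal(
            pack_genome(unpack_genome(genome, sizes)), genome
        )


class TestLoss:
    def test_zero_discrepancy(self):
        assert loss(np.array([0.2, 0.8]), np.array([0.2, 0.8])) == 0.0

    def test_scalar_unit_error(self):
        assert loss(np.array([0.0]), np.array([1.0])) == 1.0

    def test_sign_symmetric(self):
        a = loss(np.array([0.3]), np.array([0.7]))
        b = loss(np.array([0.7]), np.array([0.3]))
        assert a == b

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            loss(np.zeros(2), np.zeros(3))


class TestClanUpdate:
    def setup_method(self):
        self.rng = np.random.default_rng(0)
        self.pos = self.rng.uniform(-5, 5, size=(6, 8))
        self.fit = np.arange(6, dtype=float)  # member 0 is matriarch

    def test_movement_is_toward_matriarch(self):
        new = clan_update(self.pos, self.fit, 1.0, BOUNDS, self.rng)
        for m in range(1, 6):
            move = new[m] - self.pos[m]
            target = self.pos[0] - self.pos[m]
            # move = g * target for scalar g in [0, 1]
            ratios = move[target != 0] / target[target != 0]
            assert np.allclose(ratios, ratios[0])
            assert 0.0 <= ratios[0] <= 1.0

    def test_alpha_zero_fixes_non_matriarch_members(self):
        new = clan_update(self.pos, self.fit, 1e-300, BOUNDS, self.rng)
        np.testing.assert_allclose(new[1:], self.pos[1:], atol=1e-290)

    def test_matriarch_moves_to_scaled_center(self):
        new = clan_update(self.pos, self.fit, 0.5, BOUNDS, self.rng, beta=0.5)
        np.testing.assert_allclose(new[0], 0.5 * self.pos.mean(axis=0))

    def test_bounds_respected(self):
        pos = np.full((4, 3), 4.9)
        pos[0] = 5.0
        new = clan_update(pos, np.arange(4.0), 1.0, BOUNDS, self.rng)
        assert new.min() >= BOUNDS[0] and new.max() <= BOUNDS[1]


class TestSeparation:
    def test_only_worst_member_changes(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(-5, 5, size=(5, 7))
        fit = np.array([0.3, 0.1, 0.9, 0.2, 0.5])  # index 2 worst
        new, worst = separation(pos, fit, BOUNDS, rng)
        assert worst == 2
        np.testing.assert_array_equal(np.delete(new, 2, 0), np.delete(pos, 2, 0))
        assert not np.array_equal(new[2], pos[2])
        assert new[2].min() >= BOUNDS[0] and new[2].max() <= BOUNDS[1]

    def test_tiny_clan_rejected(self):
        with pytest.raises(ValidationError):
            separation(np.zeros((1, 3)), np.zeros(1), BOUNDS,
                       np.random.default_rng(0))


class TestCrossover:
    def test_cut_points_for_length_12(self):
        assert crossover_points(12) == (4, 10)

    def test_middle_segment_swapped(self):
        a = np.arange(12.0)
        b = np.arange(12.0) + 100
        ca, cb = two_point_crossover(a, b)
        np.testing.assert_array_equal(ca[:4], a[:4])
        np.testing.assert_array_equal(ca[4:10], b[4:10])
        np.testing.assert_array_equal(ca[10:], a[10:])
        np.testing.assert_array_equal(cb[4:10], a[4:10])

    def test_identical_parents_identical_children(self):
        a = np.arange(9.0)
        ca, cb = two_point_crossover(a, a.copy())
        np.testing.assert_array_equal(ca, a)
        np.testing.assert_array_equal(cb, a)

    def test_genes_conserved_positionwise(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(2, 31))
        ca, cb = two_point_crossover(a, b)
        for i in range(31):
            assert {ca[i], cb[i]} == {a[i], b[i]}

    def test_short_genomes_rejected(self):
        with pytest.raises(ValidationError):
            two_point_crossover(np.zeros(2), np.zeros(2))

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7, 113])
    def test_cut_points_valid_for_any_length(self, n):
        c1, c2 = crossover_points(n)
        assert 0 <= c1 < c2 <= n - 1


class TestMutation:
    def test_rate_zero_is_identity(self):
        g = np.arange(10.0)
        out = mutate(g, 0.0, BOUNDS, np.random.default_rng(0))
        np.testing.assert_array_equal(out, g)

    def test_rate_one_replaces_every_gene(self):
        g = np.linspace(-1, 1, 20)
        out = mutate(g, 1.0, BOUNDS, np.random.default_rng(1))
        assert np.all(out != g)
        assert out.min() >= BOUNDS[0] and out.max() <= BOUNDS[1]

    def test_seeded_reproducibility(self):
        g = np.arange(15.0)
        out1 = mutate(g, 0.5, BOUNDS, np.random.default_rng(7))
        out2 = mutate(g, 0.5, BOUNDS, np.random.default_rng(7))
        np.testing.assert_array_equal(out1, out2)


def separable_data(n=120, d=4, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = y[:, None] * 3.0 + rng.normal(size=(n, d))
    return X, y


class TestTraining:
    def test_best_fitness_trace_nonincreasing(self):
        X, y = separable_data()
        for seed in range(3):
            cfg = TrainConfig(
                n_clans=3, clan_size=5, max_iterations=15, seed=seed
            )
            model = train(X, y, cfg)
            trace = np.array(model.trace)
            assert np.all(np.diff(trace) <= 0)

    def test_infinite_threshold_runs_all_iterations(self):
        X, y = separable_data(n=40)
        cfg = TrainConfig(
            n_clans=2, clan_size=4, max_iterations=7,
            loss_threshold=-1.0, seed=0,
        )
        model = train(X, y, cfg)
        assert model.n_iterations == 7
        cfg2 = TrainConfig(
            n_clans=2, clan_size=4, max_iterations=7,
            loss_threshold=float("inf"), seed=0,
        )
        assert train(X, y, cfg2).n_iterations == 1  # stops immediately

    def test_sample_count_must_match_rows(self):
        X, y = separable_data(n=40)
        cfg = TrainConfig(
            n_clans=2, clan_size=4, max_iterations=2, sample_count=39, seed=0
        )
        with pytest.raises(ConfigurationError):
            train(X, y, cfg)

    def test_empty_features_rejected(self):
        with pytest.raises(ValidationError):
            train(np.empty((0, 3)), np.empty(0), TrainConfig(
                n_clans=2, clan_size=4, max_iterations=2))

    def test_evaluation_accounting(self):
        # per iteration and clan: k CM children + k clan-update candidates
        # + 1 separation replacement; plus the initial population
        X, y = separable_data(n=30)
        cfg = TrainConfig(
            n_clans=3, clan_size=4, max_iterations=5,
            loss_threshold=-1.0, seed=1,
        )
        model = train(X, y, cfg)
        pop = cfg.n_clans * cfg.clan_size
        per_iter = cfg.n_clans * (cfg.clan_size + cfg.clan_size + 1)
        assert model.n_evaluations == pop + cfg.max_iterations * per_iter

    def test_determinism_under_fixed_seed(self):
        X, y = separable_data(n=50)
        cfg = TrainConfig(n_clans=2, clan_size=4, max_iterations=5, seed=3)
        m1 = train(X, y, cfg)
        m2 = train(X, y, cfg)
        np.testing.assert_array_equal(
            pack_genome(m1.params), pack_genome(m2.params)
        )
        assert m1.trace == m2.trace

    def test_learns_separable_data(self):
        X, y = separable_data(n=120, d=4, seed=5)
        cfg = TrainConfig(
            n_clans=5, clan_size=8, max_iterations=60, seed=5
        )
        results = EHGAClassifier(config=cfg).fit(X, y)
        assert results.train_accuracy >= 0.9

    def test_multiclass_one_hot_path(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 3, 90)
        X = np.column_stack([(y == c).astype(float) * 4 for c in range(3)])
        X = X + rng.normal(scale=0.3, size=X.shape)
        cfg = TrainConfig(n_clans=4, clan_size=6, max_iterations=80, seed=8)
        results = EHGAClassifier(hidden_layers=(8,), config=cfg).fit(X, y)
        assert results.train_accuracy >= 0.8
        assert set(results.predict(X)) <= {0, 1, 2}


class TestPredict:
    def test_consistency_with_training_accuracy(self):
        X, y = separable_data(n=80, seed=2)
        cfg = TrainConfig(n_clans=4, clan_size=6, max_iterations=40, seed=2)
        results = EHGAClassifier(config=cfg).fit(X, y)
        acc = np.mean(results.predict(X) == y)
        assert acc == pytest.approx(results.train_accuracy)

    def test_single_row_and_determinism(self):
        X, y = separable_data(n=40, seed=4)
        cfg = TrainConfig(n_clans=2, clan_size=4, max_iterations=10, seed=4)
        model = train(X, y, cfg)
        single = predict(model, X[0])
        assert single.shape == (1,)
        np.testing.assert_array_equal(
            predict(model, X), predict(model, X)
        )

    def test_dimension_mismatch_rejected(self):
        X, y = separable_data(n=40)
        cfg = TrainConfig(n_clans=2, clan_size=4, max_iterations=2, seed=0)
        model = train(X, y, cfg)
        with pytest.raises(ValidationError):
            predict(model, X[:, :2])


def test_model_persistence_round_trip(tmp_path):
    X, y = separable_data(n=40, seed=6)
    cfg = TrainConfig(n_clans=2, clan_size=4, max_iterations=5, seed=6)
    model = train(X, y, cfg)
    path = tmp_path / "model.txt"
    ehga.save_model(model, path)
    loaded = ehga.load_model(path)
    np.testing.assert_array_equal(
        pack_genome(loaded.params), pack_genome(model.params)
    )
    np.testing.assert_array_equal(predict(loaded, X), predict(model, X))


def test_summary_reports_architecture_and_loss():
    X, y = separable_data(n=40, seed=7)
    cfg = TrainConfig(n_clans=2, clan_size=4, max_iterations=5, seed=7)
    results = EHGAClassifier(hidden_layers=(6,), config=cfg).fit(X, y)
    text = results.summary()
    assert "4 -> 6 -> 1" in text
    assert "final MSE loss" in text
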