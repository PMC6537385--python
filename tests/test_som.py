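"""Mixed-data SOM: distances, BMU search, training dynamics, mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phenosom as ps
from phenosom.features import Layer, LayerSet
from phenosom.som import _all_distances, grid_coordinates

from conftest import random_encoded


class TestTanimoto:
    def test_identical_vectors_at_zero(self):
        assert ps.tanimoto_distance((0, 1, 0), (0, 1, 0)) == 0.0

    def test_disjoint_one_hot_at_one(self):
        assert ps.tanimoto_distance((1, 0, 0), (0, 1, 0)) == 1.0

    def test_partial_overlap(self):
        # 1 - 1/(2 + 2 - 1)
        assert ps.tanimoto_distance((1, 1, 0), (1, 0, 1)) == \
            pytest.approx(2 / 3, abs=1e-4)

    def test_both_zero_treated_as_identical(self):
        assert ps.tanimoto_distance((0, 0), (0, 0)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ps.InputError):
            ps.tanimoto_distance((1, 0), (1, 0, 0))

    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=25, deadline=None)
    def test_bounded_and_symmetric_on_indicators(self, seed):
        rng = np.random.default_rng(seed)
        a = (rng.random(5) < 0.5).astype(float)
        b = (rng.random(5) < 0.5).astype(float)
        d = ps.tanimoto_distance(a, b)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(ps.tanimoto_distance(b, a))


class TestNeighborhood:
    @pytest.mark.parametrize("kind", ["gaussian", "bubble"])
    def test_unity_at_zero_distance(self, kind):
        assert ps.neighborhood_weight(0.0, 1.5, kind) == 1.0

    def test_bubble_cutoff(self):
        assert ps.neighborhood_weight(2.0, 1.0, "bubble") == 0.0
        assert ps.neighborhood_weight(1.0, 1.0, "bubble") == 1.0

    def test_gaussian_at_one_radius(self):
        assert ps.neighborhood_weight(2.5, 2.5, "gaussian") == \
            pytest.approx(np.exp(-0.5), abs=1e-4)

    def test_zero_radius_gaussian_collapses_to_bmu(self):
        assert ps.neighborhood_weight(0.0, 0.0, "gaussian") == 1.0
        assert ps.neighborhood_weight(0.1, 0.0, "gaussian") == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ps.InputError):
            ps.neighborhood_weight(-1.0, 1.0)


def _random_layers(rng, sizes=(5, 2, 2, 3, 3)):
    layers, start = [], 0
    for i, s in enumerate(sizes):
        kind = "euclidean" if i == 0 else "tanimoto"
        layers.append(Layer(name=f"L{i}", columns=np.arange(start, start + s),
                            distance_kind=kind, weight=rng.uniform(0.5, 2)))
        start += s
    return LayerSet(layers=layers)


class TestCombinedDistance:
    def test_zero_for_identical_views(self):
        rng = np.random.default_rng(0)
        layers = _random_layers(rng)
        x = np.abs(rng.normal(size=15))
        views = {l.name: x[l.columns] for l in layers}
        assert ps.combined_distance(views, views, layers) == 0.0

    def test_single_euclidean_layer_reduces_to_scaled_sq_distance(self):
        layers = LayerSet([Layer("num", np.arange(4), "euclidean", 1.0)])
        a, b = np.arange(4.0), np.arange(4.0) + 2.0
        d = ps.combined_distance({"num": a}, {"num": b}, layers)
        assert d == pytest.approx(((a - b) ** 2).sum() / 4)

    def test_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(3)
        layers = _random_layers(rng)
        x = np.abs(rng.normal(size=15))
        w = np.abs(rng.normal(size=15))
        sv = {l.name: x[l.columns] for l in layers}
        cv = {l.name: w[l.columns] for l in layers}
        expected = 0.0
        for l in layers:  # independent summation oracle
            if l.distance_kind == "euclidean":
                d = float(((x[l.columns] - w[l.columns]) ** 2).sum())
            else:
                num = float(x[l.columns] @ w[l.columns])
                den = float(x[l.columns] @ x[l.columns]
                            + w[l.columns] @ w[l.columns]) - num
                d = 1 - num / den
            expected += l.weight * d / len(l.columns)
        assert ps.combined_distance(sv, cv, layers) == \
            pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        layers = LayerSet([Layer("num", np.arange(3), "euclidean", 1.0)])
        with pytest.raises(ps.InputError):
            ps.combined_distance({"num": np.zeros(2)}, {"num": np.zeros(3)},
                                 layers)


class TestBMU:
    def test_single_neuron_grid(self):
        rng = np.random.default_rng(0)
        enc = random_encoded(10, 3, rng)
        model = ps.train_som(enc, ps.SOMConfig(rows=1, cols=1,
                                               n_iterations=5, seed=0))
        assert ps.find_bmu(enc.values[0], model) == 0

    def test_planted_codebook_wins(self):
        rng = np.random.default_rng(1)
        enc = random_encoded(20, 4, rng)
        model = ps.train_som(enc, ps.SOMConfig(rows=3, cols=3,
                                               n_iterations=5, seed=1))
        x = rng.normal(size=4)
        model.codebooks["numerics"][7] = x
        model.codebooks["numerics"][:7] += 50
        model.codebooks["numerics"][8] += 50
        assert ps.find_bmu(x, model) == 7

    def test_matches_brute_force_scan(self, trained_model, encoded):
        rng = np.random.default_rng(2)
        queries = encoded.values[rng.integers(0, encoded.n_samples, 100)]
        for x in queries:
            d = _all_distances(x, trained_model.codebooks,
                               trained_model.layers)
            brute = min(range(trained_model.n_neurons),
                        key=lambda i: (d[i], i))
            assert ps.find_bmu(x, trained_model) == brute


class TestGrid:
    def test_default_config_has_105_neurons(self, trained_model):
        assert trained_model.n_neurons == 15 * 7
        assert trained_model.grid.shape == (105, 2)

    def test_hexagonal_geometry(self):
        g = grid_coordinates(3, 2, "hexagonal")
        assert g[0].tolist() == [0.0, 0.0]
        assert g[2].tolist() == [0.5, pytest.approx(np.sqrt(3) / 2)]
        assert g[4].tolist() == [0.0, pytest.approx(np.sqrt(3))]

    def test_rectangular_geometry(self):
        g = grid_coordinates(2, 3, "rectangular")
        assert g[4].tolist() == [1.0, 1.0]


class TestTraining:
    def test_single_point_dataset_attracts_all_codebooks(self):
        point = np.array([1.5, -2.0, 0.5])
        enc = ps.EncodedMatrix(values=np.tile(point, (20, 1)),
                               feature_names=["Za", "Zb", "Zc"],
                               sources=["a", "b", "c"],
                               kinds=["numeric"] * 3)
        model = ps.train_som(enc, ps.SOMConfig(rows=3, cols=2,
                                               n_iterations=2000, seed=0))
        assert np.abs(model.codebooks["numerics"] - point).max() < 1e-3
        assert model.history[-1] < 1e-3

    def test_two_clouds_converge_to_centroids(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.01, size=(40, 2))
        b = rng.normal(10, 0.01, size=(40, 2))
        X = np.vstack([a, b])
        enc = ps.EncodedMatrix(values=X, feature_names=["Zx", "Zy"],
                               sources=["x", "y"], kinds=["numeric"] * 2)
        cfg = ps.SOMConfig(rows=1, cols=2, n_iterations=4000,
                           radius_start=0.5, seed=0)
        model = ps.train_som(enc, cfg)
        W = model.codebooks["numerics"]
        cents = np.array([a.mean(axis=0), b.mean(axis=0)])
        for w in W:
            assert min(np.linalg.norm(w - c) for c in cents) < 0.1
        # one codebook per cloud
        assert {int(np.linalg.norm(w - cents[0]) <
                    np.linalg.norm(w - cents[1])) for w in W} == {0, 1}

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(6)
        enc = random_encoded(30, 4, rng)
        cfg = ps.SOMConfig(rows=3, cols=3, n_iterations=200, seed=42)
        m1 = ps.train_som(enc, cfg)
        m2 = ps.train_som(enc, cfg)
        np.testing.assert_array_equal(m1.codebook_matrix(),
                                      m2.codebook_matrix())
        np.testing.assert_array_equal(m1.history, m2.history)

    def test_codebooks_stay_in_data_hull(self):
        rng = np.random.default_rng(7)
        enc = random_encoded(50, 3, rng)
        model = ps.train_som(enc, ps.SOMConfig(rows=4, cols=4,
                                               n_iterations=1000, seed=7))
        lo = enc.values.min(axis=0) - 1e-9
        hi = enc.values.max(axis=0) + 1e-9
        W = model.codebooks["numerics"]
        assert (W >= lo).all() and (W <= hi).all()

    def test_permutation_equivariance_with_zero_radius(self):
        rng = np.random.default_rng(8)
        enc = random_encoded(40, 3, rng)
        cfg = ps.SOMConfig(rows=1, cols=4, n_iterations=300,
                           radius_start=0.0, radius_end=0.0, seed=3)
        init = rng.normal(size=(4, 3))
        perm = np.array([2, 0, 3, 1])
        m1 = ps.train_som(enc, cfg, init_codebooks=init)
        m2 = ps.train_som(enc, cfg, init_codebooks=init[perm])
        np.testing.assert_allclose(m2.codebook_matrix(),
                                   m1.codebook_matrix()[perm], atol=1e-12)

    def test_epoch_mode_runs_and_converges(self):
        rng = np.random.default_rng(9)
        enc = random_encoded(25, 3, rng)
        cfg = ps.SOMConfig(rows=2, cols=2, n_iterations=30,
                           iteration_mode="epoch", seed=1)
        model = ps.train_som(enc, cfg)
        assert model.history[-1] <= model.history[0]

    def test_empty_data_rejected(self):
        enc = ps.EncodedMatrix(values=np.empty((0, 3)),
                               feature_names=["a", "b", "c"],
                               sources=["a", "b", "c"],
                               kinds=["numeric"] * 3)
        with pytest.raises(ps.InputError):
            ps.train_som(enc, ps.SOMConfig(rows=2, cols=2, n_iterations=5))

    def test_invalid_config_rejected(self):
        with pytest.raises(ps.ConfigError):
            ps.SOMConfig(alpha_start=0.0).validate()
        with pytest.raises(ps.ConfigError):
            ps.SOMConfig(rows=0).validate()


class TestMapSamples:
    def test_identical_samples_win_single_neuron(self):
        enc = ps.EncodedMatrix(values=np.ones((12, 2)),
                               feature_names=["Za", "Zb"],
                               sources=["a", "b"], kinds=["numeric"] * 2)
        model = ps.train_som(enc, ps.SOMConfig(rows=2, cols=3,
                                               n_iterations=100, seed=0))
        bmus, dead, counts = ps.map_samples(model, enc)
        assert len(set(bmus)) == 1
        assert len(dead) == model.n_neurons - 1
        assert counts.sum() == 12

    def test_pigeonhole_dead_count(self):
        rng = np.random.default_rng(10)
        enc = random_encoded(4, 3, rng)
        model = ps.train_som(enc, ps.SOMConfig(rows=3, cols=3,
                                               n_iterations=50, seed=2))
        _, dead, _ = ps.map_samples(model, enc)
        assert len(dead) >= model.n_neurons - 4

    def test_assignments_match_per_sample_bmu(self, trained_model, encoded):
        bmus, dead, counts = ps.map_samples(trained_model, encoded)
        assert counts.sum() == encoded.n_samples
        assert set(bmus).isdisjoint(set(dead))
        rng = np.random.default_rng(11)
        for i in rng.integers(0, encoded.n_samples, 25):
            assert bmus[i] == ps.find_bmu(encoded.values[i], trained_model)


def test_model_save_load_round_trip(tmp_path, small_table):
    enc = ps.expand_dummies(small_table)
    model = ps.train_som(enc, ps.SOMConfig(rows=4, cols=3, n_iterations=300,
                                           seed=5))
    model.save(tmp_path / "model")
    back = ps.SOMModel.load(tmp_path / "model")
    np.testing.assert_allclose(back.codebook_matrix(),
                               model.codebook_matrix(), atol=1e-12)
    np.testing.assert_array_equal(back.bmu_of_sample, model.bmu_of_sample)
    assert back.config == model.config
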