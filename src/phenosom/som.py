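"""Online self-organizing map for mixed numeric/categorical layers.

The map is a 2-D lattice (hexagonal by default) of neurons, each carrying one
codebook vector per input layer.  Sample-to-neuron similarity is a weighted
sum of per-layer distances, each normalized by the layer's column count:
squared Euclidean distance for the numeric layer and Tanimoto distance
(continuously extended to real-valued codebooks) for each one-hot categorical
layer.  Training is the classic online rule: present one random sample,
find its best matching unit (BMU), and pull the BMU and its lattice
neighbours towards the sample with a linearly decaying learning rate and
neighbourhood radius.

Default geometry is a 15 x 7 hexagonal grid (105 neurons) trained for 5000
presentations with a Gaussian neighbourhood, alpha decaying linearly from
0.05 to 0.01 and the radius from the 2/3-quantile of neuron-pair grid
distances down to 0.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigError, InputError
from .features import EncodedMatrix, LayerSet, build_layers

_SQRT3_2 = np.sqrt(3.0) / 2.0


@dataclass
class SOMConfig:
    rows: int = 15
    cols: int = 7
    topology: str = "hexagonal"          # "hexagonal" | "rectangular"
    neighborhood: str = "gaussian"       # "gaussian" | "bubble"
    n_iterations: int = 5000
    alpha_start: float = 0.05
    alpha_end: float = 0.01
    radius_start: float | None = None    # default: 2/3-quantile of grid dists
    radius_end: float = 0.0
    seed: int = 0
    iteration_mode: str = "presentation"  # "presentation" | "epoch"

    def validate(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ConfigError("rows and cols must be >= 1")
        if not (0 < self.alpha_end <= self.alpha_start < 1):
            raise ConfigError("need 0 < alpha_end <= alpha_start < 1")
        if self.topology not in ("hexagonal", "rectangular"):
            raise ConfigError(f"unknown topology {self.topology!r}")
        if self.neighborhood not in ("gaussian", "bubble"):
            raise ConfigError(f"unknown neighborhood {self.neighborhood!r}")
        if self.iteration_mode not in ("presentation", "epoch"):
            raise ConfigError(f"unknown iteration_mode {self.iteration_mode!r}")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        if self.radius_start is not None and self.radius_end > self.radius_start:
            raise ConfigError("radius_end must be <= radius_start")


def grid_coordinates(rows: int, cols: int, topology: str = "hexagonal"
                     ) -> np.ndarray:
    """Planar neuron positions, row-major numbering.

    Hexagonal: odd rows offset by 0.5, row pitch sqrt(3)/2.
    """
    r, c = np.divmod(np.arange(rows * cols), cols)
    if topology == "hexagonal":
        x = c + 0.5 * (r % 2)
        y = r * _SQRT3_2
    elif topology == "rectangular":
        x, y = c.astype(float), r.astype(float)
    else:
        raise ConfigError(f"unknown topology {topology!r}")
    return np.column_stack([x, y]).astype(float)


def tanimoto_distance(a, b) -> float:
    """1 - a.b / (|a|^2 + |b|^2 - a.b); 0 for identical or both-zero vectors.

    Defined on indicator vectors but extends continuously to the real-valued
    codebooks the SOM maintains.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InputError("tanimoto_distance requires equal-length vectors")
    ab = float(a @ b)
    denom = float(a @ a) + float(b @ b) - ab
    if denom <= 0:
        return 0.0
    return 1.0 - ab / denom


def neighborhood_weight(grid_distance: float, radius: float,
                        kind: str = "gaussian") -> float:
    """Lattice neighbourhood kernel in [0, 1]; 1 at distance 0."""
    if grid_distance < 0 or radius < 0:
        raise InputError("grid_distance and radius must be >= 0")
    if kind == "bubble":
        return 1.0 if grid_distance <= radius else 0.0
    if kind == "gaussian":
        if radius == 0:
            return 1.0 if grid_distance == 0 else 0.0
        return float(np.exp(-grid_distance ** 2 / (2.0 * radius ** 2)))
    raise InputError(f"unknown neighborhood kind {kind!r}")


def _layer_distances_to_neurons(x: np.ndarray, W: np.ndarray,
                                kind: str) -> np.ndarray:
    """Distance from one sample view to every neuron's codebook view."""
    if kind == "euclidean":
        diff = W - x[None, :]
        return np.einsum("ij,ij->i", diff, diff)
    if kind == "tanimoto":
        ab = W @ x
        denom = np.einsum("ij,ij->i", W, W) + float(x @ x) - ab
        with np.errstate(divide="ignore", invalid="ignore"):
            d = 1.0 - ab / denom
        d[denom <= 1e-300] = 0.0
        return d
    raise InputError(f"unknown distance kind {kind!r}")


def combined_distance(sample_views, codebook_views, layers: LayerSet) -> float:
    """Sum over layers of weight * d_layer / n_columns_layer.

    ``sample_views`` / ``codebook_views`` map layer name -> vector.
    """
    total = 0.0
    for layer in layers:
        x = np.asarray(sample_views[layer.name], dtype=float)
        w = np.asarray(codebook_views[layer.name], dtype=float)
        if x.shape != w.shape or len(x) != len(layer.columns):
            raise InputError(f"layer {layer.name!r}: dimension mismatch")
        if layer.distance_kind == "euclidean":
            d = float(((x - w) ** 2).sum())
        else:
            d = tanimoto_distance(x, w)
        total += layer.weight * d / len(layer.columns)
    return total


@dataclass
class SOMModel:
    config: SOMConfig
    grid: np.ndarray                      # (n_neurons, 2) planar coordinates
    codebooks: dict[str, np.ndarray]      # layer name -> (n_neurons, d_layer)
    layers: LayerSet
    bmu_of_sample: np.ndarray             # 0-based neuron index per sample
    history: np.ndarray                   # mean presented-sample BMU distance

    @property
    def n_neurons(self) -> int:
        return self.grid.shape[0]

    def codebook_matrix(self) -> np.ndarray:
        """Concatenated per-layer codebooks, columns in encoded order."""
        d = sum(len(l.columns) for l in self.layers)
        out = np.empty((self.n_neurons, d))
        for layer in self.layers:
            out[:, layer.columns] = self.codebooks[layer.name]
        return out

    # --- persistence -----------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": asdict(self.config),
            "layers": self.layers.to_dict(),
            "grid": self.grid.tolist(),
            "history": self.history.tolist(),
            "bmu_of_sample": [int(b) for b in self.bmu_of_sample],
        }
        with open(directory / "model.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")
        for layer in self.layers:
            pd.DataFrame(self.codebooks[layer.name]).to_csv(
                directory / f"codebooks_{layer.name}.csv", index=False)

    @classmethod
    def load(cls, directory) -> "SOMModel":
        directory = Path(directory)
        with open(directory / "model.json") as fh:
            meta = json.load(fh)
        layers = LayerSet.from_dict(meta["layers"])
        codebooks = {
            l.name: pd.read_csv(directory / f"codebooks_{l.name}.csv"
                                ).to_numpy(dtype=float)
            for l in layers}
        return cls(config=SOMConfig(**meta["config"]),
                   grid=np.asarray(meta["grid"], dtype=float),
                   codebooks=codebooks, layers=layers,
                   bmu_of_sample=np.asarray(meta["bmu_of_sample"], dtype=int),
                   history=np.asarray(meta["history"], dtype=float))


def _all_distances(x: np.ndarray, model_codebooks: dict[str, np.ndarray],
                   layers: LayerSet) -> np.ndarray:
    n_neurons = next(iter(model_codebooks.values())).shape[0]
    total = np.zeros(n_neurons)
    for layer in layers:
        xl = x[layer.columns]
        d = _layer_distances_to_neurons(xl, model_codebooks[layer.name],
                                        layer.distance_kind)
        total += layer.weight * d / len(layer.columns)
    return total


def find_bmu(sample: np.ndarray, model: SOMModel,
             layers: LayerSet | None = None) -> int:
    """Index (0-based) of the neuron with minimal combined distance;
    ties broken by lowest index."""
    layers = layers or model.layers
    d = _all_distances(np.asarray(sample, dtype=float), model.codebooks, layers)
    return int(d.argmin())


def train_som(encoded: EncodedMatrix, config: SOMConfig | None = None,
              layers: LayerSet | None = None,
              init_codebooks: np.ndarray | None = None) -> SOMModel:
    """Train the online SOM.

    Initial codebooks are random training rows (pass ``init_codebooks`` to
    override).  Learning rate and radius decay linearly over the iteration
    count; in ``presentation`` mode one iteration presents one random sample,
    in ``epoch`` mode one iteration is a full shuffled pass.  The history
    records the mean presented-sample BMU distance over ~50 equal chunks of
    the run.  Deterministic for a fixed seed.
    """
    config = config or SOMConfig()
    config.validate()
    X = np.asarray(encoded.values, dtype=float)
    if X.size == 0:
        raise InputError("cannot train on empty data")
    layers = layers or build_layers(encoded)
    layers.validate(X.shape[1])
    n_samples = X.shape[0]
    n_neurons = config.rows * config.cols

    rng = np.random.default_rng(config.seed)
    grid = grid_coordinates(config.rows, config.cols, config.topology)
    grid_d = cdist(grid, grid)

    if config.radius_start is None:
        radius_start = (float(np.quantile(grid_d[np.triu_indices(n_neurons, 1)],
                                          2.0 / 3.0))
                        if n_neurons > 1 else 0.0)
    else:
        radius_start = float(config.radius_start)
    radius_end = float(config.radius_end)
    if radius_end > radius_start:
        radius_end = radius_start

    if init_codebooks is None:
        init_codebooks = X[rng.integers(0, n_samples, size=n_neurons)]
    else:
        init_codebooks = np.asarray(init_codebooks, dtype=float)
        if init_codebooks.shape != (n_neurons, X.shape[1]):
            raise InputError("init_codebooks has the wrong shape")
    codebooks = {l.name: init_codebooks[:, l.columns].copy() for l in layers}

    N = config.n_iterations
    if config.iteration_mode == "presentation":
        order = rng.integers(0, n_samples, size=N)
        step_of_presentation = np.arange(N)
        total_presentations = N
    else:
        order = np.concatenate(
            [rng.permutation(n_samples) for _ in range(N)])
        step_of_presentation = np.repeat(np.arange(N), n_samples)
        total_presentations = N * n_samples

    denom = max(N - 1, 1)
    alphas = config.alpha_start + (config.alpha_end - config.alpha_start) * (
        np.arange(N) / denom)
    radii = radius_start + (radius_end - radius_start) * (np.arange(N) / denom)

    n_chunks = min(50, total_presentations)
    chunk_of = (np.arange(total_presentations) * n_chunks
                ) // total_presentations
    chunk_sum = np.zeros(n_chunks)
    chunk_cnt = np.zeros(n_chunks)

    layer_list = [(l.name, l.columns, l.distance_kind,
                   l.weight / len(l.columns)) for l in layers]
    use_gaussian = config.neighborhood == "gaussian"

    for p in range(total_presentations):
        x = X[order[p]]
        step = step_of_presentation[p]
        alpha, radius = alphas[step], radii[step]

        total = np.zeros(n_neurons)
        for name, cols, kind, wnorm in layer_list:
            total += wnorm * _layer_distances_to_neurons(
                x[cols], codebooks[name], kind)
        bmu = int(total.argmin())
        chunk_sum[chunk_of[p]] += total[bmu]
        chunk_cnt[chunk_of[p]] += 1

        gd = grid_d[bmu]
        if use_gaussian:
            if radius > 0:
                h = np.exp(-gd ** 2 / (2.0 * radius ** 2))
            else:
                h = (gd == 0).astype(float)
        else:
            h = (gd <= radius).astype(float)
        ah = alpha * h
        active = ah > 1e-12
        for name, cols, _, _ in layer_list:
            W = codebooks[name]
            W[active] += ah[active, None] * (x[cols] - W[active])

    history = chunk_sum / np.maximum(chunk_cnt, 1)

    model = SOMModel(config=replace(config), grid=grid, codebooks=codebooks,
                     layers=layers, bmu_of_sample=np.zeros(0, dtype=int),
                     history=history)
    model.bmu_of_sample = _assign_bmus(X, model)
    return model


def _assign_bmus(X: np.ndarray, model: SOMModel) -> np.ndarray:
    total = np.zeros((X.shape[0], model.n_neurons))
    for layer in model.layers:
        Xl = X[:, layer.columns]
        W = model.codebooks[layer.name]
        if layer.distance_kind == "euclidean":
            d = cdist(Xl, W, metric="sqeuclidean")
        else:
            ab = Xl @ W.T
            denom = (np.einsum("ij,ij->i", Xl, Xl)[:, None]
                     + np.einsum("ij,ij->i", W, W)[None, :] - ab)
            with np.errstate(divide="ignore", invalid="ignore"):
                d = 1.0 - ab / denom
            d[denom <= 1e-300] = 0.0
        total += layer.weight * d / len(layer.columns)
    return total.argmin(axis=1)


def map_samples(model: SOMModel, encoded: EncodedMatrix
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """BMU assignment for every sample, the dead-neuron set and per-neuron
    sample counts.

    Dead neurons are neurons that win no sample.  Counts sum to the sample
    count.  Neuron indices are 0-based.
    """
    X = np.asarray(encoded.values, dtype=float)
    bmus = _assign_bmus(X, model)
    counts = np.bincount(bmus, minlength=model.n_neurons)
    dead = np.flatnonzero(counts == 0)
    return bmus, dead, counts
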