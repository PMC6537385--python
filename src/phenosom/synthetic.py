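"""Synthetic plot-level maize phenotype generator.

Emulates the plot-level output of a UAV high-throughput phenotyping campaign
on a natural maize population: per-plot final plant height and fresh biomass,
dichotomous flowering/lodging status, polytomous leaf color and genetic
background, and NDVI / BIOVP / AGRPH time series on a days-after-sowing (DAS)
grid.  Plots are drawn from a configurable number of planted clusters with
Gaussian numeric separation (``effect_size`` in within-cluster-sd units) and
per-cluster categorical profiles, so every downstream stage of the pipeline
can be exercised and scored against known ground truth.

Time series are built from smooth growth templates: logistic curves for the
plant-height and BIOVP trajectories and a concave-then-plateau saturation
curve for NDVI.  AGRPH (average growth rate of plant height) is derived from
the height trajectory as per-interval increments divided by interval length,
padded to the full five-point arity by repeating the first-interval rate.

The planted ground-truth label is emitted in a dedicated ``true_cluster``
column; it exists only for scoring and must never be fed to the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, SchemaError

# Declared level order of every categorical component (order fixes one-hot
# column order downstream).
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "IS_flowering": ("Y", "N"),
    "IS_lodging": ("Y", "N"),
    "tColor": ("green", "greenyellow", "darkgreen"),
    "tGBK": ("Mixed", "TEM", "TST"),
}

#: scalar numeric components (dy* are produced from the series downstream)
NUMERIC_COMPONENTS = ("finPH", "finBiomass", "dyNDVI", "dyBIOVP", "dyAGRPH")

#: time-series components and the number of DAS points each carries
SERIES_COMPONENTS = ("NDVI", "BIOVP", "AGRPH")

DEFAULT_DAS = (24, 45, 57, 78, 85)

# Base magnitudes of the growth templates (healthy mid-season maize).
_BASE_HEIGHT_CM = 260.0
_BASE_BIOMASS_KG_M2 = 5.5
_BASE_BIOVP = 4.5
_NDVI_FLOOR = 0.10
_NDVI_SPAN = 0.70


def _even_offsets(k: int) -> tuple[float, ...]:
    """Symmetric unit-spaced cluster offsets, e.g. k=3 -> (-1, 0, 1)."""
    return tuple(float(i) - (k - 1) / 2.0 for i in range(k))


def _uniform_profiles(k: int) -> dict[str, np.ndarray]:
    out = {}
    for comp, levels in CATEGORICAL_LEVELS.items():
        out[comp] = np.full((k, len(levels)), 1.0 / len(levels))
    return out


@dataclass
class GeneratorConfig:
    """Configuration for :func:`generate_population`.

    ``effect_size`` separates per-cluster numeric means in units of the
    within-cluster standard deviation; ``noise_sd`` is that within-cluster
    standard deviation expressed as a fraction of each component's base
    magnitude (a coefficient of variation), so the separation rule holds on
    every component's own scale.
    """

    n_plots: int = 482
    subpop_sizes: Mapping[str, int] | None = None  # exact tGBK counts
    n_true_clusters: int = 3
    cluster_proportions: Sequence[float] | None = None
    effect_size: float = 5.0
    noise_sd: float = 0.06
    das_points: Sequence[int] = DEFAULT_DAS
    categorical_profiles: Mapping[str, np.ndarray] | None = None
    numeric_offsets: Mapping[str, Sequence[float]] | None = None
    seed: int = 0

    def resolved_proportions(self) -> np.ndarray:
        if self.cluster_proportions is None:
            return np.full(self.n_true_clusters, 1.0 / self.n_true_clusters)
        return np.asarray(self.cluster_proportions, dtype=float)

    def resolved_profiles(self) -> dict[str, np.ndarray]:
        base = _uniform_profiles(self.n_true_clusters)
        if self.categorical_profiles:
            for comp, mat in self.categorical_profiles.items():
                base[comp] = np.asarray(mat, dtype=float)
        return base

    def resolved_offsets(self) -> dict[str, np.ndarray]:
        base = {c: np.array(_even_offsets(self.n_true_clusters))
                for c in NUMERIC_COMPONENTS}
        if self.numeric_offsets:
            for comp, off in self.numeric_offsets.items():
                base[comp] = np.asarray(off, dtype=float)
        return base

    def validate(self) -> None:
        if self.n_plots < 0:
            raise ConfigError("n_plots must be non-negative")
        if self.n_true_clusters < 1:
            raise ConfigError("n_true_clusters must be >= 1")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        props = self.resolved_proportions()
        if len(props) != self.n_true_clusters:
            raise ConfigError(
                "cluster_proportions length must equal n_true_clusters")
        if (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
            raise ConfigError("cluster_proportions must be non-negative and "
                              "sum to 1 within 1e-9")
        if self.subpop_sizes is not None:
            unknown = set(self.subpop_sizes) - set(CATEGORICAL_LEVELS["tGBK"])
            if unknown:
                raise ConfigError(f"subpop_sizes has unknown levels {unknown}")
            if sum(self.subpop_sizes.values()) != self.n_plots:
                raise ConfigError("subpop_sizes must sum to n_plots")
        das = np.asarray(self.das_points)
        if len(das) < 2 or (np.diff(das) <= 0).any():
            raise ConfigError("das_points must be strictly increasing")
        for comp, mat in self.resolved_profiles().items():
            if mat.shape != (self.n_true_clusters, len(CATEGORICAL_LEVELS[comp])):
                raise ConfigError(
                    f"categorical_profiles[{comp}] has wrong shape {mat.shape}")
            if (mat < 0).any() or np.abs(mat.sum(axis=1) - 1.0).max() > 1e-9:
                raise ConfigError(
                    f"categorical_profiles[{comp}] rows must be probability "
                    "vectors summing to 1 within 1e-9")
        for comp, off in self.resolved_offsets().items():
            if len(off) != self.n_true_clusters:
                raise ConfigError(
                    f"numeric_offsets[{comp}] length must equal n_true_clusters")

    # --- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "n_plots": self.n_plots,
            "subpop_sizes": dict(self.subpop_sizes) if self.subpop_sizes else None,
            "n_true_clusters": self.n_true_clusters,
            "cluster_proportions": (None if self.cluster_proportions is None
                                    else [float(p) for p in self.cluster_proportions]),
            "effect_size": self.effect_size,
            "noise_sd": self.noise_sd,
            "das_points": [int(d) for d in self.das_points],
            "categorical_profiles": (
                None if self.categorical_profiles is None else
                {c: np.asarray(m, dtype=float).tolist()
                 for c, m in self.categorical_profiles.items()}),
            "numeric_offsets": (
                None if self.numeric_offsets is None else
                {c: [float(v) for v in off]
                 for c, off in self.numeric_offsets.items()}),
            "seed": self.seed,
        }
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        return cls(**{k: v for k, v in d.items() if v is not None or
                      k in ("subpop_sizes", "cluster_proportions",
                            "categorical_profiles", "numeric_offsets")})

    @classmethod
    def from_yaml(cls, text: str) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

# Planted three-cluster pattern mirroring the field study's co-expression
# summary: cluster 1 carries every lodging plot and depressed numeric means;
# cluster 2 has (almost) no green-yellow leaves and the highest NDVI; cluster
# 3 is TST-dominated, entirely non-flowering, with elevated numeric means.
_PAPER_LIKE_PROFILES = {
    "IS_flowering": np.array([[0.80, 0.20],
                              [0.90, 0.10],
                              [0.00, 1.00]]),
    "IS_lodging": np.array([[0.50, 0.50],
                            [0.00, 1.00],
                            [0.00, 1.00]]),
    "tColor": np.array([[0.40, 0.35, 0.25],
                        [0.55, 0.00, 0.45],
                        [0.15, 0.75, 0.10]]),
    "tGBK": np.array([[0.30, 0.35, 0.35],
                      [0.25, 0.55, 0.20],
                      [0.05, 0.10, 0.85]]),
}

# NDVI peaks in cluster 2 (and stays flat in cluster 3), all other numerics
# rise monotonically from cluster 1 to cluster 3.
_PAPER_LIKE_OFFSETS = {
    "finPH": (-1.0, 0.0, 1.0),
    "finBiomass": (-1.0, 0.0, 1.0),
    "dyNDVI": (-1.0, 1.0, 0.0),
    "dyBIOVP": (-1.0, 0.0, 1.0),
    "dyAGRPH": (-1.0, 0.0, 1.0),
}

_PAPER_LIKE_PROPORTIONS = (201 / 482, 165 / 482, 116 / 482)


def _paper_like(seed: int) -> GeneratorConfig:
    return GeneratorConfig(
        n_plots=482,
        n_true_clusters=3,
        cluster_proportions=_PAPER_LIKE_PROPORTIONS,
        categorical_profiles=_PAPER_LIKE_PROFILES,
        numeric_offsets=_PAPER_LIKE_OFFSETS,
        seed=seed,
    )


def _natural_population_2017(seed: int) -> GeneratorConfig:
    return replace(
        _paper_like(seed),
        subpop_sizes={"Mixed": 106, "TEM": 162, "TST": 214},
    )


PRESETS = {
    "paper-like": _paper_like,
    "natural-population-2017": _natural_population_2017,
}


def preset_config(name: str, seed: int = 0, **overrides) -> GeneratorConfig:
    """Return a registered preset configuration, optionally overridden."""
    if name not in PRESETS:
        raise ConfigError(
            f"unknown preset {name!r}; known: {sorted(PRESETS)}")
    cfg = PRESETS[name](seed)
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# Phenotype table container
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Plot-level phenotype records in wide form.

    ``data`` holds one row per plot: identifier, categorical components,
    scalar numerics, flattened series columns (``NDVI_24`` ... ``AGRPH_85``)
    and, for synthetic tables, an oracle-only ``true_cluster`` column.
    ``series_das`` maps each series component to its DAS grid.
    """

    data: pd.DataFrame
    series_das: dict[str, tuple[int, ...]] = field(default_factory=dict)

    @property
    def n_plots(self) -> int:
        return len(self.data)

    def series(self, component: str) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(das, values)``; values is (n_plots, n_points)."""
        if component not in self.series_das:
            raise SchemaError(f"unknown series component {component!r}")
        das = np.asarray(self.series_das[component])
        cols = [f"{component}_{t}" for t in das]
        return das, self.data[cols].to_numpy(dtype=float)

    def validate(self) -> None:
        df = self.data
        for comp, levels in CATEGORICAL_LEVELS.items():
            bad = set(df[comp].unique()) - set(levels)
            if bad:
                raise SchemaError(
                    f"component {comp!r} has undeclared level(s) {sorted(bad)}")
        if len(df):
            if (df["finPH"].to_numpy(dtype=float) <= 0).any():
                raise SchemaError("finPH must be > 0")
            if (df["finBiomass"].to_numpy(dtype=float) < 0).any():
                raise SchemaError("finBiomass must be >= 0")
            das, ndvi = self.series("NDVI")
            if (np.abs(ndvi) > 1).any():
                raise SchemaError("NDVI values must lie in [-1, 1]")
        for comp, das in self.series_das.items():
            if (np.diff(das) <= 0).any():
                raise SchemaError(f"{comp} DAS grid must be strictly increasing")

    # --- I/O -------------------------------------------------------------
    def to_wide_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def to_long_csv(self, path) -> None:
        """Series in long form: plot_id, component, das, value."""
        rows = []
        for comp, das in self.series_das.items():
            for t in das:
                rows.append(pd.DataFrame({
                    "plot_id": self.data["plot_id"],
                    "component": comp,
                    "das": t,
                    "value": self.data[f"{comp}_{t}"],
                }))
        long = (pd.concat(rows, ignore_index=True)
                if rows else pd.DataFrame(
                    columns=["plot_id", "component", "das", "value"]))
        long.to_csv(path, index=False)

    @classmethod
    def from_wide_csv(cls, path) -> "PhenotypeTable":
        df = pd.read_csv(path)
        series_das: dict[str, tuple[int, ...]] = {}
        for comp in SERIES_COMPONENTS:
            ts = sorted(int(c.split("_", 1)[1]) for c in df.columns
                        if c.startswith(f"{comp}_"))
            if ts:
                series_das[comp] = tuple(ts)
        return cls(data=df, series_das=series_das)


def _empty_table(das_all, das_ndvi) -> PhenotypeTable:
    cols = ["plot_id", "tGBK", "tColor", "IS_flowering", "IS_lodging",
            "finPH", "finBiomass"]
    cols += [f"NDVI_{t}" for t in das_ndvi]
    cols += [f"BIOVP_{t}" for t in das_all]
    cols += [f"AGRPH_{t}" for t in das_all]
    cols += ["true_cluster"]
    return PhenotypeTable(
        data=pd.DataFrame(columns=cols),
        series_das={"NDVI": tuple(das_ndvi), "BIOVP": tuple(das_all),
                    "AGRPH": tuple(das_all)},
    )


# ---------------------------------------------------------------------------
# Growth templates
# ---------------------------------------------------------------------------

def _logistic(t: np.ndarray, amp: float, t_mid: float, tau: float) -> np.ndarray:
    return amp / (1.0 + np.exp(-(t - t_mid) / tau))


def _ndvi_template(t: np.ndarray, scale: float) -> np.ndarray:
    # concave rise to a plateau; scale perturbs the span only
    return _NDVI_FLOOR + _NDVI_SPAN * scale * (1.0 - np.exp(-(t - 12.0) / 30.0))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def separated_blobs(n_points: int, n_clusters: int, dim: int = 5,
                    separation: float = 8.0, within_sd: float = 1.0,
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Well-separated Gaussian point clouds (synthetic codebook sets).

    Cluster centers sit on the vertices of a regular simplex, so every pair
    of centers is exactly ``separation`` apart (unambiguous clouds for
    ``separation >> within_sd``); the simplex is randomly rotated per seed.
    Returns ``(points, labels)`` with labels 1..n_clusters; used to exercise
    the cluster-count voting and Ward recovery machinery.
    """
    if n_clusters < 1 or n_points < n_clusters:
        raise ConfigError("need n_points >= n_clusters >= 1")
    if dim < n_clusters - 1:
        raise ConfigError("dim must be >= n_clusters - 1 for a simplex")
    rng = np.random.default_rng(seed)
    # regular simplex: centered identity columns, all pairwise distances equal
    simplex = np.eye(n_clusters) - 1.0 / n_clusters
    simplex = simplex[:, :max(n_clusters - 1, 1)]
    pair = np.linalg.norm(simplex[0] - simplex[1]) if n_clusters > 1 else 1.0
    simplex *= separation / pair
    centers = np.zeros((n_clusters, dim))
    centers[:, :simplex.shape[1]] = simplex
    q, _ = np.linalg.qr(rng.normal(size=(dim, dim)))
    centers = centers @ q.T
    labels = np.concatenate([
        np.arange(n_clusters),                       # every cluster occupied
        rng.integers(0, n_clusters, n_points - n_clusters)])
    rng.shuffle(labels)
    points = centers[labels] + rng.normal(0.0, within_sd, (n_points, dim))
    return points, labels + 1


def generate_population(config: GeneratorConfig) -> PhenotypeTable:
    """Draw a synthetic plot-level phenotype table.

    Deterministic for a fixed ``config.seed``.  Numeric components are drawn
    from per-cluster Gaussian means separated by ``effect_size * noise_sd``
    (in relative units of each component's base magnitude); series come from
    smooth per-cluster growth templates plus observation noise; categoricals
    are drawn from the per-cluster profiles.  The planted label is recorded
    in ``true_cluster``.
    """
    config.validate()
    das_all = np.asarray(config.das_points, dtype=int)
    das_ndvi = das_all[:-1] if len(das_all) > 2 else das_all
    if config.n_plots == 0:
        return _empty_table(das_all, das_ndvi)

    rng = np.random.default_rng(config.seed)
    n = config.n_plots
    k = config.n_true_clusters
    props = config.resolved_proportions()
    profiles = config.resolved_profiles()
    offsets = config.resolved_offsets()
    gbk_levels = CATEGORICAL_LEVELS["tGBK"]

    if config.subpop_sizes is not None:
        # exact background composition; clusters drawn conditionally on it
        bg = np.repeat(
            np.arange(len(gbk_levels)),
            [config.subpop_sizes.get(l, 0) for l in gbk_levels])
        rng.shuffle(bg)
        post = profiles["tGBK"][:, bg] * props[:, None]  # (k, n)
        colsum = post.sum(axis=0)
        if (colsum <= 0).any():
            raise ConfigError(
                "subpop_sizes includes a background with zero probability "
                "under every cluster's tGBK profile")
        post /= colsum
        u = rng.random(n)
        clusters = (post.cumsum(axis=0) < u).sum(axis=0)
    else:
        clusters = rng.choice(k, size=n, p=props)
        u = rng.random(n)
        cum = profiles["tGBK"].cumsum(axis=1)
        bg = (cum[clusters] < u[:, None]).sum(axis=1)

    def draw_levels(comp: str) -> np.ndarray:
        cum = profiles[comp].cumsum(axis=1)
        u = rng.random(n)
        idx = (cum[clusters] < u[:, None]).sum(axis=1)
        return np.array(CATEGORICAL_LEVELS[comp])[idx]

    flowering = draw_levels("IS_flowering")
    lodging = draw_levels("IS_lodging")
    color = draw_levels("tColor")

    # per-plot multiplicative scale factors: N(1 + es*noise*offset_c, noise)
    def scales(comp: str) -> np.ndarray:
        mu = 1.0 + config.effect_size * config.noise_sd * offsets[comp][clusters]
        s = rng.normal(mu, config.noise_sd)
        return np.maximum(s, 0.05)

    s_ph = scales("finPH")
    s_bm = scales("finBiomass")
    s_nd = scales("dyNDVI")
    s_bv = scales("dyBIOVP")
    s_gr = scales("dyAGRPH")

    # height trajectory (cm) on the full DAS grid; AGRPH derives from it
    height = _logistic(das_all[None, :], _BASE_HEIGHT_CM, 55.0, 12.0)
    height = height * ((s_ph + s_gr) / 2.0)[:, None]
    height = height + rng.normal(0.0, 1.0, height.shape)
    height = np.maximum(height, 1.0)
    fin_ph = height[:, -1]

    dt = np.diff(das_all).astype(float)
    rates = np.diff(height, axis=1) / dt[None, :]
    agrph = np.concatenate([rates[:, :1], rates], axis=1)  # pad first rate

    biovp = _logistic(das_all[None, :], _BASE_BIOVP, 50.0, 10.0) * s_bv[:, None]
    biovp = np.maximum(biovp + rng.normal(0.0, 0.05, biovp.shape), 0.0)

    ndvi = _ndvi_template(das_ndvi[None, :].astype(float), s_nd[:, None])
    ndvi = np.clip(ndvi + rng.normal(0.0, 0.01, ndvi.shape), -1.0, 1.0)

    fin_bm = np.maximum(
        _BASE_BIOMASS_KG_M2 * s_bm + rng.normal(0.0, 0.05, n), 0.0)

    data = {
        "plot_id": [f"P{i + 1:04d}" for i in range(n)],
        "tGBK": np.array(gbk_levels)[bg],
        "tColor": color,
        "IS_flowering": flowering,
        "IS_lodging": lodging,
        "finPH": fin_ph,
        "finBiomass": fin_bm,
    }
    for j, t in enumerate(das_ndvi):
        data[f"NDVI_{t}"] = ndvi[:, j]
    for j, t in enumerate(das_all):
        data[f"BIOVP_{t}"] = biovp[:, j]
    for j, t in enumerate(das_all):
        data[f"AGRPH_{t}"] = agrph[:, j]
    data["true_cluster"] = clusters + 1

    table = PhenotypeTable(
        data=pd.DataFrame(data),
        series_das={"NDVI": tuple(int(t) for t in das_ndvi),
                    "BIOVP": tuple(int(t) for t in das_all),
                    "AGRPH": tuple(int(t) for t in das_all)},
    )
    table.validate()
    return table
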