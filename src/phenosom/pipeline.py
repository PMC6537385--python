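"""End-to-end preselection pipeline.

generate/load -> encode -> SOM -> two-step clustering -> profiling ->
biplot, with every artifact written as CSV/JSON into one output directory
and a run manifest recording seeds, the config hash and per-stage summaries.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biplot as biplot_mod
from . import clustering, features, profiling, synthetic
from .errors import ConfigError, InputError
from .som import SOMConfig, map_samples, train_som


@dataclass
class PipelineConfig:
    """Exactly one input source: a generator preset/config or a table CSV."""

    preset: str | None = "paper-like"
    generator: synthetic.GeneratorConfig | None = None
    table_csv: str | None = None
    som: SOMConfig = field(default_factory=SOMConfig)
    k: int | None = None                 # fixed k; None -> majority vote
    k_min: int = 2
    k_max: int = 6
    index_names: tuple[str, ...] = clustering.DEFAULT_INDICES
    tree_max_depth: int = 4
    tree_min_leaf: int = 5
    seed: int = 0
    out_dir: str = "phenosom-run"

    def validate(self) -> None:
        sources = [s is not None for s in
                   (self.preset, self.generator, self.table_csv)]
        if sum(sources) != 1:
            raise ConfigError(
                "exactly one input source (preset, generator or table_csv) "
                "must be set")
        if self.k is not None and self.k < 1:
            raise ConfigError("k must be >= 1")
        n_neurons = self.som.rows * self.som.cols
        if not (2 <= self.k_min < self.k_max <= max(n_neurons - 1, 3)):
            raise ConfigError("k range must satisfy 2 <= k_min < k_max "
                              "<= neuron count - 1")

    def to_dict(self) -> dict:
        d = {
            "preset": self.preset,
            "generator": (None if self.generator is None
                          else self.generator.to_dict()),
            "table_csv": self.table_csv,
            "som": asdict(self.som),
            "k": self.k, "k_min": self.k_min, "k_max": self.k_max,
            "index_names": list(self.index_names),
            "tree_max_depth": self.tree_max_depth,
            "tree_min_leaf": self.tree_min_leaf,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("generator") is not None:
            d["generator"] = synthetic.GeneratorConfig.from_dict(d["generator"])
        if d.get("som") is not None:
            d["som"] = SOMConfig(**d["som"])
        if d.get("index_names") is not None:
            d["index_names"] = tuple(d["index_names"])
        d.pop("out_dir", None)
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_table(config: PipelineConfig) -> synthetic.PhenotypeTable:
    if config.table_csv is not None:
        path = Path(config.table_csv)
        if not path.exists():
            raise InputError(f"input CSV not found: {path}")
        table = synthetic.PhenotypeTable.from_wide_csv(path)
        table.validate()
        return table
    if config.preset is not None:
        gen = synthetic.preset_config(config.preset, seed=config.seed)
    else:
        gen = replace(config.generator, seed=config.seed)
    return synthetic.generate_population(gen)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and return the run manifest.

    The manifest (also written to ``manifest.json``) records the config
    hash, every seed consumed, artifact paths (relative to the output
    directory) and per-stage summaries; the adjusted Rand index against
    planted labels is included whenever the input table carries them.
    """
    config.validate()
    table = _load_table(config)  # validate input before creating outputs
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "seeds": {"generator": config.seed, "som": config.som.seed},
        "artifacts": {},
        "stages": {},
    }

    def art(name: str, fname: str):
        manifest["artifacts"][name] = fname
        return out / fname

    table.to_wide_csv(art("population", "population.csv"))
    manifest["stages"]["input"] = {"n_plots": table.n_plots}

    encoded = features.expand_dummies(table)
    encoded.save(art("encoded", "encoded.csv"),
                 art("encoding_meta", "encoding.json"))
    layers = features.build_layers(encoded)
    manifest["stages"]["features"] = {
        "n_features": encoded.n_features,
        "n_layers": len(layers),
        "layer_names": [l.name for l in layers],
    }

    som_cfg = replace(config.som, seed=config.som.seed)
    model = train_som(encoded, som_cfg, layers)
    model.save(out / "som_model")
    manifest["artifacts"]["som_model"] = "som_model"
    bmus, dead, counts = map_samples(model, encoded)
    manifest["stages"]["som"] = {
        "n_neurons": model.n_neurons,
        "n_dead_neurons": int(len(dead)),
        "dead_neuron_percent": 100.0 * len(dead) / model.n_neurons,
        "history_first": float(model.history[0]),
        "history_last": float(model.history[-1]),
    }

    if config.k is None:
        voted_k, votes = clustering.vote_optimal_k(
            model, config.k_min, config.k_max, config.index_names)
        k = voted_k
    else:
        k, votes = config.k, {}
    solution = clustering.cluster_codebooks(model, k)
    solution.index_votes = votes or None
    sample_labels = clustering.assign_samples(solution, bmus)
    pd.DataFrame({
        "plot_id": table.data["plot_id"],
        "neuron": bmus + 1,  # 1-based, row-major neuron numbering
        "cluster": sample_labels,
    }).to_csv(art("assignments", "assignments.csv"), index=False)
    pd.DataFrame(sorted(votes.items()), columns=["index", "voted_k"]).to_csv(
        art("votes", "votes.csv"), index=False)
    pd.DataFrame(solution.merge_history,
                 columns=["node_a", "node_b", "height", "size"]).to_csv(
        art("merge_history", "merges.csv"), index=False)
    solution.summary().to_csv(art("cluster_sizes", "cluster_sizes.csv"),
                              index=False)
    cluster_stage = {
        "k": int(k), "votes": {i: int(v) for i, v in votes.items()},
        "neuron_sizes": solution.neuron_sizes,
        "sample_sizes": solution.sample_sizes,
    }
    if "true_cluster" in table.data.columns and table.n_plots:
        cluster_stage["ari_vs_planted"] = clustering.adjusted_rand_index(
            table.data["true_cluster"].to_numpy(), sample_labels)
    manifest["stages"]["clustering"] = cluster_stage

    numerics = features.numeric_components(table)
    profile = profiling.wilcoxon_profile(numerics, sample_labels)
    profile.table.to_csv(art("profile", "profile.csv"), index=False)
    profile.anova.to_csv(art("anova", "anova.csv"), index=False)
    inter_frames = []
    for comp in synthetic.CATEGORICAL_LEVELS:
        counts_df = profiling.intersection_counts(
            sample_labels, table.data[comp].astype(str))
        counts_df.insert(0, "component", comp)
        inter_frames.append(counts_df)
    pd.concat(inter_frames, ignore_index=True).to_csv(
        art("intersections", "intersections.csv"), index=False)
    tree = profiling.fit_rule_tree(
        encoded.to_dataframe(), sample_labels,
        max_depth=config.tree_max_depth, min_leaf=config.tree_min_leaf)
    (out / "tree.txt").write_text(tree.to_text() + "\n")
    manifest["artifacts"]["tree_text"] = "tree.txt"
    with open(art("tree_json", "tree.json"), "w") as fh:
        json.dump(tree.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["stages"]["profiling"] = {
        "n_significant_calls": int((profile.table["direction"] != "ns").sum()),
        "tree_accuracy": tree.resubstitution_accuracy,
        "tree_leaves": len(tree.leaves()),
    }

    result = biplot_mod.pca_fit(encoded)
    result.variance_table().to_csv(art("variance", "variance.csv"),
                                   index=False)
    pd.DataFrame(result.scores[:, :5],
                 columns=[f"PC{i + 1}" for i in range(min(5, result.n_pcs))]
                 ).assign(plot_id=table.data["plot_id"].values,
                          cluster=sample_labels).to_csv(
        art("scores", "scores.csv"), index=False)
    result.loadings_table().to_csv(art("loadings", "loadings_cos2.csv"),
                                   index=False)
    Z, names = biplot_mod.component_similarity(encoded)
    pd.DataFrame(Z, columns=["node_a", "node_b", "height", "size"]).to_csv(
        art("component_dendrogram", "component_dendrogram.csv"), index=False)
    manifest["stages"]["biplot"] = {
        "variance_percent_pc1": float(result.variance_explained[0]),
        "variance_percent_pc2": float(result.variance_explained[1]),
        "cumulative_percent_top5": float(
            result.cumulative[min(4, result.n_pcs - 1)]),
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    log_lines = [f"config_hash: {manifest['config_hash']}",
                 f"seeds: generator={config.seed} som={config.som.seed}"]
    for stage, info in manifest["stages"].items():
        log_lines.append(f"[{stage}] " + json.dumps(info, sort_keys=True,
                                                    default=float))
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return manifest
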