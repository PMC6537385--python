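"""Trait feature encoding.

Turns a plot-level phenotype table into the standardized, dummy-expanded,
layered matrix the mixed-data SOM consumes:

* each time-series component is collapsed to a scalar by the area under its
  polyline over the DAS axis (trapezoid rule), giving ``dyNDVI``, ``dyBIOVP``
  and ``dyAGRPH``;
* the five scalar numerics are z-standardized (sample sd, prefixed ``Z``);
* each categorical component is expanded to a full one-hot block (no
  reference level is dropped), in declared level order;
* columns are organized into SOM layers: one Euclidean layer holding all
  numerics and one Tanimoto layer per source categorical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateError, InputError, SchemaError
from .synthetic import (CATEGORICAL_LEVELS, NUMERIC_COMPONENTS,
                        SERIES_COMPONENTS, PhenotypeTable)


def polyline_area(times: Sequence[float], values: Sequence[float]) -> float:
    """Trapezoidal area under the piecewise-linear curve value(time).

    Units are value x days.  Requires >= 2 points and strictly increasing
    times.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise InputError("times and values must be 1-D of equal length")
    if len(t) < 2:
        raise InputError("polyline_area needs at least 2 points")
    if (np.diff(t) <= 0).any():
        raise InputError("times must be strictly increasing")
    return float(np.trapezoid(v, t))


def standardize(values: Sequence[float]) -> np.ndarray:
    """z-scores with the sample (n-1) standard deviation.

    Raises :class:`DegenerateError` for constant input.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise InputError("standardize needs a 1-D array of >= 2 values")
    sd = x.std(ddof=1)
    if sd <= 0 or not np.isfinite(sd):
        raise DegenerateError("cannot standardize a constant input")
    return (x - x.mean()) / sd


@dataclass
class EncodedMatrix:
    """Plots x features matrix with provenance metadata.

    ``kinds[j]`` is ``"numeric"`` for standardized numeric columns and the
    categorical level name for one-hot columns; ``sources[j]`` names the
    originating phenotypic component.
    """

    values: np.ndarray
    feature_names: list[str]
    sources: list[str]
    kinds: list[str]
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    plot_ids: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        if self.plot_ids:
            df.insert(0, "plot_id", self.plot_ids)
        return df

    def save(self, csv_path, sidecar_path) -> None:
        self.to_dataframe().to_csv(csv_path, index=False)
        meta = {
            "feature_names": self.feature_names,
            "sources": self.sources,
            "kinds": self.kinds,
            "means": self.means,
            "sds": self.sds,
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, csv_path, sidecar_path) -> "EncodedMatrix":
        df = pd.read_csv(csv_path)
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        plot_ids = (df["plot_id"].astype(str).tolist()
                    if "plot_id" in df.columns else [])
        vals = df[meta["feature_names"]].to_numpy(dtype=float)
        return cls(values=vals, feature_names=meta["feature_names"],
                   sources=meta["sources"], kinds=meta["kinds"],
                   means=meta["means"], sds=meta["sds"], plot_ids=plot_ids)


@dataclass
class Layer:
    name: str
    columns: np.ndarray  # indices into the EncodedMatrix
    distance_kind: str   # "euclidean" | "tanimoto"
    weight: float = 1.0


@dataclass
class LayerSet:
    layers: list[Layer]

    def __iter__(self):
        return iter(self.layers)

    def __len__(self):
        return len(self.layers)

    def validate(self, n_features: int) -> None:
        seen: list[int] = []
        for layer in self.layers:
            if layer.weight < 0:
                raise InputError(f"layer {layer.name!r} has negative weight")
            seen.extend(int(c) for c in layer.columns)
        if sorted(seen) != list(range(n_features)):
            raise InputError("layers must partition the encoded columns")

    def to_dict(self) -> dict:
        return {"layers": [
            {"name": l.name, "columns": [int(c) for c in l.columns],
             "distance_kind": l.distance_kind, "weight": l.weight}
            for l in self.layers]}

    @classmethod
    def from_dict(cls, d: dict) -> "LayerSet":
        return cls(layers=[
            Layer(name=e["name"], columns=np.asarray(e["columns"], dtype=int),
                  distance_kind=e["distance_kind"], weight=e["weight"])
            for e in d["layers"]])


def numeric_components(table: PhenotypeTable) -> pd.DataFrame:
    """Raw (unstandardized) scalar numerics, dy* computed by polyline area."""
    df = table.data
    out = pd.DataFrame({"plot_id": df["plot_id"]})
    out["finPH"] = df["finPH"].astype(float)
    out["finBiomass"] = df["finBiomass"].astype(float)
    for comp in SERIES_COMPONENTS:
        das, vals = table.series(comp)
        out[f"dy{comp}"] = [polyline_area(das, row) for row in vals]
    return out


def expand_dummies(table: PhenotypeTable) -> EncodedMatrix:
    """Standardize numerics and one-hot-expand categoricals.

    For the standard schema (5 numerics + two 2-level + two 3-level
    categoricals) this yields 15 feature columns.
    """
    df = table.data
    if len(df) < 2:
        raise InputError("need at least 2 plots to standardize")
    numerics = numeric_components(table)

    cols: list[np.ndarray] = []
    names: list[str] = []
    sources: list[str] = []
    kinds: list[str] = []
    means: dict[str, float] = {}
    sds: dict[str, float] = {}

    for comp in NUMERIC_COMPONENTS:
        raw = numerics[comp].to_numpy(dtype=float)
        means[comp] = float(raw.mean())
        sds[comp] = float(raw.std(ddof=1))
        cols.append(standardize(raw))
        names.append(f"Z{comp}")
        sources.append(comp)
        kinds.append("numeric")

    for comp, levels in CATEGORICAL_LEVELS.items():
        if comp not in df.columns:
            continue
        observed = df[comp].astype(str).to_numpy()
        bad = set(observed) - set(levels)
        if bad:
            raise SchemaError(
                f"component {comp!r} has undeclared level(s) {sorted(bad)}")
        for level in levels:
            cols.append((observed == level).astype(float))
            names.append(f"{comp}.{level}")
            sources.append(comp)
            kinds.append(level)

    return EncodedMatrix(
        values=np.column_stack(cols),
        feature_names=names, sources=sources, kinds=kinds,
        means=means, sds=sds,
        plot_ids=df["plot_id"].astype(str).tolist(),
    )


def decode_categoricals(encoded: EncodedMatrix) -> pd.DataFrame:
    """Invert the one-hot expansion (round-trip check for the encoding)."""
    out = {}
    for comp in dict.fromkeys(encoded.sources):
        idx = [j for j, s in enumerate(encoded.sources)
               if s == comp and encoded.kinds[j] != "numeric"]
        if not idx:
            continue
        levels = [encoded.kinds[j] for j in idx]
        block = encoded.values[:, idx]
        out[comp] = [levels[int(r)] for r in block.argmax(axis=1)]
    return pd.DataFrame(out)


def build_layers(encoded: EncodedMatrix, weights: dict[str, float] | None = None
                 ) -> LayerSet:
    """One Euclidean layer for all numerics, one Tanimoto layer per
    source categorical; default weights are equal (1.0)."""
    if encoded.n_features == 0 or encoded.n_samples == 0:
        raise InputError("cannot build layers from an empty matrix")
    weights = weights or {}
    layers: list[Layer] = []
    num_idx = [j for j, k in enumerate(encoded.kinds) if k == "numeric"]
    if num_idx:
        layers.append(Layer(name="numerics",
                            columns=np.asarray(num_idx, dtype=int),
                            distance_kind="euclidean",
                            weight=weights.get("numerics", 1.0)))
    for comp in dict.fromkeys(encoded.sources):
        idx = [j for j, (s, k) in enumerate(zip(encoded.sources, encoded.kinds))
               if s == comp and k != "numeric"]
        if idx:
            layers.append(Layer(name=comp,
                                columns=np.asarray(idx, dtype=int),
                                distance_kind="tanimoto",
                                weight=weights.get(comp, 1.0)))
    ls = LayerSet(layers=layers)
    ls.validate(encoded.n_features)
    return ls
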