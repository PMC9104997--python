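"""Dataset and prediction file handling, run configuration, logging.

Datasets are CSV files with header ``smiles,logEC50`` (the label column is
optional for query files).  Prediction output carries the posterior mean,
latent and predictive standard deviations, a Gaussian 95% interval
(mean +- 1.96 predictive_sd) and, when requested, posterior sample
columns.  A flat key-value run configuration with a content hash makes
every pipeline run reproducible and self-describing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .chem import MoleculeRecord, parse_molecule, SmilesParseError
from .dkl import GridConfig, NetworkConfig, PredictiveDistribution

__all__ = ["RunConfig", "read_dataset", "write_predictions", "DatasetError"]

logger = logging.getLogger("iltox")

# Hyperparameter search ranges explored upstream of the defaults below;
# recorded as metadata only, no search is performed by this package.
SEARCH_RANGES = {
    "grid_size": (16, 100),
    "learning_rate": (1e-5, 3e-1),
    "optimizer": ("sgd", "rmsprop", "adam"),
    "dnn_layers": (2, 7),
    "units_per_layer": (32, 512),
    "activation": ("relu", "leaky_relu", "tanh"),
}


class DatasetError(ValueError):
    """Raised for malformed dataset files (bad header, bad rows)."""


@dataclass
class RunConfig:
    """Flat, hashable run configuration; defaults are the tuned optimum
    (RBF base kernel, grid 35/dim, RMSprop at 0.0130925, five network
    layers of 163 units into a 2-unit latent, LeakyReLU)."""

    layer_sizes: tuple[int, ...] = (310, 163, 163, 163, 163, 2)
    activation: str = "leaky_relu"
    grid_size: int = 35
    optimizer: str = "rmsprop"
    learning_rate: float = 0.0130925
    n_iter: int = 1000
    covariance: str = "ski"
    seed: int = 42
    split_seed: int = 42
    n_test: int = 15
    k_folds: int = 5
    embedding_dim: int = 300
    corpus_size: int = 500
    min_count: int = 1

    def network(self) -> NetworkConfig:
        return NetworkConfig(layer_sizes=tuple(self.layer_sizes),
                             activation=self.activation)

    def grid(self) -> GridConfig:
        return GridConfig(points_per_dim=self.grid_size)

    def fit_kwargs(self) -> dict:
        return {"optimizer": self.optimizer, "learning_rate": self.learning_rate,
                "n_iter": self.n_iter, "seed": self.seed,
                "covariance": self.covariance}

    @property
    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DatasetError(f"unknown config keys: {sorted(unknown)}")
        if "layer_sizes" in raw:
            raw["layer_sizes"] = tuple(raw["layer_sizes"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["layer_sizes"] = list(data["layer_sizes"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def read_dataset(path: str | Path, require_label: bool = False) -> list[MoleculeRecord]:
    """Read a ``smiles[,logEC50]`` CSV into parsed molecule records.

    SMILES are parsed eagerly; unparseable rows are collected and reported
    together with their (1-based, header-exclusive) row numbers.  Duplicate
    SMILES trigger a warning; the first occurrence is kept.
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "smiles" not in cols:
        raise DatasetError(f"{path}: missing required column 'smiles'")
    has_label = "logec50" in cols
    if require_label and not has_label:
        raise DatasetError(f"{path}: missing required column 'logEC50'")

    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    bad_rows: list[str] = []
    n_dup = 0
    for i, row in df.iterrows():
        smiles = str(row[cols["smiles"]]).strip()
        label = None
        if has_label and not pd.isna(row[cols["logec50"]]):
            label = float(row[cols["logec50"]])
        if require_label and label is None:
            bad_rows.append(f"row {i + 1}: missing logEC50")
            continue
        try:
            rec = parse_molecule(smiles, label=label)
        except SmilesParseError:
            bad_rows.append(f"row {i + 1}: unparseable SMILES {smiles!r}")
            continue
        if rec.canonical_smiles in seen:
            n_dup += 1
            continue
        seen.add(rec.canonical_smiles)
        records.append(rec)
    if bad_rows:
        raise DatasetError(f"{path}: " + "; ".join(bad_rows))
    if n_dup:
        warnings.warn(f"{path}: dropped {n_dup} duplicate SMILES (kept first)",
                      stacklevel=2)
    return records


def write_predictions(path: str | Path, smiles: Sequence[str],
                      dist: PredictiveDistribution,
                      ad_statuses: Optional[Sequence] = None) -> pd.DataFrame:
    """Write a prediction CSV; returns the frame that was written.

    Columns: smiles, mean, latent_sd, predictive_sd, lower95, upper95
    (mean +- 1.96 predictive_sd), ad_classification (blank when no AD
    analysis was run) and sample_1..sample_k when the distribution carries
    posterior draws.  Values are written with 6 significant digits.
    """
    n = len(smiles)
    if dist.mean.size != n:
        raise ValueError("SMILES list and predictions differ in length")
    if ad_statuses is not None and len(ad_statuses) != n:
        raise ValueError("AD statuses and predictions differ in length")
    frame = pd.DataFrame({
        "smiles": list(smiles),
        "mean": dist.mean,
        "latent_sd": dist.latent_sd,
        "predictive_sd": dist.predictive_sd,
        "lower95": dist.mean - 1.96 * dist.predictive_sd,
        "upper95": dist.mean + 1.96 * dist.predictive_sd,
        "ad_classification": ([s.classification for s in ad_statuses]
                              if ad_statuses is not None else [""] * n),
    })
    if dist.samples is not None:
        for j in range(dist.samples.shape[0]):
            frame[f"sample_{j + 1}"] = dist.samples[j]
    frame.to_csv(path, index=False, float_format="%.6g")
    return frame


@contextmanager
def log_stage(name: str, **info):
    """One structured log line per pipeline stage, with wall time."""
    t0 = time.perf_counter()
    yield
    dt = time.perf_counter() - t0
    extra = " ".join(f"{k}={v}" for k, v in info.items())
    logger.info("stage=%s wall_s=%.2f %s", name, dt, extra)
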