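"""Study workflow: dataset split, five-fold CV, metrics, evaluation.

The workflow mirrors the standard QSAR protocol: a random train/test split
(140/15 for a 155-record dataset), five-fold cross-validation on the
training portion with a representative model chosen by validation RMSE,
and final evaluation of that model on the held-out test set.

Metrics: MSE, RMSE, R^2 (about the mean of the measured values) and the
average absolute relative deviation AARD = mean |pred - exp| / |exp|,
reported both as a fraction and as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chem import MoleculeRecord, featurize_records
from .dkl import (DeepKernelGP, DeepKernelGPResults, GridConfig, NetworkConfig,
                  PredictiveDistribution)

__all__ = [
    "DatasetSplit",
    "CVResult",
    "MetricsReport",
    "split_dataset",
    "make_folds",
    "cross_validate",
    "compute_metrics",
    "evaluate",
]


@dataclass
class DatasetSplit:
    train: list
    test: list
    seed: int


@dataclass
class MetricsReport:
    """Regression metrics on n predictions."""

    mse: float
    rmse: float
    r2: float
    aard: float
    n: int

    @property
    def aard_percent(self) -> float:
        return 100.0 * self.aard

    def as_dict(self) -> dict:
        return {"n": self.n, "mse": self.mse, "rmse": self.rmse,
                "r2": self.r2, "aard_percent": self.aard_percent}


@dataclass
class CVResult:
    """Per-fold models and metrics plus the representative-model choice."""

    fold_assignments: np.ndarray          # fold index (0-based) per record
    fold_reports: list[MetricsReport]     # validation metrics per fold
    selected_fold: int
    selected_model: DeepKernelGPResults
    models: list[DeepKernelGPResults]
    pooled_predictions: np.ndarray        # out-of-fold prediction per record
    pooled_report: MetricsReport


def split_dataset(records: Sequence, n_test: int = 15, seed: int = 42) -> DatasetSplit:
    """Uniform random train/test split without replacement, seeded."""
    records = list(records)
    if n_test >= len(records):
        raise ValueError(
            f"n_test={n_test} must be smaller than the dataset ({len(records)})")
    rng = np.random.default_rng(seed)
    test_idx = set(rng.choice(len(records), size=n_test, replace=False).tolist())
    train = [r for i, r in enumerate(records) if i not in test_idx]
    test = [r for i, r in enumerate(records) if i in test_idx]
    return DatasetSplit(train=train, test=test, seed=seed)


def make_folds(n_or_records, k: int = 5, seed: int = 42) -> np.ndarray:
    """Balanced random k-fold assignment; fold sizes differ by at most 1."""
    n = n_or_records if isinstance(n_or_records, int) else len(n_or_records)
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} records")
    rng = np.random.default_rng(seed)
    base = np.arange(n) % k        # balanced fold sizes
    return base[rng.permutation(n)]


def compute_metrics(y_exp: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """MSE, RMSE, R^2 and AARD between measured and predicted values."""
    y_exp = np.asarray(y_exp, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_exp.size != y_pred.size:
        raise ValueError("measured and predicted vectors differ in length")
    if y_exp.size < 2:
        raise ValueError("need at least 2 observations for metrics")
    if np.any(y_exp == 0):
        raise ValueError("AARD is undefined when a measured value is exactly 0")
    resid = y_pred - y_exp
    mse = float(np.mean(resid ** 2))
    tss = float(np.sum((y_exp - y_exp.mean()) ** 2))
    if tss == 0:
        raise ValueError("R^2 is undefined for constant measured values")
    return MetricsReport(
        mse=mse,
        rmse=float(np.sqrt(mse)),
        r2=1.0 - float(np.sum(resid ** 2)) / tss,
        aard=float(np.mean(np.abs(resid) / np.abs(y_exp))),
        n=y_exp.size,
    )


def _fit_one(x, y, network, grid, fit_kwargs) -> DeepKernelGPResults:
    model = DeepKernelGP(y, x, network=network, grid=grid)
    return model.fit(**fit_kwargs)


def cross_validate(x: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 42,
                   network: Optional[NetworkConfig] = NetworkConfig(),
                   grid: GridConfig = GridConfig(),
                   folds: Optional[np.ndarray] = None,
                   **fit_kwargs) -> CVResult:
    """Five-fold CV with representative-model selection.

    One model is trained per fold (that fold held out for validation); the
    representative model is the one with the lowest validation RMSE, ties
    broken toward the lower fold index.  Pooled out-of-fold predictions
    cover every training record exactly once and give the "train + valid"
    metrics of the workflow.  ``folds`` overrides the seeded random fold
    assignment with an explicit one (0-based fold index per record).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if folds is None:
        folds = make_folds(y.size, k=k, seed=seed)
    else:
        folds = np.asarray(folds, dtype=int)
        if folds.size != y.size:
            raise ValueError("fold assignment length does not match the data")
    fit_kwargs.setdefault("seed", seed)

    models, reports = [], []
    pooled = np.empty_like(y)
    for fold in range(k):
        val = folds == fold
        try:
            res = _fit_one(x[~val], y[~val], network, grid, fit_kwargs)
        except Exception as exc:                       # noqa: BLE001
            raise RuntimeError(f"model fit failed on fold {fold + 1}: {exc}") from exc
        pred = res.predict(x[val])
        pooled[val] = pred.mean
        models.append(res)
        reports.append(compute_metrics(y[val], pred.mean))

    rmses = [r.rmse for r in reports]
    selected = int(np.argmin(rmses))  # argmin takes the first minimum: low fold wins ties
    return CVResult(
        fold_assignments=folds,
        fold_reports=reports,
        selected_fold=selected,
        selected_model=models[selected],
        models=models,
        pooled_predictions=pooled,
        pooled_report=compute_metrics(y, pooled),
    )


def evaluate(results: DeepKernelGPResults,
             records: Sequence[MoleculeRecord],
             embedding_model,
             n_samples: Optional[int] = None,
             seed: int = 0) -> tuple[MetricsReport, PredictiveDistribution]:
    """Featurize labeled records, predict, and score the predictions."""
    labels = [r.label for r in records]
    if any(lab is None for lab in labels):
        missing = [r.source_smiles for r in records if r.label is None][:3]
        raise ValueError(f"evaluation needs labeled records; unlabeled: {missing}")
    x = featurize_records(records, embedding_model)
    dist = results.predict(x, samples=n_samples, seed=seed)
    report = compute_metrics(np.array(labels, dtype=float), dist.mean)
    return report, dist
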