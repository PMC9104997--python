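"""Applicability-domain analysis by the standardization technique.

Each feature column is z-scored with the mean and sample standard
deviation of the *training* set only.  A record whose largest absolute
standardized value exceeds 3.0 is called an *outlier* when it belongs to
the training set and *outside the applicability domain (AD)* when it is a
test/query record — the premise being that ~99.7% of a well-behaved
population lies within mean +- 3 SD per column.

By default the analysis runs over all feature columns the model consumes
(the 10 descriptors plus the 300 embedding dimensions when given the full
feature matrix); pass the descriptor column indices to restrict it to the
named descriptors for interpretability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ADStandardizer",
    "ADStatus",
    "fit_standardizer",
    "assess",
    "assess_matrix",
    "max_abs_scores",
    "ad_coverage",
    "plot_distribution_map",
]

logger = logging.getLogger(__name__)

THRESHOLD_DEFAULT = 3.0


@dataclass
class ADStandardizer:
    """Training-set column statistics for AD z-scoring."""

    mean: np.ndarray
    sd: np.ndarray                      # sample sd, n-1 denominator
    threshold: float = THRESHOLD_DEFAULT
    columns_used: np.ndarray = field(default=None)  # indices with sd > 0

    @property
    def n_features(self) -> int:
        return self.mean.size


@dataclass
class ADStatus:
    """Classification of one record against the applicability domain."""

    record_id: str
    max_abs_z: float
    role: str                           # "train" or "test"
    classification: str                 # "within" / "outlier" / "outside_ad"


def fit_standardizer(train_features: np.ndarray,
                     threshold: float = THRESHOLD_DEFAULT,
                     columns: Optional[Sequence[int]] = None) -> ADStandardizer:
    """Column means and sample standard deviations of the training matrix.

    Zero-variance columns cannot be standardized; they are excluded from
    classification (logged as a warning).  ``columns`` optionally restricts
    the analysis to a subset (e.g. the 10 named descriptors).
    """
    x = np.atleast_2d(np.asarray(train_features, dtype=float))
    if x.shape[0] < 2:
        raise ValueError("need at least 2 training rows to fit AD statistics")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    usable = sd > 0
    if columns is not None:
        mask = np.zeros(x.shape[1], dtype=bool)
        mask[list(columns)] = True
        usable &= mask
    n_zero = int((sd == 0).sum())
    if n_zero:
        logger.warning("excluding %d zero-variance column(s) from the AD analysis",
                       n_zero)
    return ADStandardizer(mean=mean, sd=sd, threshold=threshold,
                          columns_used=np.flatnonzero(usable))


def max_abs_scores(features: np.ndarray, standardizer: ADStandardizer) -> np.ndarray:
    """Max over used columns of |x - mean| / sd, per row (vectorized)."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != standardizer.n_features:
        raise ValueError(
            f"records have {x.shape[1]} features, standardizer expects "
            f"{standardizer.n_features}")
    cols = standardizer.columns_used
    if cols.size == 0:
        return np.zeros(x.shape[0])
    z = np.abs(x[:, cols] - standardizer.mean[cols]) / standardizer.sd[cols]
    return z.max(axis=1)


def assess(features: np.ndarray, standardizer: ADStandardizer,
           role: str, record_id: str = "") -> ADStatus:
    """Classify one record: within AD, training outlier, or outside AD.

    The statistic is max over used columns of |x - mean| / sd; the record
    is flagged only when it exceeds the threshold strictly.
    """
    if role not in ("train", "test"):
        raise ValueError("role must be 'train' or 'test'")
    max_abs_z = float(max_abs_scores(np.asarray(features).reshape(1, -1),
                                     standardizer)[0])
    if max_abs_z > standardizer.threshold:
        classification = "outlier" if role == "train" else "outside_ad"
    else:
        classification = "within"
    return ADStatus(record_id=record_id, max_abs_z=max_abs_z, role=role,
                    classification=classification)


def assess_matrix(features: np.ndarray, standardizer: ADStandardizer,
                  role: str, ids: Optional[Sequence[str]] = None) -> list[ADStatus]:
    """Vector version of :func:`assess` over the rows of a feature matrix."""
    if role not in ("train", "test"):
        raise ValueError("role must be 'train' or 'test'")
    x = np.atleast_2d(np.asarray(features, dtype=float))
    ids = ids if ids is not None else [str(i) for i in range(x.shape[0])]
    scores = max_abs_scores(x, standardizer)
    flagged = "outlier" if role == "train" else "outside_ad"
    return [ADStatus(record_id=ids[i], max_abs_z=float(s), role=role,
                     classification=flagged if s > standardizer.threshold
                     else "within")
            for i, s in enumerate(scores)]


def ad_coverage(statuses: Sequence[ADStatus]) -> dict[str, float]:
    """Percentage of records within the AD, per role, to one decimal."""
    if not statuses:
        raise ValueError("cannot compute coverage of an empty status list")
    out: dict[str, float] = {}
    for role in sorted({s.role for s in statuses}):
        group = [s for s in statuses if s.role == role]
        within = sum(s.classification == "within" for s in group)
        out[role] = round(100.0 * within / len(group), 1)
    return out


def plot_distribution_map(statuses: Sequence[ADStatus], path=None, ax=None):
    """Record index vs max |z| with the threshold line (AD distribution map)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    markers = {"train": "o", "test": "s"}
    for role in sorted({s.role for s in statuses}):
        pts = [(i, s.max_abs_z) for i, s in enumerate(statuses) if s.role == role]
        ax.scatter([p[0] for p in pts], [p[1] for p in pts],
                   marker=markers.get(role, "o"), label=role, s=18)
    ax.axhline(THRESHOLD_DEFAULT, color="red", linestyle="--", label="threshold 3.0")
    ax.set_xlabel("record index")
    ax.set_ylabel("max |standardized descriptor value|")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
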