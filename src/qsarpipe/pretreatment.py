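"""Descriptor pretreatment: variance filter, de-redundancy, normalization.

The correlation filter is a deterministic greedy stand-in for
redundancy-removal tools: offending pairs are resolved by dropping the
member with the weaker link to the activity (or the smaller variance
when the activity tie-break is disabled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .io import Dataset

NORMALIZATION_VARIANTS = ("paper", "minmax")


@dataclass
class PretreatmentLog:
    dropped_constant: List[str] = field(default_factory=list)
    #: (dropped name, kept name, |r|)
    dropped_correlated: List[Tuple[str, str, float]] = field(default_factory=list)
    variance_tol: Optional[float] = None
    r_threshold: Optional[float] = None
    notes: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dropped_constant": list(self.dropped_constant),
            "dropped_correlated": [list(t) for t in self.dropped_correlated],
            "variance_tol": self.variance_tol,
            "r_threshold": self.r_threshold,
            "notes": list(self.notes),
        }


def remove_low_variance(
    dataset: Dataset, variance_tol: float = 1e-6
) -> Tuple[Dataset, PretreatmentLog]:
    """Drop descriptors whose sample variance is <= ``variance_tol``."""
    if variance_tol < 0:
        raise ValueError("variance_tol must be >= 0")
    variances = dataset.X.var(axis=0, ddof=1)
    dropped = variances.index[variances <= variance_tol].tolist()
    kept = [c for c in dataset.X.columns if c not in set(dropped)]
    if not kept:
        raise ValueError("all descriptors removed by the variance filter")
    log = PretreatmentLog(dropped_constant=dropped, variance_tol=variance_tol)
    log.notes.append("variance tolerance is an assumed default; tool settings unpublished")
    out = Dataset(dataset.X[kept].copy(), dataset.y.copy(), dataset.activity_name)
    return out, log


def correlation_filter(
    dataset: Dataset,
    r_threshold: float = 0.95,
    use_activity_tiebreak: bool = True,
) -> Tuple[Dataset, PretreatmentLog]:
    """Greedy elimination until every retained pair has ``|r| < r_threshold``.

    The most-correlated offending pair is resolved first (ties broken by
    column order); within a pair, the descriptor with the smaller
    |correlation to activity| is dropped (smaller variance if the
    activity tie-break is disabled). Deterministic and idempotent.
    """
    if not (0 < r_threshold <= 1):
        raise ValueError("r_threshold must lie in (0, 1]")
    X = dataset.X
    cols = list(X.columns)
    corr = np.abs(np.corrcoef(X.to_numpy(dtype=float), rowvar=False))
    corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)
    np.fill_diagonal(corr, 0.0)
    if use_activity_tiebreak:
        yv = dataset.y.to_numpy(dtype=float)
        merit = np.array([
            abs(np.corrcoef(X[c].to_numpy(dtype=float), yv)[0, 1]) for c in cols
        ])
        merit = np.nan_to_num(merit, nan=0.0)
    else:
        merit = X.var(axis=0, ddof=1).to_numpy(dtype=float)

    active = list(range(len(cols)))
    dropped: List[Tuple[str, str, float]] = []
    while True:
        sub = corr[np.ix_(active, active)]
        if sub.size == 0 or sub.max() < r_threshold:
            break
        i_loc, j_loc = np.unravel_index(np.argmax(sub), sub.shape)
        i, j = active[i_loc], active[j_loc]
        if i > j:
            i, j = j, i
        r = corr[i, j]
        # drop the weaker column; on an exact merit tie drop the later one
        loser, keeper = (i, j) if merit[i] < merit[j] else (j, i)
        dropped.append((cols[loser], cols[keeper], float(r)))
        active.remove(loser)

    kept_names = [cols[k] for k in active]
    log = PretreatmentLog(
        dropped_correlated=dropped, r_threshold=r_threshold,
        notes=["greedy pairwise elimination; threshold is an assumed default"],
    )
    out = Dataset(X[kept_names].copy(), dataset.y.copy(), dataset.activity_name)
    return out, log


@dataclass
class NormalizationParams:
    """Per-descriptor min/max fitted on the training partition only."""

    xmin: pd.Series
    xmax: pd.Series
    variant: str = "paper"

    def __post_init__(self) -> None:
        if self.variant not in NORMALIZATION_VARIANTS:
            raise ValueError(f"variant must be one of {NORMALIZATION_VARIANTS}")
        bad = self.xmax.index[(self.xmax - self.xmin) <= 0].tolist()
        if bad:
            raise ValueError(f"constant columns cannot be normalized: {bad}")


def fit_normalizer(train: Dataset, variant: str = "paper") -> NormalizationParams:
    """Learn column minima/maxima from the training partition."""
    return NormalizationParams(
        xmin=train.X.min(axis=0), xmax=train.X.max(axis=0), variant=variant
    )


def apply_normalizer(dataset: Dataset, params: NormalizationParams) -> Dataset:
    """Normalize columns with training-set parameters.

    ``paper`` variant: (X - Xmax)/(Xmax - Xmin), mapping training columns
    into [-1, 0]; ``minmax``: (X - Xmin)/(Xmax - Xmin), into [0, 1].
    Values outside the training range are NOT clipped.
    """
    missing = [c for c in dataset.X.columns if c not in params.xmin.index]
    if missing:
        raise KeyError(f"no normalization parameters for: {missing}")
    xmin = params.xmin[dataset.X.columns]
    xmax = params.xmax[dataset.X.columns]
    span = xmax - xmin
    if params.variant == "paper":
        X = (dataset.X - xmax) / span
    else:
        X = (dataset.X - xmin) / span
    return Dataset(X, dataset.y.copy(), dataset.activity_name)
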