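"""Kennard-Stone train/test division and partition descriptive statistics."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy import stats as sps

from .io import Dataset

logger = logging.getLogger(__name__)


@dataclass
class SplitResult:
    train_ids: List
    test_ids: List
    selection_order: List
    distance_metric: str = "euclidean"

    def to_dict(self) -> dict:
        return {
            "train_ids": list(self.train_ids),
            "test_ids": list(self.test_ids),
            "selection_order": list(self.selection_order),
            "distance_metric": self.distance_metric,
        }


def kennard_stone_split(dataset: Dataset, n_train: int) -> SplitResult:
    """Classic maximin selection on Euclidean distances in descriptor space.

    The first two picks are the mutually farthest pair; each further pick
    maximizes the minimum distance to the points already selected. Ties
    are broken by the lowest row index, so the split is deterministic.
    Descriptors should be normalized beforehand (a warning is logged when
    column scales differ wildly, but the split proceeds).
    """
    n = dataset.n_compounds
    if not (2 <= n_train <= n):
        raise ValueError(f"n_train must lie in [2, {n}], got {n_train}")
    X = dataset.X.to_numpy(dtype=float)
    spans = X.max(axis=0) - X.min(axis=0)
    nonzero = spans[spans > 0]
    if nonzero.size and nonzero.max() / nonzero.min() > 1e3:
        logger.warning("descriptor scales differ by >1000x; consider normalizing before splitting")
    D = squareform(pdist(X, metric="euclidean"))

    # farthest pair; ties -> lexicographically smallest (i, j)
    flat = np.argmax(D)
    maxval = D.flat[flat]
    candidates = np.argwhere(np.isclose(D, maxval, rtol=0.0, atol=0.0))
    i, j = min((int(a), int(b)) for a, b in candidates if a < b)
    if maxval == 0:
        logger.warning("all rows identical; Kennard-Stone falling back to index order")
    selected = [i, j]
    remaining = [k for k in range(n) if k not in (i, j)]

    while len(selected) < n_train:
        dmin = D[np.ix_(remaining, selected)].min(axis=1)
        best = float(dmin.max())
        # lowest original row index wins on ties
        pick = next(r for r, d in zip(remaining, dmin) if d == best)
        selected.append(pick)
        remaining.remove(pick)

    ids = dataset.compound_ids
    train_set = set(selected)
    return SplitResult(
        train_ids=[ids[k] for k in sorted(selected)],
        test_ids=[ids[k] for k in range(n) if k not in train_set],
        selection_order=[ids[k] for k in selected],
    )


@dataclass
class DescriptiveStats:
    """Spreadsheet-style summary of an activity vector.

    Skewness and kurtosis use the bias-corrected sample conventions
    (excess kurtosis); fields that need more observations than supplied
    are ``None``.
    """

    n: int
    mean: float
    standard_error: float
    median: float
    standard_deviation: float
    sample_variance: float
    kurtosis: Optional[float]
    skewness: Optional[float]
    range: float
    minimum: float
    maximum: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "standard_error": self.standard_error,
            "median": self.median,
            "standard_deviation": self.standard_deviation,
            "sample_variance": self.sample_variance,
            "kurtosis": self.kurtosis,
            "skewness": self.skewness,
            "range": self.range,
            "minimum": self.minimum,
            "maximum": self.maximum,
        }


def describe_activity(values, zero_spread_convention: bool = True) -> DescriptiveStats:
    """Compute the descriptive statistics block for one partition.

    With ``zero_spread_convention``, a constant vector reports skewness
    and kurtosis of 0 instead of undefined.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = float(np.std(v, ddof=1))

    skew: Optional[float]
    kurt: Optional[float]
    with warnings.catch_warnings():
        # constant vectors trigger a precision warning; handled by convention
        warnings.simplefilter("ignore", RuntimeWarning)
        if n >= 3:
            skew = float(sps.skew(v, bias=False))
        else:
            skew = None
        if n >= 4:
            kurt = float(sps.kurtosis(v, fisher=True, bias=False))
        else:
            kurt = None
            logger.info("kurtosis omitted: needs n >= 4, got %d", n)
    if sd == 0 and zero_spread_convention:
        skew = 0.0 if skew is not None else skew
        kurt = 0.0 if kurt is not None else kurt
    elif sd == 0:
        skew = None if skew is None or np.isnan(skew) else skew
        kurt = None if kurt is None or np.isnan(kurt) else kurt

    return DescriptiveStats(
        n=n,
        mean=float(np.mean(v)),
        standard_error=sd / float(np.sqrt(n)),
        median=float(np.median(v)),
        standard_deviation=sd,
        sample_variance=sd * sd,
        kurtosis=kurt,
        skewness=skew,
        range=float(v.max() - v.min()),
        minimum=float(v.min()),
        maximum=float(v.max()),
    )
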