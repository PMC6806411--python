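"""Descriptor/activity table I/O and packaged reference constants.

The on-disk format is the CSV dialect emitted by common descriptor
calculators: a header row, one row per compound, an identifier column,
an activity column, and numeric descriptor columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Tokens treated as missing on ingestion.
MISSING_TOKENS = ("", "NA", "NaN", "Inf")

MISSING_POLICIES = ("drop_column", "drop_row", "error")


class DatasetError(ValueError):
    """Raised when a table violates the Dataset contract."""


class NonNumericColumnError(DatasetError):
    """Raised when a descriptor column contains non-numeric, non-missing values."""

    def __init__(self, column: str, offending: Sequence[str]):
        self.column = column
        self.offending = list(offending)
        super().__init__(
            f"descriptor column {column!r} contains non-numeric values: "
            f"{self.offending[:5]!r}"
        )


@dataclass
class Dataset:
    """A descriptor matrix plus activity vector, indexed by compound ID.

    Parameters
    ----------
    X : pandas.DataFrame
        Descriptor values, one row per compound, indexed by compound ID.
    y : pandas.Series
        Activity values (pKi, dimensionless -log units), same index as ``X``.
    activity_name : str
        Label of the activity column.

    Compound order is significant and defines all downstream indexing;
    no implicit sorting is ever applied.
    """

    X: pd.DataFrame
    y: pd.Series
    activity_name: str = "pKi"

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise DatasetError(
                f"activity length {len(self.y)} != number of compounds {len(self.X)}"
            )
        if len(self.X) == 0:
            raise DatasetError("empty table: no compounds")
        ids = list(self.X.index)
        dup = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        if dup:
            raise DatasetError(f"duplicate compound IDs: {dup}")
        dup_cols = self.X.columns[self.X.columns.duplicated()].unique().tolist()
        if dup_cols:
            raise DatasetError(f"duplicate descriptor names: {dup_cols}")
        if not (self.X.index == self.y.index).all():
            self.y = self.y.loc[self.X.index]
        if self.X.shape[1] and not np.isfinite(self.X.to_numpy(dtype=float)).all():
            raise DatasetError("non-finite descriptor values after ingestion")
        if not np.isfinite(self.y.to_numpy(dtype=float)).all():
            raise DatasetError("non-finite activity values")

    # -- convenience accessors -------------------------------------------------

    @property
    def compound_ids(self) -> list:
        return list(self.X.index)

    @property
    def descriptor_names(self) -> list:
        return list(self.X.columns)

    @property
    def n_compounds(self) -> int:
        return len(self.X)

    @property
    def n_descriptors(self) -> int:
        return self.X.shape[1]

    def select_descriptors(self, names: Sequence[str]) -> "Dataset":
        missing = [n for n in names if n not in self.X.columns]
        if missing:
            raise DatasetError(f"unknown descriptors: {missing}")
        return Dataset(self.X[list(names)].copy(), self.y.copy(), self.activity_name)

    def subset(self, ids: Sequence) -> "Dataset":
        missing = [i for i in ids if i not in self.X.index]
        if missing:
            raise DatasetError(f"unknown compound IDs: {missing}")
        return Dataset(self.X.loc[list(ids)].copy(), self.y.loc[list(ids)].copy(),
                       self.activity_name)

    def copy(self) -> "Dataset":
        return Dataset(self.X.copy(), self.y.copy(), self.activity_name)

    def equals(self, other: "Dataset") -> bool:
        return (
            self.activity_name == other.activity_name
            and self.X.equals(other.X)
            and self.y.equals(other.y)
        )


def read_dataset(
    path,
    id_column: str = "ID",
    activity_column: str = "pKi",
    missing_policy: str = "drop_column",
) -> Dataset:
    """Read a descriptor/activity CSV into a :class:`Dataset`.

    Missing tokens (``""``, ``NA``, ``NaN``, ``Inf``) in descriptor columns are
    handled per ``missing_policy``: ``drop_column`` removes the descriptor,
    ``drop_row`` removes the compound, ``error`` raises. Missing activity
    values always raise. Non-numeric descriptor columns raise
    :class:`NonNumericColumnError`.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.empty:
        raise DatasetError(f"empty table: {path}")
    for col in (id_column, activity_column):
        if col not in raw.columns:
            raise DatasetError(f"required column {col!r} not in {list(raw.columns)}")

    ids = raw[id_column]
    dup = ids[ids.duplicated()].unique().tolist()
    if dup:
        raise DatasetError(f"duplicate compound IDs: {dup}")

    def _numeric(col: pd.Series) -> pd.Series:
        vals = col.where(~col.isin(MISSING_TOKENS), other=np.nan)
        try:
            # astype goes through float(), which is correctly rounded;
            # pd.to_numeric's fast parser can be off by 1 ulp
            return vals.astype(float)
        except (ValueError, TypeError):
            converted = pd.to_numeric(vals, errors="coerce")
            bad = vals.notna() & converted.isna()
            raise NonNumericColumnError(str(col.name), vals[bad].unique())

    y = _numeric(raw[activity_column])
    if y.isna().any():
        raise DatasetError("missing values in activity column")

    desc_cols = [c for c in raw.columns if c not in (id_column, activity_column)]
    X = pd.DataFrame({c: _numeric(raw[c]) for c in desc_cols})

    dropped_cols: list[str] = []
    dropped_rows: list = []
    na_mask = X.isna()
    if na_mask.to_numpy().any():
        if missing_policy == "error":
            bad_cols = X.columns[na_mask.any(axis=0)].tolist()
            raise DatasetError(f"missing values in descriptor columns: {bad_cols}")
        if missing_policy == "drop_column":
            dropped_cols = X.columns[na_mask.any(axis=0)].tolist()
            X = X.drop(columns=dropped_cols)
        else:  # drop_row
            keep = ~na_mask.any(axis=1)
            dropped_rows = ids[~keep].tolist()
            X, y, ids = X[keep], y[keep], ids[keep]
            if len(X) == 0:
                raise DatasetError("all rows dropped by drop_row policy")

    X.index = pd.Index(ids, name=id_column)
    y.index = X.index
    y.name = activity_column
    logger.info(
        "read %s: %d compounds, %d descriptors kept; dropped columns=%s rows=%s",
        path, len(X), X.shape[1], dropped_cols, dropped_rows,
    )
    return Dataset(X, y, activity_name=activity_column)


def write_dataset(dataset: Dataset, path) -> None:
    """Write ``dataset`` as CSV: id column first, activity second, descriptors
    in stored order. Floats are written at full repr precision so a read-back
    is value-identical."""
    path = Path(path)
    activity = dataset.y.rename(dataset.y.name or dataset.activity_name)
    out = pd.concat([activity, dataset.X], axis=1)
    out.index.name = dataset.X.index.name or "ID"
    out.to_csv(path, float_format=None)  # pandas default = repr round-trip


# --------------------------------------------------------------------------
# Published reference constants (regression-test fixture)
# --------------------------------------------------------------------------

#: Descriptor order of the published six-term model.
PUBLISHED_DESCRIPTORS = ("ALogP", "AATS7i", "ATSC3p", "IC2", "GGI10", "RDF75u")


@dataclass(frozen=True)
class PublishedModelFixture:
    """Printed constants of the published six-descriptor pKi model.

    Carries the model equation, headline fit statistics, the standardized
    contributions table, the descriptor correlation/VIF/t table and the
    Y-randomization table, exactly as printed.
    """

    intercept: float
    coefficients: Mapping[str, float]
    n_train: int
    n_test: int
    r2_train: float
    r2_adjusted: float
    q2_loo: float
    r2_test: float
    #: descriptor -> (standardized coefficient b*, percent contribution)
    table2_contributions: Mapping[str, tuple]
    #: 6x6 symmetric Pearson matrix over PUBLISHED_DESCRIPTORS
    table4_correlations: tuple
    table4_vif: Mapping[str, float]
    table4_t: Mapping[str, float]
    #: (R, R2, Q2) of the un-randomized fit
    table5_original: tuple
    #: ten (R, R2, Q2) triples for the randomized fits
    table5_randomized: tuple
    table5_average_r: float
    table5_average_r2: float
    table5_average_q2: float
    table5_crp2: float
    descriptor_order: tuple = PUBLISHED_DESCRIPTORS

    def correlation(self, a: str, b: str) -> float:
        i = self.descriptor_order.index(a)
        j = self.descriptor_order.index(b)
        return self.table4_correlations[i][j]


def _symmetrize(lower: Sequence[Sequence[float]]) -> tuple:
    n = len(lower)
    m = np.ones((n, n))
    for i in range(n):
        for j in range(i):
            m[i, j] = m[j, i] = lower[i][j]
    return tuple(tuple(row) for row in m)


def load_published_fixture() -> PublishedModelFixture:
    """Return the published model's printed constants."""
    return PublishedModelFixture(
        intercept=0.989,
        coefficients={
            "ALogP": 2.788,
            "AATS7i": 3.382,
            "ATSC3p": 3.782,
            "IC2": 2.234,
            "GGI10": -5.147,
            "RDF75u": 3.728,
        },
        n_train=36,
        n_test=14,
        r2_train=0.9156,
        r2_adjusted=0.8982,
        q2_loo=0.8755,
        r2_test=0.5832,
        table2_contributions={
            "ALogP": (0.513, 13.3),
            "AATS7i": (0.500, 13.0),
            "ATSC3p": (0.631, 16.4),
            "IC2": (0.383, 10.0),
            "GGI10": (-1.061, 27.6),
            "RDF75u": (0.756, 19.7),
        },
        table4_correlations=_symmetrize([
            [],
            [-0.3321],
            [-0.2592, -0.2991],
            [-0.2742, 0.0487, 0.0765],
            [-0.2382, 0.0921, -0.1711, 0.5005],
            [-0.2940, 0.2215, -0.1337, 0.4759, 0.6377],
        ]),
        table4_vif={
            "ALogP": 1.5021,
            "AATS7i": 1.4789,
            "ATSC3p": 1.4376,
            "IC2": 1.4177,
            "GGI10": 4.5022,
            "RDF75u": 4.3800,
        },
        table4_t={
            "ALogP": 7.5604,
            "AATS7i": 7.4649,
            "ATSC3p": 9.4970,
            "IC2": 5.8502,
            "GGI10": -9.5663,
            "RDF75u": 6.7912,
        },
        table5_original=(0.9545, 0.9111, 0.8702),
        table5_randomized=(
            (0.4197, 0.1762, -0.2759),
            (0.3402, 0.1157, -0.4558),
            (0.3943, 0.1555, -0.3333),
            (0.4690, 0.2199, -0.2220),
            (0.4408, 0.1943, -0.1861),
            (0.1560, 0.0243, -0.6456),
            (0.3589, 0.1288, -0.3166),
            (0.3237, 0.1048, -0.3536),
            (0.3323, 0.1104, -0.4357),
            (0.3646, 0.1329, -0.3307),
        ),
        table5_average_r=0.3599,
        table5_average_r2=0.1363,
        table5_average_q2=-0.3555,
        table5_crp2=0.8439,
    )
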