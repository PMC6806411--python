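"""Synthetic descriptor/activity data with known linear ground truth.

Emulates the shape of a descriptor-calculator export: ~50 compounds, a
large descriptor pool with correlated blocks and near-constant columns,
and an activity built from a sparse linear combination plus Gaussian
noise, affinely rescaled onto a pKi-like range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import Dataset
from .gfa import MLRModel

#: SD of the jitter added to near-constant columns; far below any sensible
#: variance tolerance, so the low-variance filter has real work to do.
NEAR_CONSTANT_JITTER_SD = 1e-9


@dataclass
class SyntheticSpec:
    """Parameters of the generator.

    ``true_support`` indexes descriptor columns; the activity is
    ``intercept + X[:, support] @ true_coefficients + N(0, noise_sd)``,
    then (optionally) affinely rescaled so the realized activities span
    ``activity_range_target``, with the ground-truth model transformed
    consistently.

    Column layout: correlated blocks occupy the first
    ``n_correlated_blocks * block_size`` columns (one latent factor per
    block, pairwise correlation ``block_correlation``); the last
    ``n_near_constant`` columns are near-constant; everything between is
    i.i.d. standard normal.
    """

    n_compounds: int = 50
    n_descriptors: int = 300
    #: None -> six indices spread evenly over the non-near-constant columns
    true_support: Optional[tuple] = None
    true_coefficients: tuple = (1.0, 0.8, -1.2, 0.6, -0.9, 1.1)
    intercept: float = 7.0
    noise_sd: float = 0.3
    n_correlated_blocks: int = 5
    block_size: int = 8
    block_correlation: float = 0.7
    n_near_constant: int = 10
    activity_range_target: Optional[tuple] = (4.5, 9.6)
    seed: int = 0

    def resolved_support(self) -> tuple:
        if self.true_support is not None:
            return tuple(self.true_support)
        first_const = self.n_descriptors - self.n_near_constant
        k = len(self.true_coefficients)
        if first_const < k:
            raise ValueError("too few informative columns for the default support")
        return tuple(
            int(i) for i in np.linspace(0, first_const - 1, k).round().astype(int)
        )

    def validate(self) -> None:
        self.true_support = self.resolved_support()
        if len(self.true_support) != len(self.true_coefficients):
            raise ValueError("true_support and true_coefficients lengths differ")
        if len(set(self.true_support)) != len(self.true_support):
            raise ValueError("true_support indices must be distinct")
        if len(self.true_support) > self.n_descriptors:
            raise ValueError("support larger than descriptor pool")
        if any(i < 0 or i >= self.n_descriptors for i in self.true_support):
            raise ValueError("support index out of range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.block_correlation < 1):
            raise ValueError("block_correlation must be in [0, 1)")
        n_block_cols = self.n_correlated_blocks * self.block_size
        if n_block_cols + self.n_near_constant > self.n_descriptors:
            raise ValueError("blocks + near-constant columns exceed pool size")
        first_const = self.n_descriptors - self.n_near_constant
        if any(i >= first_const for i in self.true_support):
            raise ValueError("true_support overlaps near-constant columns")

    def descriptor_name(self, j: int) -> str:
        return f"D{j:04d}"


def generate_dataset(spec: SyntheticSpec) -> tuple:
    """Generate a :class:`Dataset` and its ground-truth :class:`MLRModel`.

    Deterministic: the same spec (including seed) yields identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_compounds, spec.n_descriptors
    X = np.empty((n, m))

    n_block_cols = spec.n_correlated_blocks * spec.block_size
    rho = spec.block_correlation
    for b in range(spec.n_correlated_blocks):
        latent = rng.standard_normal(n)
        lo = b * spec.block_size
        for j in range(lo, lo + spec.block_size):
            X[:, j] = np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * rng.standard_normal(n)

    first_const = m - spec.n_near_constant
    X[:, n_block_cols:first_const] = rng.standard_normal((n, first_const - n_block_cols))

    for j in range(first_const, m):
        level = rng.uniform(-5.0, 5.0)
        X[:, j] = level + NEAR_CONSTANT_JITTER_SD * rng.standard_normal(n)

    support = list(spec.true_support)
    beta = np.asarray(spec.true_coefficients, dtype=float)
    y = spec.intercept + X[:, support] @ beta + spec.noise_sd * rng.standard_normal(n)

    b0 = spec.intercept
    if spec.activity_range_target is not None:
        lo, hi = spec.activity_range_target
        ymin, ymax = y.min(), y.max()
        if ymax - ymin <= 0:
            raise ValueError("degenerate activity: cannot rescale a constant vector")
        a = (hi - lo) / (ymax - ymin)
        b = lo - a * ymin
        y = a * y + b
        beta = a * beta
        b0 = a * b0 + b

    names = [spec.descriptor_name(j) for j in range(m)]
    ids = [f"CPD{i + 1:03d}" for i in range(n)]
    frame = pd.DataFrame(X, index=pd.Index(ids, name="ID"), columns=names)
    activity = pd.Series(y, index=frame.index, name="pKi")
    dataset = Dataset(frame, activity, activity_name="pKi")

    truth = MLRModel(
        intercept=float(b0),
        coefficients={spec.descriptor_name(j): float(c) for j, c in zip(support, beta)},
        n_train=n,
    )
    return dataset, truth
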