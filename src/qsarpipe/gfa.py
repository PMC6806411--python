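"""Ordinary least squares and the genetic search over descriptor subsets.

The search evolves a population of linear models (descriptor subsets),
scored by the Friedman lack-of-fit, and returns the final population
ranked best-first. Only linear terms are used; no splines or quadratics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; names the offending columns."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; collinear columns: {self.columns}")


@dataclass
class MLRModel:
    """Intercept plus named descriptor coefficients, with cached fit stats."""

    intercept: float
    coefficients: Dict[str, float]
    n_train: int = 0
    sse: Optional[float] = None
    see: Optional[float] = None
    r2: Optional[float] = None

    @property
    def p(self) -> int:
        """Number of descriptor terms."""
        return len(self.coefficients)

    @property
    def descriptor_names(self) -> list:
        return list(self.coefficients)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "n_train": self.n_train,
            "sse": self.sse,
            "see": self.see,
            "r2": self.r2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLRModel":
        return cls(
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            n_train=int(d.get("n_train", 0)),
            sse=d.get("sse"),
            see=d.get("see"),
            r2=d.get("r2"),
        )


def _as_matrix(X, names: Optional[Sequence[str]]) -> Tuple[np.ndarray, List[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if names is None:
        names = [f"x{j}" for j in range(arr.shape[1])]
    return arr, list(names)


def fit_mlr(X, y, names: Optional[Sequence[str]] = None) -> MLRModel:
    """Ordinary least squares with intercept.

    Raises :class:`RankDeficientError` on a collinear design rather than
    silently falling back to a pseudo-inverse.
    """
    arr, names = _as_matrix(X, names)
    yv = np.asarray(y, dtype=float)
    n, p = arr.shape
    if n < p + 2:
        raise ValueError(f"need at least p + 2 = {p + 2} rows, got {n}")
    design = np.column_stack([np.ones(n), arr])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        # pivoted QR identifies which columns are in the collinear tail
        from scipy.linalg import qr

        _, _, piv = qr(design, pivoting=True, mode="economic")
        bad = [names[j - 1] for j in piv[rank:] if j > 0]
        raise RankDeficientError(bad or names)
    coef, _, _, _ = np.linalg.lstsq(design, yv, rcond=None)
    resid = yv - design @ coef
    sse = float(resid @ resid)
    dof = n - p - 1
    see = float(np.sqrt(sse / dof)) if dof > 0 else float("nan")
    sst = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return MLRModel(
        intercept=float(coef[0]),
        coefficients={nm: float(c) for nm, c in zip(names, coef[1:])},
        n_train=n,
        sse=sse,
        see=see,
        r2=r2,
    )


def predict(model: MLRModel, X) -> np.ndarray:
    """Evaluate the linear model on ``X`` (DataFrame or aligned array)."""
    names = model.descriptor_names
    if isinstance(X, pd.DataFrame):
        missing = [n for n in names if n not in X.columns]
        if missing:
            raise KeyError(f"missing descriptor columns: {missing}")
        arr = X[names].to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[1] != len(names):
            raise KeyError(
                f"expected {len(names)} descriptor columns, got {arr.shape[1]}"
            )
    beta = np.array([model.coefficients[n] for n in names])
    return model.intercept + arr @ beta


# --------------------------------------------------------------------------
# Friedman lack-of-fit
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LOFScore:
    """Lack-of-fit value together with the quantities that produced it."""

    lof: float
    sse: float
    c: int
    d: float
    p: int
    M: int


def lof(
    sse: float,
    M: int,
    p: int,
    c: Optional[int] = None,
    d: float = 0.5,
    numerator: str = "sse_over_m",
) -> LOFScore:
    """Friedman lack-of-fit: ``(SSE/M) / (1 - (c + d*p)/M)**2``.

    ``c`` (number of basis functions) defaults to ``p + 1`` — the linear
    terms plus intercept. ``numerator="see"`` instead uses the standard
    error of estimate ``sqrt(SSE/(M-p-1))`` as a literal alternative
    reading; the default is the published definition.
    """
    if c is None:
        c = p + 1
    if sse < 0:
        raise ValueError("sse must be >= 0")
    penalty_arg = (c + d * p) / M
    if penalty_arg >= 1:
        raise ValueError(
            f"model too complex for M={M}: (c + d*p)/M = {penalty_arg:.3f} >= 1"
        )
    if numerator == "sse_over_m":
        num = sse / M
    elif numerator == "see":
        dof = M - p - 1
        if dof <= 0:
            raise ValueError("M - p - 1 must be positive for the SEE numerator")
        num = float(np.sqrt(sse / dof))
    else:
        raise ValueError("numerator must be 'sse_over_m' or 'see'")
    value = num / (1.0 - penalty_arg) ** 2
    return LOFScore(lof=float(value), sse=float(sse), c=c, d=d, p=p, M=M)


# --------------------------------------------------------------------------
# Genetic search
# --------------------------------------------------------------------------

@dataclass
class GFAConfig:
    population_size: int = 100
    generations: int = 500
    min_terms: int = 2
    max_terms: int = 8
    d: float = 0.5
    mutation_rate: float = 0.1
    crossover_rate: float = 0.9
    elitism: int = 2
    seed: int = 0
    stagnation_patience: int = 50
    lof_numerator: str = "sse_over_m"
    #: parsimony guard: refuse max_terms > n_train / 5 unless overridden
    allow_term_ratio_violation: bool = False

    def validate(self, n_train: int) -> None:
        if self.min_terms < 1:
            raise ValueError("min_terms must be >= 1")
        if self.max_terms < self.min_terms:
            raise ValueError("max_terms must be >= min_terms")
        if self.max_terms >= n_train - 1:
            raise ValueError("max_terms must be < n_train - 1")
        for r in (self.mutation_rate, self.crossover_rate):
            if not (0 <= r <= 1):
                raise ValueError("rates must lie in [0, 1]")
        if self.max_terms > n_train / 5:
            if not self.allow_term_ratio_violation:
                raise ValueError(
                    f"max_terms={self.max_terms} exceeds the 1:5 term-to-sample "
                    f"guard for n_train={n_train}; set "
                    "allow_term_ratio_violation=True to override"
                )
            warnings.warn(
                "term-to-sample ratio guard overridden: "
                f"max_terms={self.max_terms}, n_train={n_train}",
                stacklevel=3,
            )


def _evaluate(subset: frozenset, names: list, dataset, config: GFAConfig, cache: dict):
    if subset in cache:
        return cache[subset]
    try:
        model = fit_mlr(dataset.X[names], dataset.y.to_numpy(), names)
        score = lof(
            model.sse, M=dataset.n_compounds, p=len(names),
            d=config.d, numerator=config.lof_numerator,
        )
    except (np.linalg.LinAlgError, ValueError):
        model, score = None, None
    cache[subset] = (model, score)
    return model, score


def _random_subset(pool: list, size: int, rng) -> frozenset:
    return frozenset(rng.choice(len(pool), size=size, replace=False).tolist())


def gfa_search(
    dataset, config: GFAConfig, history: Optional[list] = None
) -> List[Tuple[MLRModel, LOFScore]]:
    """Evolve descriptor subsets under lack-of-fit fitness (lower = better).

    Rank-based parent selection, one-point crossover on sorted name sets
    with size repair, swap/grow/shrink mutation, elitism, duplicate
    collapse, and stagnation-based early stopping. Fully reproducible
    from ``config.seed``. Returns the final population sorted by LOF.

    When ``history`` is a list, the best LOF of each generation
    (including the initial population) is appended to it.
    """
    pool = list(dataset.descriptor_names)
    if len(pool) < config.min_terms:
        raise ValueError(
            f"descriptor pool ({len(pool)}) smaller than min_terms "
            f"({config.min_terms})"
        )
    config.validate(dataset.n_compounds)
    rng = np.random.default_rng(config.seed)
    name_index = {n: j for j, n in enumerate(pool)}
    cache: dict = {}

    def subset_names(s: frozenset) -> list:
        return sorted(pool[j] for j in s)

    def repair(s: set) -> frozenset:
        s = set(s)
        while len(s) > config.max_terms:
            s.remove(int(rng.choice(sorted(s))))
        while len(s) < config.min_terms:
            s.add(int(rng.integers(len(pool))))
        return frozenset(s)

    # initial population: random subsets, duplicates resampled
    population: List[frozenset] = []
    seen = set()
    attempts = 0
    while len(population) < config.population_size and attempts < 50 * config.population_size:
        size = int(rng.integers(config.min_terms, config.max_terms + 1))
        size = min(size, len(pool))
        cand = _random_subset(pool, size, rng)
        attempts += 1
        if cand not in seen:
            seen.add(cand)
            population.append(cand)
    if not population:
        raise ValueError("failed to build an initial population")

    def ranked(pop: List[frozenset]):
        scored = []
        for s in pop:
            model, score = _evaluate(s, subset_names(s), dataset, config, cache)
            key = score.lof if score is not None else float("inf")
            scored.append((key, s))
        scored.sort(key=lambda t: (t[0], subset_names(t[1])))
        return scored

    scored = ranked(population)
    best_lof = scored[0][0]
    if history is not None:
        history.append(best_lof)
    stagnant = 0

    for _ in range(config.generations):
        n_pop = len(scored)
        # rank weights: best gets n, worst gets 1
        weights = np.arange(n_pop, 0, -1, dtype=float)
        weights /= weights.sum()
        order = [s for _, s in scored]

        next_pop: List[frozenset] = [s for _, s in scored[: config.elitism]]
        next_seen = set(next_pop)
        guard = 0
        while len(next_pop) < config.population_size and guard < 50 * config.population_size:
            guard += 1
            i, j = rng.choice(n_pop, size=2, p=weights)
            pa, pb = subset_names(order[i]), subset_names(order[j])
            if rng.random() < config.crossover_rate:
                cut_a = int(rng.integers(len(pa) + 1))
                cut_b = int(rng.integers(len(pb) + 1))
                child = set(pa[:cut_a]) | set(pb[cut_b:])
                if not child:
                    child = set(pa) or set(pb)
            else:
                child = set(pa)
            child_idx = {name_index[n] for n in child}
            if rng.random() < config.mutation_rate:
                op = rng.random()
                if op < 0.6 or len(child_idx) <= config.min_terms:
                    # swap one member for an outside descriptor
                    out = int(rng.choice(sorted(child_idx)))
                    child_idx.discard(out)
                    child_idx.add(int(rng.integers(len(pool))))
                elif op < 0.8 and len(child_idx) < config.max_terms:
                    child_idx.add(int(rng.integers(len(pool))))
                elif len(child_idx) > config.min_terms:
                    child_idx.remove(int(rng.choice(sorted(child_idx))))
            cand = repair(child_idx)
            if cand not in next_seen:
                next_seen.add(cand)
                next_pop.append(cand)
        # pad with random subsets if deduplication starved the population
        while len(next_pop) < config.population_size and len(next_seen) < 2 ** len(pool):
            size = int(rng.integers(config.min_terms, config.max_terms + 1))
            cand = _random_subset(pool, min(size, len(pool)), rng)
            if cand not in next_seen:
                next_seen.add(cand)
                next_pop.append(cand)

        scored = ranked(next_pop)
        if history is not None:
            history.append(scored[0][0])
        if scored[0][0] < best_lof - 1e-15:
            best_lof = scored[0][0]
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= config.stagnation_patience:
                break

    results = []
    for lof_value, s in scored:
        model, score = cache[s]
        if model is not None:
            results.append((model, score))
    if not results:
        raise RuntimeError("no fittable model found in the final population")
    return results
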