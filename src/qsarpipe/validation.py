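"""Statistical validation battery for fitted activity models.

Covers training fit statistics, leave-one-out cross-validation,
external-set prediction quality, response randomization, standardized
descriptor contributions, collinearity diagnostics, per-coefficient
inference, and the pass/fail acceptance checklist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gfa import MLRModel, fit_mlr, predict


def r_squared(y, yhat) -> float:
    """Coefficient of determination, 1 - SSE/SStot."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("y and yhat must be equal-length vectors of size >= 2")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("constant response: R^2 undefined")
    sse = float(np.sum((y - yhat) ** 2))
    return 1.0 - sse / sst


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def q2_loo(X, y, names: Optional[Sequence[str]] = None) -> float:
    """Leave-one-out cross-validated R^2 (PRESS-based).

    Each row is predicted by a model refitted on the other rows; the
    denominator uses the mean of the FULL training response.
    """
    preds = loo_predictions(X, y, names)
    y = np.asarray(y, dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("constant response: Q^2 undefined")
    press = float(np.sum((preds - y) ** 2))
    return 1.0 - press / sst


def loo_predictions(X, y, names: Optional[Sequence[str]] = None) -> np.ndarray:
    """Explicit leave-one-out refit predictions, one per row."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
    y = np.asarray(y, dtype=float)
    n, p = arr.shape
    if n < p + 3:
        raise ValueError(f"need n >= p + 3 for leave-one-out (n={n}, p={p})")
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        try:
            model = fit_mlr(arr[keep], y[keep], names)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"rank-deficient subfit when leaving out row {i}: {exc}"
            ) from exc
        preds[i] = predict(model, arr[i][None, :])[0]
    return preds


def r2_external(
    model: MLRModel,
    X_test,
    y_test,
    y_train_mean: float,
    variant: str = "standard",
) -> float:
    """External-set determination coefficient.

    ``standard``: 1 - SSE / sum((y_test - y_train_mean)^2).
    ``as_printed``: denominator uses the PREDICTED test values minus the
    training mean, a literal alternative reading.
    """
    yhat = predict(model, X_test)
    y = np.asarray(y_test, dtype=float)
    sse = float(np.sum((yhat - y) ** 2))
    if variant == "standard":
        denom = float(np.sum((y - y_train_mean) ** 2))
    elif variant == "as_printed":
        denom = float(np.sum((yhat - y_train_mean) ** 2))
    else:
        raise ValueError("variant must be 'standard' or 'as_printed'")
    if denom == 0:
        raise ZeroDivisionError(f"zero denominator in external R^2 ({variant})")
    return 1.0 - sse / denom


def standardized_contributions(model: MLRModel, X_train, y_train) -> Dict[str, Tuple[float, float]]:
    """Standardized coefficients b*_j = s_j b_j / S_y and percent shares.

    Percent share of descriptor j is 100 |b*_j| / sum_k |b*_k|.
    """
    if isinstance(X_train, pd.DataFrame):
        X_train = X_train[model.descriptor_names]
    arr = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    sy = float(np.std(y, ddof=1))
    if sy == 0:
        raise ValueError("zero activity standard deviation")
    sj = np.std(arr, axis=0, ddof=1)
    beta = np.array([model.coefficients[n] for n in model.descriptor_names])
    bstar = sj * beta / sy
    total = float(np.sum(np.abs(bstar)))
    return {
        name: (float(b), float(100.0 * abs(b) / total))
        for name, b in zip(model.descriptor_names, bstar)
    }


def contribution_percents(bstar: Sequence[float]) -> List[float]:
    """Percent shares from standardized coefficients alone."""
    b = np.abs(np.asarray(bstar, dtype=float))
    total = b.sum()
    if total == 0:
        raise ValueError("all standardized coefficients are zero")
    return list(100.0 * b / total)


def pearson_matrix(X) -> pd.DataFrame:
    """Pearson correlation matrix of descriptor columns."""
    if isinstance(X, pd.DataFrame):
        cols = list(X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        cols = [f"x{j}" for j in range(arr.shape[1])]
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    sd = arr.std(axis=0, ddof=1)
    constant = [cols[j] for j in np.flatnonzero(sd == 0)]
    if constant:
        raise ValueError(f"constant columns have no correlation: {constant}")
    corr = np.corrcoef(arr, rowvar=False)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=cols, columns=cols)


def vif(X_or_corr) -> Dict[str, float]:
    """Variance inflation factors, the diagonal of the inverse correlation
    matrix (equivalently 1/(1 - R^2) of each descriptor on the rest)."""
    if isinstance(X_or_corr, pd.DataFrame) and (
        X_or_corr.shape[0] == X_or_corr.shape[1]
        and list(X_or_corr.index) == list(X_or_corr.columns)
        and np.allclose(np.diag(X_or_corr.to_numpy(dtype=float)), 1.0)
    ):
        corr = X_or_corr
    else:
        corr = pearson_matrix(X_or_corr)
    mat = corr.to_numpy(dtype=float)
    if np.linalg.eigvalsh(mat).min() < 1e-10:
        raise np.linalg.LinAlgError("correlation matrix is singular or not positive definite")
    inv = np.linalg.inv(mat)
    return {name: float(inv[i, i]) for i, name in enumerate(corr.columns)}


def coefficient_inference(model: MLRModel, X_train, y_train) -> Dict[str, Dict[str, float]]:
    """Classical OLS per-coefficient standard errors, t statistics, and
    two-sided p-values (t distribution, n - p - 1 df).

    A zero-residual fit reports infinite t and zero p for nonzero
    estimates.
    """
    names = model.descriptor_names
    if isinstance(X_train, pd.DataFrame):
        X_train = X_train[names]
    arr = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    n, p = arr.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    design = np.column_stack([np.ones(n), arr])
    if np.linalg.matrix_rank(design) < p + 1:
        raise np.linalg.LinAlgError("rank-deficient design")
    beta = np.array([model.intercept] + [model.coefficients[nm] for nm in names])
    resid = y - design @ beta
    dof = n - p - 1
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    out: Dict[str, Dict[str, float]] = {}
    for label, est, s in zip(["(intercept)"] + list(names), beta, se):
        if s == 0:
            t = float("inf") if est != 0 else 0.0
            pval = 0.0 if est != 0 else 1.0
        else:
            t = est / s
            pval = 2.0 * float(sps.t.sf(abs(t), dof))
        out[label] = {"estimate": float(est), "se": float(s), "t": float(t), "p": pval}
    return out


def f_statistic(r2: float, n: int, p: int) -> float:
    """Overall-regression F = (R^2/p) / ((1-R^2)/(n-p-1))."""
    if n <= p + 1:
        raise ValueError("need n > p + 1")
    if r2 >= 1.0:
        return float("inf")
    return (r2 / p) / ((1.0 - r2) / (n - p - 1))


# --------------------------------------------------------------------------
# Y-randomization
# --------------------------------------------------------------------------

@dataclass
class YRandomizationResult:
    """Per-permutation (R, R^2, Q^2) triples with their averages and cRp^2."""

    iterations: List[Tuple[float, float, float]]
    original: Tuple[float, float, float]
    average_r: float
    average_r2: float
    average_q2: float
    crp2: float
    n_iterations: int
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "iterations": [list(t) for t in self.iterations],
            "original": list(self.original),
            "average_r": self.average_r,
            "average_r2": self.average_r2,
            "average_q2": self.average_q2,
            "crp2": self.crp2,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
        }


def crp2(r_original: float, rr_average: float, r2_original: Optional[float] = None) -> float:
    """Randomization penalty coefficient: R * sqrt(R^2 - Rr^2)."""
    r2 = r_original * r_original if r2_original is None else r2_original
    if rr_average * rr_average > r2:
        raise ValueError(
            "average randomized R exceeds the original R: randomized models fit better"
        )
    return r_original * float(np.sqrt(r2 - rr_average * rr_average))


def summarize_randomization(
    iterations: Sequence[Tuple[float, float, float]],
    original: Tuple[float, float, float],
    seed: Optional[int] = None,
) -> YRandomizationResult:
    """Aggregate (R, R^2, Q^2) triples into averages and cRp^2."""
    if not iterations:
        raise ValueError("need at least one randomization iteration")
    arr = np.asarray(iterations, dtype=float)
    avg_r, avg_r2, avg_q2 = (float(v) for v in arr.mean(axis=0))
    return YRandomizationResult(
        iterations=[tuple(map(float, t)) for t in iterations],
        original=tuple(map(float, original)),
        average_r=avg_r,
        average_r2=avg_r2,
        average_q2=avg_q2,
        crp2=crp2(original[0], avg_r, r2_original=original[1]),
        n_iterations=len(iterations),
        seed=seed,
    )


def randomization_permutations(n: int, n_iterations: int, seed: int) -> List[np.ndarray]:
    """The index permutations a seeded randomization run will apply.

    Each is a rearrangement of ``arange(n)``, so every permuted response
    keeps the original activity multiset.
    """
    rng = np.random.default_rng(seed)
    return [rng.permutation(n) for _ in range(n_iterations)]


def y_randomization(
    X_train,
    y_train,
    descriptor_names: Optional[Sequence[str]] = None,
    n_iterations: int = 10,
    seed: int = 0,
) -> YRandomizationResult:
    """Permute the response, refit the same descriptor subset, and record
    (R, R^2, Q^2) per iteration; R is the multiple correlation between
    observed and fitted response."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if isinstance(X_train, pd.DataFrame):
        if descriptor_names is not None:
            X_train = X_train[list(descriptor_names)]
        frame = X_train
    else:
        arr = np.asarray(X_train, dtype=float)
        names = descriptor_names or [f"x{j}" for j in range(arr.shape[1])]
        frame = pd.DataFrame(arr, columns=list(names))
    y = np.asarray(y_train, dtype=float)

    def triple(y_vec: np.ndarray) -> Tuple[float, float, float]:
        model = fit_mlr(frame, y_vec)
        yhat = predict(model, frame)
        r2 = r_squared(y_vec, yhat)
        r = float(np.corrcoef(y_vec, yhat)[0, 1])
        q2 = q2_loo(frame, y_vec)
        return (r, r2, q2)

    original = triple(y)
    iterations = [
        triple(y[perm])
        for perm in randomization_permutations(len(y), n_iterations, seed)
    ]
    return summarize_randomization(iterations, original, seed=seed)


# --------------------------------------------------------------------------
# Report assembly and acceptance checklist
# --------------------------------------------------------------------------

@dataclass
class ValidationReport:
    r2: float
    r2_adjusted: float
    see: float
    f_statistic: float
    q2_loo: float
    r2_test: Optional[float]
    n_train: int
    n_test: Optional[int]
    coefficients: Dict[str, Dict[str, float]]
    vif: Dict[str, float]
    pearson: pd.DataFrame
    contributions: Dict[str, Tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "r2_adjusted": self.r2_adjusted,
            "see": self.see,
            "f_statistic": self.f_statistic,
            "q2_loo": self.q2_loo,
            "r2_test": self.r2_test,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "coefficients": self.coefficients,
            "vif": self.vif,
            "pearson": self.pearson.to_dict(),
            "contributions": {k: list(v) for k, v in self.contributions.items()},
        }


def validate_model(
    model: MLRModel,
    train,
    test=None,
    r2_test_variant: str = "standard",
) -> ValidationReport:
    """Run the full battery for a fitted model on its training (and
    optional test) partition. ``train``/``test`` are Datasets."""
    names = model.descriptor_names
    Xtr = train.X[names]
    ytr = train.y.to_numpy(dtype=float)
    yhat = predict(model, Xtr)
    r2 = r_squared(ytr, yhat)
    p = model.p
    n = len(ytr)
    sse = float(np.sum((ytr - yhat) ** 2))
    see = float(np.sqrt(sse / (n - p - 1)))
    q2 = q2_loo(Xtr, ytr)
    r2t = None
    n_test = None
    if test is not None:
        r2t = r2_external(model, test.X[names], test.y.to_numpy(dtype=float),
                          y_train_mean=float(ytr.mean()), variant=r2_test_variant)
        n_test = test.n_compounds
    return ValidationReport(
        r2=r2,
        r2_adjusted=adjusted_r2(r2, n, p),
        see=see,
        f_statistic=f_statistic(r2, n, p),
        q2_loo=q2,
        r2_test=r2t,
        n_train=n,
        n_test=n_test,
        coefficients=coefficient_inference(model, Xtr, ytr),
        vif=vif(Xtr) if p > 1 else {nm: 1.0 for nm in names},
        pearson=pearson_matrix(Xtr),
        contributions=standardized_contributions(model, Xtr, ytr),
    )


#: (label, description, predicate over the assembled value dict)
CHECKLIST_CRITERIA = (
    ("r2", "R^2 >= 0.6", lambda v: v >= 0.6),
    ("q2_loo", "Q^2 > 0.5", lambda v: v > 0.5),
    ("r2_minus_q2", "R^2 - Q^2 <= 0.3", lambda v: v <= 0.3),
    ("n_test", "external set size >= 5", lambda v: v >= 5),
    ("r2_test", "R^2_test >= 0.5", lambda v: v >= 0.5),
    ("crp2", "cRp^2 > 0.5", lambda v: v > 0.5),
    ("r2_adjusted", "adjusted R^2 > 0.6", lambda v: v > 0.6),
    ("max_vif", "all VIF < 10", lambda v: v < 10),
    ("min_abs_t", "all |t| > 2", lambda v: v > 2),
)


def acceptance_checklist(
    report: ValidationReport,
    yrand: Optional[YRandomizationResult],
    n_test: Optional[int] = None,
) -> dict:
    """Evaluate the model-quality checklist; every criterion must pass.

    Missing inputs make the affected criterion "not evaluable" and fail
    the overall verdict.
    """
    desc_t = [
        rec["t"] for label, rec in report.coefficients.items() if label != "(intercept)"
    ]
    values = {
        "r2": report.r2,
        "q2_loo": report.q2_loo,
        "r2_minus_q2": report.r2 - report.q2_loo,
        "n_test": n_test if n_test is not None else report.n_test,
        "r2_test": report.r2_test,
        "crp2": yrand.crp2 if yrand is not None else None,
        "r2_adjusted": report.r2_adjusted,
        "max_vif": max(report.vif.values()) if report.vif else None,
        "min_abs_t": min(abs(t) for t in desc_t) if desc_t else None,
    }
    out = {}
    overall = True
    for key, description, pred in CHECKLIST_CRITERIA:
        v = values[key]
        if v is None:
            out[key] = {"description": description, "value": None,
                        "verdict": "not evaluable"}
            overall = False
        else:
            ok = bool(pred(v))
            out[key] = {"description": description, "value": float(v),
                        "verdict": "pass" if ok else "fail"}
            overall = overall and ok
    out["overall"] = {"verdict": "pass" if overall else "fail"}
    return out
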