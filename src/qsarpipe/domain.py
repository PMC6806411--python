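"""Leverage-based applicability domain and the Williams-plot table.

Structural outliers are compounds with leverage above the warning
threshold; response outliers have |standardized residual| > 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .gfa import MLRModel, predict
from .io import Dataset

RESIDUAL_BOUND = 3.0

FLAGS = ("in_domain", "response_outlier", "structural_outlier", "both")


def leverage_values(X_train, X_query=None) -> np.ndarray:
    """Hat values h_i = x_i (X'X)^-1 x_i' against the training design.

    An intercept column is appended internally. With ``X_query`` None the
    training leverages are returned (they sum to p + 1).
    """
    Xt = np.asarray(
        X_train.to_numpy(dtype=float) if isinstance(X_train, pd.DataFrame) else X_train,
        dtype=float,
    )
    if Xt.ndim == 1:
        Xt = Xt[:, None]
    n, p = Xt.shape
    design = np.column_stack([np.ones(n), Xt])
    xtx = design.T @ design
    if np.linalg.matrix_rank(design) < p + 1:
        raise np.linalg.LinAlgError("singular X'X: training design is rank deficient")
    if X_query is None:
        Q = design
    else:
        Xq = np.asarray(
            X_query.to_numpy(dtype=float) if isinstance(X_query, pd.DataFrame) else X_query,
            dtype=float,
        )
        if Xq.ndim == 1:
            Xq = Xq[:, None]
        Q = np.column_stack([np.ones(len(Xq)), Xq])
    # h = diag(Q (X'X)^-1 Q')
    solved = np.linalg.solve(xtx, Q.T)
    return np.einsum("ij,ji->i", Q, solved)


def warning_leverage(p: int, n: int, variant: str = "eq9") -> float:
    """Warning leverage h*: ``eq9`` -> 3(p+1)/n; ``section32`` -> 3p/n."""
    if n <= 0:
        raise ValueError("n must be positive")
    if variant == "eq9":
        return 3.0 * (p + 1) / n
    if variant == "section32":
        return 3.0 * p / n
    raise ValueError("variant must be 'eq9' or 'section32'")


def standardized_residuals(y, yhat, dof: int) -> np.ndarray:
    """Residuals divided by the training RMSE s = sqrt(SSE/dof)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat lengths differ")
    if dof < 1:
        raise ValueError("dof must be >= 1")
    resid = y - yhat
    s = float(np.sqrt(np.sum(resid**2) / dof))
    if s == 0:
        return np.zeros_like(resid)
    return resid / s


@dataclass
class ADResult:
    """Per-compound applicability-domain table."""

    leverages: Dict[str, float]
    warning_leverage: float
    standardized_residuals: Dict[str, float]
    flags: Dict[str, str]
    partition: Dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.leverages)
        return pd.DataFrame(
            {
                "partition": [self.partition[i] for i in ids],
                "leverage": [self.leverages[i] for i in ids],
                "std_residual": [self.standardized_residuals[i] for i in ids],
                "flag": [self.flags[i] for i in ids],
            },
            index=pd.Index(ids, name="ID"),
        )

    def to_dict(self) -> dict:
        return {
            "warning_leverage": self.warning_leverage,
            "compounds": {
                i: {
                    "partition": self.partition[i],
                    "leverage": self.leverages[i],
                    "std_residual": self.standardized_residuals[i],
                    "flag": self.flags[i],
                }
                for i in self.leverages
            },
        }

    @property
    def n_outliers(self) -> int:
        return sum(1 for f in self.flags.values() if f != "in_domain")


def _flag(h: float, hstar: float, r: float) -> str:
    structural = h > hstar
    response = abs(r) > RESIDUAL_BOUND
    if structural and response:
        return "both"
    if structural:
        return "structural_outlier"
    if response:
        return "response_outlier"
    return "in_domain"


def williams_table(
    model: MLRModel,
    train: Dataset,
    test: Optional[Dataset] = None,
    hstar_variant: str = "eq9",
) -> ADResult:
    """Leverages, warning leverage, standardized residuals and flags for
    the training (and optional test) partition.

    Residuals of both partitions are standardized by the training RMSE
    with n - p - 1 degrees of freedom; no refitting.
    """
    names = model.descriptor_names
    Xtr = train.X[names]
    ytr = train.y.to_numpy(dtype=float)
    n, p = len(ytr), model.p
    hstar = warning_leverage(p, n, variant=hstar_variant)

    h_train = leverage_values(Xtr)
    total = h_train.sum()
    if not np.isclose(total, p + 1, atol=1e-8):
        raise AssertionError(f"training leverages sum to {total}, expected {p + 1}")

    yhat_tr = predict(model, Xtr)
    resid = ytr - yhat_tr
    dof = n - p - 1
    s = float(np.sqrt(np.sum(resid**2) / dof))
    # a numerically perfect fit has only rounding noise as residuals;
    # dividing by a ~1e-15-scale s would fabricate outliers
    if s <= 1e-8 * max(float(np.std(ytr)), 1e-300):
        s = 0.0
    r_train = resid / s if s > 0 else np.zeros_like(resid)

    leverages = dict(zip(train.compound_ids, h_train.tolist()))
    residuals = dict(zip(train.compound_ids, r_train.tolist()))
    partition = {i: "train" for i in train.compound_ids}

    if test is not None:
        Xte = test.X[names]
        h_test = leverage_values(Xtr, Xte)
        yhat_te = predict(model, Xte)
        r_test = (test.y.to_numpy(dtype=float) - yhat_te)
        r_test = r_test / s if s > 0 else np.zeros_like(r_test)
        leverages.update(zip(test.compound_ids, h_test.tolist()))
        residuals.update(zip(test.compound_ids, r_test.tolist()))
        partition.update({i: "test" for i in test.compound_ids})

    flags = {i: _flag(leverages[i], hstar, residuals[i]) for i in leverages}
    return ADResult(
        leverages=leverages,
        warning_leverage=hstar,
        standardized_residuals=residuals,
        flags=flags,
        partition=partition,
    )


def plot_williams(ad: ADResult, path) -> None:
    """Render the Williams plot (residuals vs leverage) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = ad.to_frame()
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for part, marker, color in (("train", "o", "tab:blue"), ("test", "s", "tab:orange")):
        sub = frame[frame["partition"] == part]
        if len(sub):
            ax.scatter(sub["leverage"], sub["std_residual"], marker=marker,
                       label=f"{part} (n={len(sub)})", color=color, alpha=0.8)
    ax.axvline(ad.warning_leverage, color="red", linestyle="--",
               label=f"h* = {ad.warning_leverage:.3f}")
    for b in (-RESIDUAL_BOUND, RESIDUAL_BOUND):
        ax.axhline(b, color="gray", linestyle=":")
    ax.set_xlabel("leverage")
    ax.set_ylabel("standardized residual")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
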