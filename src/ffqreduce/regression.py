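"""Multi-target linear regression as a Model / Results pair.

Each quality score (target) is regressed on the selected question columns by
ordinary least squares; fitting all targets at once against one shared design
matrix is what makes the problem multi-target.  The fit is the minimum-norm
least-squares solution, so rank-deficient designs (duplicate or constant
columns) are handled without error.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

__all__ = [
    "MultiTargetRegression",
    "MultiTargetRegressionResults",
    "per_goal_error",
]


class MultiTargetRegression:
    """Ordinary least squares for several targets over one feature set.

    Parameters
    ----------
    X : (n, p) array
        Feature matrix (scaled question answers).
    Y : (n, t) array
        Target matrix (scaled quality scores); a 1-D vector is treated as a
        single target.
    feature_names, target_names : sequence of str, optional
        Column labels used by :meth:`MultiTargetRegressionResults.summary`.
    """

    def __init__(self, X, Y, feature_names: Sequence[str] | None = None,
                 target_names: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.ndim != 2 or Y.ndim != 2:
            raise ValueError("X and Y must be 2-D")
        if X.shape[0] != Y.shape[0]:
            raise ValueError(f"row mismatch: X has {X.shape[0]}, Y has {Y.shape[0]}")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit")
        if Y.shape[1] < 1:
            raise ValueError("need at least 1 target")
        self.X = X
        self.Y = Y
        self.nobs, self.n_features = X.shape
        self.n_targets = Y.shape[1]
        self.feature_names = tuple(
            feature_names if feature_names is not None
            else (f"x{j}" for j in range(self.n_features))
        )
        self.target_names = tuple(
            target_names if target_names is not None
            else (f"y{t}" for t in range(self.n_targets))
        )
        if len(self.feature_names) != self.n_features:
            raise ValueError("feature_names length mismatch")
        if len(self.target_names) != self.n_targets:
            raise ValueError("target_names length mismatch")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, features: Sequence[str],
                       targets: Sequence[str]) -> "MultiTargetRegression":
        return cls(
            data[list(features)].to_numpy(dtype=float),
            data[list(targets)].to_numpy(dtype=float),
            feature_names=features,
            target_names=targets,
        )

    def fit(self) -> "MultiTargetRegressionResults":
        """Minimum-norm least squares; deterministic."""
        design = np.column_stack([np.ones(self.nobs), self.X])
        beta, _, rank, _ = scipy.linalg.lstsq(design, self.Y, lapack_driver="gelsd")
        intercept = beta[0]
        coef = beta[1:].T  # (targets, features)

        resid = self.Y - design @ beta
        rss = (resid ** 2).sum(axis=0)
        dof = max(self.nobs - rank, 1)
        sigma2 = rss / dof
        # generalized inverse keeps standard errors defined (though inflated
        # in a minimum-norm sense) when the design is rank deficient
        xtx_inv = np.linalg.pinv(design.T @ design)
        diag = np.clip(np.diag(xtx_inv), 0.0, None)  # roundoff can dip below 0
        se_all = np.sqrt(np.outer(sigma2, diag))  # (targets, p+1)

        tss = ((self.Y - self.Y.mean(axis=0)) ** 2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rsquared = np.where(tss > 0, 1.0 - rss / np.where(tss > 0, tss, 1.0), 1.0)

        return MultiTargetRegressionResults(
            model=self,
            coef=coef,
            intercept=intercept,
            bse_coef=se_all[:, 1:],
            bse_intercept=se_all[:, 0],
            rsquared=rsquared,
            rank=rank,
        )


@dataclass(frozen=True)
class MultiTargetRegressionResults:
    """Fitted coefficients, standard errors and per-target diagnostics."""

    model: MultiTargetRegression
    coef: np.ndarray          # (targets, features)
    intercept: np.ndarray     # (targets,)
    bse_coef: np.ndarray
    bse_intercept: np.ndarray
    rsquared: np.ndarray
    rank: int

    @property
    def params(self) -> pd.DataFrame:
        """Coefficients as a targets x features table."""
        return pd.DataFrame(
            self.coef,
            index=list(self.model.target_names),
            columns=list(self.model.feature_names),
        )

    def predict(self, X) -> np.ndarray:
        """Affine prediction in the scaled target space; (n, targets)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.model.n_features:
            raise ValueError(
                f"X has {X.shape[1]} columns, model expects {self.model.n_features}"
            )
        return X @ self.coef.T + self.intercept

    @property
    def resid(self) -> np.ndarray:
        return self.model.Y - self.predict(self.model.X)

    def summary(self) -> str:
        lines = [
            "Multi-target linear regression (minimum-norm OLS)",
            f"  observations: {self.model.nobs}   features: {self.model.n_features}"
            f"   targets: {self.model.n_targets}   design rank: {self.rank}",
            "",
        ]
        for t, name in enumerate(self.model.target_names):
            lines.append(f"target {name!r}   R^2 = {self.rsquared[t]:.4f}")
            table = pd.DataFrame(
                {
                    "coef": np.concatenate([[self.intercept[t]], self.coef[t]]),
                    "std err": np.concatenate(
                        [[self.bse_intercept[t]], self.bse_coef[t]]
                    ),
                },
                index=["const", *self.model.feature_names],
            )
            lines.append(table.to_string(float_format=lambda v: f"{v: .4f}"))
            lines.append("")
        return "\n".join(lines)


def per_goal_error(y_true: np.ndarray, y_pred: np.ndarray,
                   metric: str = "mae") -> np.ndarray:
    """Per-column prediction error (both arguments on the same scale)."""
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float))
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch between truths and predictions")
    if y_true.shape[0] == 0:
        raise ValueError("empty test set")
    diff = y_pred - y_true
    if metric == "mae":
        return np.abs(diff).mean(axis=0)
    if metric == "rmse":
        return np.sqrt((diff ** 2).mean(axis=0))
    raise ValueError(f"unknown error metric {metric!r}")
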