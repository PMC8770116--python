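"""Accuracy statistics on the log scale and cross-validation schemes.

Predictions spanning seven orders of magnitude are judged on log10 scale
against the 1:1 line: the residual of point *i* is
``r_i = log10(pred_i) − log10(obs_i)`` and

* ``se_log  = sqrt(Σ r_i² / n)`` — RMSE about the 1:1 line (divisor ``n``
  by default: the comparison line is fixed, not fitted; an ``n−1`` toggle
  is provided),
* ``r2_log = 1 − Σ r_i² / Σ (log10 obs_i − mean)²`` — may be negative for
  predictors worse than the observed mean (not clamped).

Three cross-validation schemes probe different generalization questions:
leave-chemical-group-out (new chemical families), leave-study-out
(experimental bias), and seeded tenfold random CV stratified by material.
The mechanistic predictor involves no fitting, so folds only partition
the evaluation; the regression predictor is refit on every training fold.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, FoldError
from .pipeline import mechanistic_predict, prepare_design, regression_predict
from .regression import DEFAULT_CANDIDATES, fit_forward_selection

__all__ = [
    "CVReport",
    "CVScheme",
    "FitMetrics",
    "FoldResult",
    "MechanisticPredictor",
    "RegressionPredictor",
    "cross_validate",
    "log_accuracy",
]


@dataclass(frozen=True)
class FitMetrics:
    r2_log: float
    se_log: float
    n: int

    def to_json_dict(self) -> dict:
        return {"r2_log": self.r2_log, "se_log": self.se_log, "n": self.n}


def log_accuracy(
    pred: Sequence[float], obs: Sequence[float], ddof: int = 0
) -> FitMetrics:
    """Log10-scale R² and standard error of ``pred`` against ``obs`` for
    the 1:1 line. ``ddof=1`` switches the Se divisor to n−1."""
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise DomainError("pred and obs must be equal-length 1-D vectors")
    n = p.size
    if n < 2:
        raise DomainError(f"need n >= 2, got {n}")
    if np.any(~np.isfinite(p)) or np.any(~np.isfinite(o)) or np.any(p <= 0) or np.any(o <= 0):
        raise DomainError("pred and obs must be finite and strictly positive")
    r = np.log10(p) - np.log10(o)
    ss_res = float(np.sum(r * r))
    lo = np.log10(o)
    ss_tot = float(np.sum((lo - lo.mean()) ** 2))
    se = float(np.sqrt(ss_res / (n - ddof)))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return FitMetrics(r2_log=r2, se_log=se, n=n)


class CVScheme(str, enum.Enum):
    LEAVE_CHEMICAL_GROUP_OUT = "leave_chemical_group_out"
    LEAVE_STUDY_OUT = "leave_study_out"
    KFOLD_RANDOM_10 = "kfold_random_10"


_SCHEME_LABEL = {
    CVScheme.LEAVE_CHEMICAL_GROUP_OUT: "chemical_group",
    CVScheme.LEAVE_STUDY_OUT: "study_id",
}


class Predictor(Protocol):
    """Anything that can (optionally) fit on a training frame and predict
    positive rates on a test frame."""

    def fit(self, train: pd.DataFrame) -> None: ...
    def predict(self, test: pd.DataFrame) -> np.ndarray: ...


class MechanisticPredictor:
    """Fit-free predictor: the mechanistic model with QSPR inputs."""

    def __init__(self, materials=None, archetypes=None, conservative: bool = False):
        self.materials = materials
        self.archetypes = archetypes
        self.conservative = conservative

    def fit(self, train: pd.DataFrame) -> None:  # nothing to fit
        return None

    def predict(self, test: pd.DataFrame) -> np.ndarray:
        out = mechanistic_predict(
            test, materials=self.materials, archetypes=self.archetypes,
            conservative=self.conservative,
        )
        return out["rate_pred"].to_numpy(dtype=float)


class RegressionPredictor:
    """Forward-selection regression refit on every training fold."""

    def __init__(
        self,
        candidates: Sequence[str] = DEFAULT_CANDIDATES,
        entry_alpha: float = 0.05,
        materials=None,
        conservative: bool = False,
    ):
        self.candidates = tuple(candidates)
        self.entry_alpha = entry_alpha
        self.materials = materials
        self.conservative = conservative
        self.model_ = None

    def fit(self, train: pd.DataFrame) -> None:
        design = prepare_design(train, materials=self.materials,
                                conservative=self.conservative)
        self.model_ = fit_forward_selection(
            design, candidates=self.candidates, entry_alpha=self.entry_alpha
        )

    def predict(self, test: pd.DataFrame) -> np.ndarray:
        if self.model_ is None:
            raise DomainError("predictor not fitted")
        return regression_predict(
            test, self.model_, materials=self.materials,
            conservative=self.conservative,
        ).to_numpy(dtype=float)


@dataclass(frozen=True)
class FoldResult:
    label: str
    n_train: int
    metrics: FitMetrics

    def to_json_dict(self) -> dict:
        return {"label": self.label, "n_train": self.n_train,
                "metrics": self.metrics.to_json_dict()}


@dataclass(frozen=True)
class CVReport:
    scheme: CVScheme
    folds: tuple[FoldResult, ...]
    pooled: FitMetrics
    seed: int | None = None  # kfold only

    def to_json_dict(self) -> dict:
        return {
            "scheme": self.scheme.value,
            "seed": self.seed,
            "pooled": self.pooled.to_json_dict(),
            "folds": [f.to_json_dict() for f in self.folds],
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)
            fh.write("\n")


def _group_folds(df: pd.DataFrame, column: str) -> list[tuple[str, np.ndarray]]:
    labels = df[column].astype(str)
    unique = sorted(labels.unique())
    if len(unique) < 2:
        raise FoldError(
            f"cannot cross-validate: all observations share one {column} ({unique})"
        )
    return [(lab, (labels == lab).to_numpy()) for lab in unique]


def _stratified_kfold(df: pd.DataFrame, k: int, seed: int) -> list[tuple[str, np.ndarray]]:
    # stratify by material so no fold loses a material entirely
    n = len(df)
    if n < k:
        raise FoldError(f"cannot form {k} folds from {n} observations")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    for _, idx in df.groupby(df["material"].astype(str)).groups.items():
        ipos = df.index.get_indexer(idx)
        perm = rng.permutation(ipos)
        fold_of[perm] = np.arange(perm.size) % k
    return [(f"fold-{j}", fold_of == j) for j in range(k)]


def cross_validate(
    df: pd.DataFrame,
    scheme: CVScheme | str,
    predictor: Predictor,
    seed: int = 0,
    n_folds: int = 10,
    obs_column: str = "rate_ug_per_10cm2_min",
    ddof: int = 0,
) -> CVReport:
    """Out-of-fold accuracy of ``predictor`` under a CV ``scheme``.

    Per-fold metrics are computed on each held-out fold (folds with fewer
    than 2 test points contribute to the pooled metrics only); pooled
    metrics gather all out-of-fold predictions into one comparison.
    """
    scheme = CVScheme(scheme)
    if scheme is CVScheme.KFOLD_RANDOM_10:
        folds = _stratified_kfold(df, n_folds, seed)
        report_seed = seed
    else:
        folds = _group_folds(df, _SCHEME_LABEL[scheme])
        report_seed = None

    obs_all = df[obs_column].to_numpy(dtype=float)
    pooled_pred = np.full(len(df), np.nan)
    results: list[FoldResult] = []
    for label, test_mask in folds:
        train = df.loc[~test_mask]
        test = df.loc[test_mask]
        predictor.fit(train)
        pred = predictor.predict(test)
        pooled_pred[test_mask] = pred
        if test_mask.sum() >= 2:
            results.append(FoldResult(
                label=label, n_train=len(train),
                metrics=log_accuracy(pred, obs_all[test_mask], ddof=ddof),
            ))
    keep = np.isfinite(pooled_pred) & (pooled_pred > 0) & (obs_all > 0)
    if keep.sum() < 2:
        raise FoldError("fewer than 2 valid out-of-fold predictions")
    pooled = log_accuracy(pooled_pred[keep], obs_all[keep], ddof=ddof)
    return CVReport(scheme=scheme, folds=tuple(results), pooled=pooled, seed=report_seed)
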