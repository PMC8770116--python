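"""Regression-based migration predictor and its forward-selection fit.

The alternative to the mechanistic model is an ordinary multiple linear
regression on the log10 scale,

    log10 R_mgr = β0 + Σ_i βi·x_i + ε,

with candidate predictors log10 C0, log10 D_p, log10 Kow, log10 K_ms and
log10 MW. Predictors enter by classic forward selection on the partial-t
p-value: at each step the candidate with the smallest p-value below
``entry_alpha`` joins the model, until none qualifies. The shipped
default model (``data/eq5_model.json``) is the published fit on the
harmonized experimental dataset,

    log10 R_mgr = 3.23 + 0.73·log10 D_p + 0.92·log10 C0 − 0.06·log10 Kow,

with units frozen inside the model document (cm²/s, µg/g, dimensionless →
µg/10cm²/min) so a model cannot silently be applied to other units.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DomainError, MissingPredictorError

__all__ = [
    "DEFAULT_CANDIDATES",
    "RegressionModel",
    "default_eq5_model",
    "fit_forward_selection",
    "predict_rmgr_eq5",
]

DEFAULT_CANDIDATES: tuple[str, ...] = (
    "log10_c0", "log10_dp", "log10_kow", "log10_kms", "log10_mw"
)

_DEFAULT_UNITS = {
    "response": "log10(ug/10cm2/min)",
    "log10_c0": "log10(ug/g)",
    "log10_dp": "log10(cm2/s)",
    "log10_kow": "dimensionless",
    "log10_kms": "dimensionless",
    "log10_mw": "log10(g/mol)",
}


@dataclass(frozen=True)
class RegressionModel:
    """A fitted (or shipped) log10-scale migration-rate regression."""

    intercept: float
    slopes: Mapping[str, float]
    included: tuple[str, ...]
    p_values: Mapping[str, float] | None = None
    conf_int: Mapping[str, tuple[float, float]] | None = None  # 95% CIs
    fit_r2: float | None = None
    fit_se: float | None = None
    n_obs: int | None = None
    units: Mapping[str, str] = field(default_factory=lambda: dict(_DEFAULT_UNITS))
    name: str = "migration-rate-regression"
    provenance: str = ""

    def __post_init__(self) -> None:
        if set(self.included) != set(self.slopes):
            raise DomainError("included predictors and slopes must match")
        for k, v in self.slopes.items():
            if not math.isfinite(v):
                raise DomainError(f"non-finite slope for {k}")

    def predict_log10_rate(self, predictors: Mapping[str, float] | pd.DataFrame):
        """log10 migration rate from predictor values (scalar mapping or frame)."""
        if isinstance(predictors, pd.DataFrame):
            missing = [k for k in self.included if k not in predictors.columns]
            if missing:
                raise MissingPredictorError(f"missing predictor columns: {missing}")
            y = np.full(len(predictors), self.intercept, dtype=float)
            for k in self.included:
                y += self.slopes[k] * predictors[k].to_numpy(dtype=float)
            return y
        missing = [k for k in self.included if k not in predictors]
        if missing:
            raise MissingPredictorError(f"missing predictor values: {missing}")
        return self.intercept + sum(
            self.slopes[k] * float(predictors[k]) for k in self.included
        )

    def predict_rate(self, predictors):
        """Migration rate in µg/10cm²/min (10**log10 prediction)."""
        return 10.0 ** self.predict_log10_rate(predictors)

    # -- JSON document -------------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "name": self.name,
            "intercept": self.intercept,
            "slopes": dict(self.slopes),
            "included": list(self.included),
            "p_values": dict(self.p_values) if self.p_values is not None else None,
            "conf_int": (
                {k: list(v) for k, v in self.conf_int.items()}
                if self.conf_int is not None else None
            ),
            "fit_r2": self.fit_r2,
            "fit_se": self.fit_se,
            "n_obs": self.n_obs,
            "units": dict(self.units),
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json_dict(cls, doc: Mapping) -> "RegressionModel":
        return cls(
            intercept=float(doc["intercept"]),
            slopes={k: float(v) for k, v in doc["slopes"].items()},
            included=tuple(doc["included"]),
            p_values=(
                {k: float(v) for k, v in doc["p_values"].items()}
                if doc.get("p_values") else None
            ),
            conf_int=(
                {k: (float(v[0]), float(v[1])) for k, v in doc["conf_int"].items()}
                if doc.get("conf_int") else None
            ),
            fit_r2=doc.get("fit_r2"),
            fit_se=doc.get("fit_se"),
            n_obs=doc.get("n_obs"),
            units=dict(doc.get("units", _DEFAULT_UNITS)),
            name=str(doc.get("name", "migration-rate-regression")),
            provenance=str(doc.get("provenance", "")),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RegressionModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_json_dict(json.load(fh))


def default_eq5_model() -> RegressionModel:
    """The published default regression shipped with the package."""
    ref = resources.files("migrisk.data").joinpath("eq5_model.json")
    with resources.as_file(ref) as path:
        return RegressionModel.from_json(path)


def predict_rmgr_eq5(
    d_p_coeff: float,
    c0: float,
    log_kow: float,
    model: RegressionModel | None = None,
) -> float:
    """Migration rate (µg/10cm²/min) from D_p (cm²/s), C0 (µg/g) and log Kow.

    Uses the shipped default regression unless another model is given.
    """
    if not (d_p_coeff > 0 and c0 > 0) or not math.isfinite(log_kow):
        raise DomainError("d_p_coeff and c0 must be > 0 and log_kow finite")
    model = model if model is not None else default_eq5_model()
    # only the three arguments are supplied: a model needing more
    # predictors raises MissingPredictorError rather than guessing
    return model.predict_rate({
        "log10_dp": math.log10(d_p_coeff),
        "log10_c0": math.log10(c0),
        "log10_kow": log_kow,
    })


def fit_forward_selection(
    design: pd.DataFrame,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    entry_alpha: float = 0.05,
    response: str = "log10_rate",
) -> RegressionModel:
    """Fit the migration-rate regression by forward selection.

    ``design`` must carry the response column and every candidate column
    (see :func:`migrisk.pipeline.prepare_design`). Selection is fully
    deterministic: ties in p-value break by candidate order. A candidate
    that makes the design matrix numerically singular is skipped with the
    selection continuing among the rest.
    """
    if design.empty:
        raise DomainError("cannot fit a regression on an empty dataset")
    data = design.dropna(subset=[response, *candidates])
    n = len(data)
    if n < 10:
        raise DomainError(f"need >= 10 complete observations, got {n}")
    y = data[response].to_numpy(dtype=float)

    included: list[str] = []
    # degenerate-response guard: a constant response has no signal, but
    # float rounding in OLS can manufacture spurious "significance"
    if np.ptp(y) == 0.0:
        return RegressionModel(
            intercept=float(y[0]), slopes={}, included=(), p_values={},
            conf_int={}, fit_r2=0.0, fit_se=0.0, n_obs=n,
            provenance=f"forward selection (entry_alpha={entry_alpha}) on {n} observations",
        )
    while True:
        best: tuple[float, str] | None = None
        for cand in candidates:
            if cand in included:
                continue
            X = sm.add_constant(data[included + [cand]].to_numpy(dtype=float))
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue  # collinear with what is already in the model
            fit = sm.OLS(y, X).fit()
            p = float(fit.pvalues[-1])
            if not math.isfinite(p):
                continue
            if best is None or p < best[0]:
                best = (p, cand)
        if best is None or best[0] >= entry_alpha:
            break
        included.append(best[1])

    X = sm.add_constant(data[included].to_numpy(dtype=float)) if included else np.ones((n, 1))
    fit = sm.OLS(y, X).fit()
    resid = y - fit.predict(X)
    ci = fit.conf_int(alpha=0.05)
    return RegressionModel(
        intercept=float(fit.params[0]),
        slopes={k: float(fit.params[i + 1]) for i, k in enumerate(included)},
        included=tuple(included),
        p_values={k: float(fit.pvalues[i + 1]) for i, k in enumerate(included)},
        conf_int={k: (float(ci[i + 1][0]), float(ci[i + 1][1])) for i, k in enumerate(included)},
        fit_r2=float(fit.rsquared) if included else 0.0,
        fit_se=float(np.sqrt(np.mean(resid ** 2))),
        n_obs=n,
        provenance=f"forward selection (entry_alpha={entry_alpha}) on {n} observations",
    )
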