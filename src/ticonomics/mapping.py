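"""Regression mappings from YGTSS tic scores to EQ-5D-Y utility indices.

Two families (ordinary Gaussian-identity linear regression and logit-link
beta regression) crossed with four predictor sets (total score; subscale
scores; each plus sex) give eight candidate mappings. Fits report
coefficients, standard errors, p-values, AIC/BIC, adjusted R-squared and
held-in predictive accuracy (MAE/RMSE), and serialize to JSON. A fixed
reference coefficient set for the total-score linear model feeds the
downstream cost-utility analysis.
"""
from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.othermod.betareg import BetaModel

from .cohort import PatientRecord

__all__ = [
    "GAUSSIAN_IDENTITY",
    "BETA_LOGIT",
    "MODEL_PREDICTORS",
    "REFERENCE_INTERCEPT",
    "REFERENCE_SLOPE",
    "MappingSpec",
    "FittedMapping",
    "ValidationMetrics",
    "FittingError",
    "reference_model1",
    "reference_predictor",
    "transform_boundaries",
    "fit_mapping",
    "predict_utility",
    "validation_metrics",
    "compare_models",
    "screen_covariates",
]

GAUSSIAN_IDENTITY = "gaussian_identity"
BETA_LOGIT = "beta_logit"
FAMILIES = (GAUSSIAN_IDENTITY, BETA_LOGIT)

MODEL_PREDICTORS: dict[int, tuple[str, ...]] = {
    1: ("ygtss_total",),
    2: ("ygtss_motor", "ygtss_vocal"),
    3: ("ygtss_total", "sex"),
    4: ("ygtss_motor", "ygtss_vocal", "sex"),
}

MIN_FIT_ROWS = 10

# Reference total-score linear mapping used by the cost-utility model.
REFERENCE_INTERCEPT = 0.9881
REFERENCE_SLOPE = -0.0035


class FittingError(ValueError):
    """Raised when a mapping fit cannot proceed (too few rows, singular design)."""


@dataclass(frozen=True)
class MappingSpec:
    """Which regression family and which of the four predictor sets."""

    family: str
    model: int

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.model not in MODEL_PREDICTORS:
            raise ValueError(f"model must be in 1..4, got {self.model!r}")

    @property
    def predictors(self) -> tuple[str, ...]:
        return MODEL_PREDICTORS[self.model]


@dataclass
class FittedMapping:
    spec: MappingSpec
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    n_used: int
    aic: float
    bic: float
    adj_r2: float
    boundary_n: int | None = None  # beta family only
    precision: float | None = None  # beta family dispersion (phi)
    data_checksum: str | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "spec": {"family": self.spec.family, "model": self.spec.model},
            "coefficients": self.coefficients,
            "standard_errors": self.standard_errors,
            "p_values": self.p_values,
            "n_used": self.n_used,
            "aic": self.aic,
            "bic": self.bic,
            "adj_r2": self.adj_r2,
            "boundary_n": self.boundary_n,
            "precision": self.precision,
            "data_checksum": self.data_checksum,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FittedMapping":
        text = Path(source).read_text(encoding="utf-8") if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            spec=MappingSpec(**payload["spec"]),
            coefficients=payload["coefficients"],
            standard_errors=payload["standard_errors"],
            p_values=payload["p_values"],
            n_used=payload["n_used"],
            aic=payload["aic"],
            bic=payload["bic"],
            adj_r2=payload["adj_r2"],
            boundary_n=payload.get("boundary_n"),
            precision=payload.get("precision"),
            data_checksum=payload.get("data_checksum"),
        )


@dataclass(frozen=True)
class ValidationMetrics:
    mae: float
    rmse: float

    def __post_init__(self) -> None:
        if not 0 <= self.mae <= self.rmse + 1e-12:
            raise ValueError(f"need 0 <= MAE <= RMSE, got mae={self.mae}, rmse={self.rmse}")


def reference_model1() -> FittedMapping:
    """The fixed total-score linear mapping consumed by the decision tree."""
    return FittedMapping(
        spec=MappingSpec(GAUSSIAN_IDENTITY, 1),
        coefficients={"intercept": REFERENCE_INTERCEPT, "ygtss_total": REFERENCE_SLOPE},
        standard_errors={"intercept": 0.0139, "ygtss_total": 0.0008},
        p_values={},
        n_used=144,
        aic=math.nan,
        bic=math.nan,
        adj_r2=math.nan,
    )


def reference_predictor(ygtss_total) -> np.ndarray | float:
    """Predicted utility index from the reference linear mapping."""
    return REFERENCE_INTERCEPT + REFERENCE_SLOPE * np.asarray(ygtss_total, dtype=float)


def transform_boundaries(utilities, n_participants: int) -> np.ndarray:
    """Squeeze observed utilities into (0, 1) via ``(y*(N-1) + 0.5) / N``.

    Order-preserving affine map; for y in [0, 1] the image is
    ``[0.5/N, 1 - 0.5/N]``, which beta regression requires.
    """
    if n_participants < 2:
        raise ValueError(f"n_participants must be >= 2, got {n_participants}")
    y = np.asarray(utilities, dtype=float)
    return (y * (n_participants - 1) + 0.5) / n_participants


def invert_boundary_transform(transformed, n_participants: int) -> np.ndarray:
    if n_participants < 2:
        raise ValueError(f"n_participants must be >= 2, got {n_participants}")
    t = np.asarray(transformed, dtype=float)
    return (t * n_participants - 0.5) / (n_participants - 1)


def _records_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sex": [r.sex for r in records],
            "age": [r.age for r in records],
            "height": [np.nan if r.height is None else r.height for r in records],
            "weight": [np.nan if r.weight is None else r.weight for r in records],
            "ygtss_motor": [r.ygtss_motor for r in records],
            "ygtss_vocal": [r.ygtss_vocal for r in records],
            "ygtss_total": [r.ygtss_total for r in records],
            "eq5dy_utility": [r.eq5dy_utility for r in records],
        }
    )


def _checksum(records: Sequence[PatientRecord]) -> str:
    digest = hashlib.sha256()
    for r in records:
        digest.update(f"{r.id}|{r.ygtss_total}|{r.eq5dy_utility!r};".encode())
    return digest.hexdigest()[:16]


def _adjusted_r2(r2: float, n: int, n_predictors: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_predictors - 1)


def fit_mapping(
    records: Sequence[PatientRecord],
    spec: MappingSpec,
    boundary_n: int | None = None,
) -> FittedMapping:
    """Fit one family/predictor-set combination on complete rows.

    Rows missing a required covariate are dropped (``n_used`` reports the
    remainder). For the beta family the response is first passed through
    :func:`transform_boundaries` with ``N = boundary_n`` (default: the
    number of rows entering the fit) and fitted by maximum likelihood with
    a logit mean link and constant precision.
    """
    frame = _records_frame(records)
    terms = list(spec.predictors)
    used = frame.dropna(subset=terms + ["eq5dy_utility"])
    n_used = len(used)
    if n_used < MIN_FIT_ROWS:
        raise FittingError(
            f"need at least {MIN_FIT_ROWS} complete rows, got {n_used}"
        )
    for term in terms:
        if used[term].nunique() < 2:
            raise FittingError(f"predictor {term!r} is constant in the fitting data")

    X = sm.add_constant(used[terms].astype(float), has_constant="add")
    X = X.rename(columns={"const": "intercept"})
    y = used["eq5dy_utility"].to_numpy(dtype=float)
    names = list(X.columns)

    if spec.family == GAUSSIAN_IDENTITY:
        result = sm.OLS(y, X).fit()
        coef = {name: float(result.params[name]) for name in names}
        se = {name: float(result.bse[name]) for name in names}
        pvals = {name: float(result.pvalues[name]) for name in names}
        return FittedMapping(
            spec=spec,
            coefficients=coef,
            standard_errors=se,
            p_values=pvals,
            n_used=n_used,
            aic=float(result.aic),
            bic=float(result.bic),
            adj_r2=float(result.rsquared_adj),
            data_checksum=_checksum(records),
        )

    n_boundary = boundary_n if boundary_n is not None else n_used
    y_t = transform_boundaries(y, n_boundary)
    model = BetaModel(y_t, X)
    result = model.fit(disp=False)
    # params order: mean coefficients then the (log-)precision parameter
    params_arr = np.asarray(result.params, dtype=float)
    bse_arr = np.asarray(result.bse, dtype=float)
    pval_arr = np.asarray(result.pvalues, dtype=float)
    coef = {name: float(params_arr[i]) for i, name in enumerate(names)}
    se = {name: float(bse_arr[i]) for i, name in enumerate(names)}
    pvals = {name: float(pval_arr[i]) for i, name in enumerate(names)}
    fitted_mean = expit(np.asarray(X, dtype=float) @ np.array([coef[n] for n in names]))
    r2 = float(np.corrcoef(fitted_mean, y_t)[0, 1]) ** 2
    return FittedMapping(
        spec=spec,
        coefficients=coef,
        standard_errors=se,
        p_values=pvals,
        n_used=n_used,
        aic=float(result.aic),
        bic=float(result.bic),
        adj_r2=_adjusted_r2(r2, n_used, len(terms)),
        boundary_n=n_boundary,
        precision=float(np.exp(params_arr[-1])),
        data_checksum=_checksum(records),
    )


def _covariate_matrix(fit: FittedMapping, covariates) -> tuple[np.ndarray, list[str]]:
    terms = [t for t in fit.coefficients if t != "intercept"]
    if isinstance(covariates, Sequence) and covariates and isinstance(covariates[0], PatientRecord):
        frame = _records_frame(covariates)
    elif isinstance(covariates, pd.DataFrame):
        frame = covariates
    elif isinstance(covariates, Mapping):
        frame = pd.DataFrame({k: np.atleast_1d(v) for k, v in covariates.items()})
    else:
        raise TypeError("covariates must be records, a DataFrame or a mapping")
    missing = [t for t in terms if t not in frame.columns]
    if missing:
        raise ValueError(f"missing covariates: {', '.join(missing)}")
    return frame[terms].to_numpy(dtype=float), terms


def predict_utility(fit: FittedMapping, covariates) -> np.ndarray:
    """Predicted utility index under a fitted (or reference) mapping.

    Gaussian family: the raw linear predictor, deliberately unclipped.
    Beta family: inverse-logit of the linear predictor.
    """
    X, terms = _covariate_matrix(fit, covariates)
    beta = np.array([fit.coefficients[t] for t in terms])
    linear = fit.coefficients["intercept"] + X @ beta
    if fit.spec.family == BETA_LOGIT:
        return expit(linear)
    return linear


def validation_metrics(
    fit: FittedMapping,
    records: Sequence[PatientRecord],
    invert_boundary: bool = False,
) -> ValidationMetrics:
    """MAE and RMSE of the fit against observed utilities.

    Computed on the original utility scale by default; ``invert_boundary``
    additionally maps beta-family predictions back through the inverse of
    the boundary transform before comparing.
    """
    frame = _records_frame(records)
    terms = [t for t in fit.coefficients if t != "intercept"]
    used = frame.dropna(subset=terms + ["eq5dy_utility"])
    if used.empty:
        raise ValueError("no usable rows for validation")
    predicted = predict_utility(fit, used)
    if invert_boundary and fit.spec.family == BETA_LOGIT:
        predicted = invert_boundary_transform(predicted, fit.boundary_n)
    observed = used["eq5dy_utility"].to_numpy(dtype=float)
    errors = observed - predicted
    return ValidationMetrics(
        mae=float(np.mean(np.abs(errors))),
        rmse=float(np.sqrt(np.mean(errors**2))),
    )


_BEST_TOL = 1e-9


def compare_models(
    fits: Sequence[FittedMapping],
    metrics: Sequence[ValidationMetrics],
) -> pd.DataFrame:
    """Rank fits of the same data by AIC, BIC, adjusted R², MAE and RMSE.

    One row per fit in input order; ``best_*`` columns flag the winner per
    criterion, with ties flagging every tied fit. Per-coefficient p-values
    are flattened into ``p_<term>`` columns so covariate screening is
    visible. Fits on different record sets are refused.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    if len(fits) != len(metrics):
        raise ValueError("fits and metrics must align")
    checksums = {f.data_checksum for f in fits}
    if len(checksums) > 1:
        raise ValueError("fits were produced on different record sets")

    rows = []
    for fit, metric in zip(fits, metrics):
        row = {
            "family": fit.spec.family,
            "model": fit.spec.model,
            "n_used": fit.n_used,
            "aic": fit.aic,
            "bic": fit.bic,
            "adj_r2": fit.adj_r2,
            "mae": metric.mae,
            "rmse": metric.rmse,
        }
        for term, p in fit.p_values.items():
            row[f"p_{term}"] = p
        rows.append(row)
    table = pd.DataFrame(rows)

    lower_better = {"aic": True, "bic": True, "adj_r2": False, "mae": True, "rmse": True}
    for criterion, minimize in lower_better.items():
        values = table[criterion]
        target = values.min() if minimize else values.max()
        table[f"best_{criterion}"] = (values - target).abs() <= _BEST_TOL
    return table


def screen_covariates(
    records: Sequence[PatientRecord],
    family: str = GAUSSIAN_IDENTITY,
    base_model: int = 1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """p-value of each demographic covariate added singly to a base model.

    Adds sex, age, height and weight one at a time to the base predictor
    set and reports the added term's p-value and whether it clears
    ``alpha``. Rows with the candidate covariate missing are dropped for
    that candidate only.
    """
    frame = _records_frame(records)
    base_terms = list(MODEL_PREDICTORS[base_model])
    rows = []
    for candidate in ("sex", "age", "height", "weight"):
        if candidate in base_terms:
            continue
        terms = base_terms + [candidate]
        used = frame.dropna(subset=terms + ["eq5dy_utility"])
        if len(used) < MIN_FIT_ROWS or used[candidate].nunique() < 2:
            rows.append({"covariate": candidate, "p_value": np.nan, "significant": False})
            continue
        X = sm.add_constant(used[terms].astype(float), has_constant="add")
        y = used["eq5dy_utility"].to_numpy(dtype=float)
        if family == GAUSSIAN_IDENTITY:
            p = float(sm.OLS(y, X).fit().pvalues[candidate])
        else:
            y_t = transform_boundaries(y, len(used))
            result = BetaModel(y_t, X).fit(disp=False)
            p = float(np.asarray(result.pvalues)[list(X.columns).index(candidate)])
        rows.append({"covariate": candidate, "p_value": p, "significant": p < alpha})
    return pd.DataFrame(rows).set_index("covariate")
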