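"""Simultaneous regression models for chelate stability constants.

For the four metals Mn, Fe, Co, Ni the stability constants of the amino
acid chelates are modelled with a single quadratic form in the
connectivity index, normalized on the Ni complex of the same ligand:

    log K = a1 * x**2 + a2 * x + a3 * chi_Ni + b,
    x = chi(MB) - chi(NiB)

for log K1 (mono-complex indices) and analogously with the bis-complex
indices for log beta2.  The x-normalization places Ni at x = 0 so the
quadratic terms encode the Irving-Williams metal trend, while the
chi_Ni term carries the linear ligand trend.  Cu deviates strongly from
the quadratic metal trend (it is by far the strongest Lewis acid of the
series) and is excluded from fitting, though its complexes are fully
supported in the index computation and in the per-metal/per-ligand
diagnostic fits.

Fitting is ordinary least squares; model quality is reported as the
Pearson correlation r between observed and fitted values, the standard
error of estimate S.E. = sqrt(RSS / (N - 1)), and its leave-one-out
counterpart S.E._cv computed from the cross-validation residuals with
the same N - 1 convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .fixtures import MODEL_METALS, StabilityRecord

__all__ = [
    "FeatureRow",
    "ModelFit",
    "LooResult",
    "ExcludedMetalError",
    "AbsentValueError",
    "make_features",
    "fit_model",
    "loo_cv",
    "predict",
    "fit_linear_per_metal",
    "fit_quadratic_per_ligand",
]

ChiTable = Mapping[tuple[str, str, str], float]

_SPECIES = {"K1": "mono", "B2": "bis"}
_RESPONSE_ATTR = {"K1": "logK1", "B2": "logB2"}


class ExcludedMetalError(ValueError):
    """Raised when Cu (or another unsupported metal) enters the simultaneous fit."""


class AbsentValueError(ValueError):
    """Raised when the requested stability constant was never measured."""


@dataclass(frozen=True)
class FeatureRow:
    """Design-matrix row for one record: (x^2, x, chi_Ni) plus the response."""

    metal: str
    ligand: str
    x: float
    x2: float
    yref: float
    response: float | None


@dataclass
class ModelFit:
    """An OLS fit of the simultaneous model, Table-2 style.

    Coefficients are ordered (a1, a2, a3, intercept) for the regressors
    (x^2, x, chi_Ni, 1).
    """

    response: str
    records: list[StabilityRecord]
    features: list[FeatureRow]
    a1: float
    a2: float
    a3: float
    intercept: float
    se_coef: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    r: float
    se_fit: float

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def coef(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3, self.intercept])


@dataclass
class LooResult:
    """Leave-one-out cross-validation summary for a simultaneous model."""

    response: str
    records: list[StabilityRecord]
    loo_pred: np.ndarray
    loo_residuals: np.ndarray
    se_cv: float
    max_cv_error: float


def _feature_xy(metal: str, ligand: str, chi: ChiTable, response: str
                ) -> tuple[float, float]:
    species = _SPECIES[response]
    x = chi[(metal, ligand, species)] - chi[("Ni", ligand, species)]
    yref = chi[("Ni", ligand, species)]
    return x, yref


def make_features(record: StabilityRecord, chi: ChiTable, response: str
                  ) -> FeatureRow:
    """Build the model features for one experimental record.

    ``response`` is ``"K1"`` (mono-complex indices) or ``"B2"``
    (bis-complex indices).  The Ni reference index for the ligand is used
    even when Ni itself has no measured constant for that ligand.
    """
    if response not in _SPECIES:
        raise ValueError(f"response must be 'K1' or 'B2', got {response!r}")
    if record.metal not in MODEL_METALS:
        raise ExcludedMetalError(
            f"{record.metal} is excluded from the simultaneous model "
            f"(supported: {MODEL_METALS}); Cu complexes deviate from the "
            "quadratic metal trend"
        )
    value = getattr(record, _RESPONSE_ATTR[response])
    if value is None:
        raise AbsentValueError(
            f"no measured log{response} for {record.metal}/{record.ligand}"
        )
    x, yref = _feature_xy(record.metal, record.ligand, chi, response)
    return FeatureRow(record.metal, record.ligand, x, x * x, yref, value)


def _select(records: Iterable[StabilityRecord], response: str
            ) -> list[StabilityRecord]:
    attr = _RESPONSE_ATTR[response]
    return [
        r for r in records
        if r.metal in MODEL_METALS and getattr(r, attr) is not None
    ]


def _design(features: Sequence[FeatureRow]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([[f.x2, f.x, f.yref, 1.0] for f in features])
    y = np.array([f.response for f in features])
    return X, y


def fit_model(records: Iterable[StabilityRecord], chi: ChiTable, response: str
              ) -> ModelFit:
    """Fit the simultaneous model by OLS on all usable records.

    Records for Cu and records lacking the requested constant are
    filtered out (12 remain for log K1, 14 for log beta2 with the
    built-in table).  Raises on a rank-deficient design rather than
    regularizing silently.
    """
    usable = _select(records, response)
    if len(usable) < 5:
        raise ValueError(
            f"need at least 5 records with log{response}, got {len(usable)}"
        )
    features = [make_features(r, chi, response) for r in usable]
    X, y = _design(features)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix in simultaneous fit")
    res = sm.OLS(y, X).fit()
    fitted = res.fittedvalues
    residuals = y - fitted
    n = len(y)
    r = float(np.corrcoef(y, fitted)[0, 1])
    se_fit = float(np.sqrt(np.sum(residuals**2) / (n - 1)))
    return ModelFit(
        response=response,
        records=usable,
        features=features,
        a1=float(res.params[0]),
        a2=float(res.params[1]),
        a3=float(res.params[2]),
        intercept=float(res.params[3]),
        se_coef=np.asarray(res.bse),
        fitted=np.asarray(fitted),
        residuals=residuals,
        r=r,
        se_fit=se_fit,
    )


def loo_cv(records: Iterable[StabilityRecord], chi: ChiTable, response: str
           ) -> LooResult:
    """Leave-one-out cross-validation of the simultaneous model.

    Each usable record is predicted from a model refitted on the other
    N - 1; S.E._cv = sqrt(sum of squared cv residuals / (N - 1)).
    """
    usable = _select(records, response)
    features = [make_features(r, chi, response) for r in usable]
    X, y = _design(features)
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        beta = np.linalg.lstsq(X[mask], y[mask], rcond=None)[0]
        preds[i] = X[i] @ beta
    resid = y - preds
    se_cv = float(np.sqrt(np.sum(resid**2) / (n - 1)))
    return LooResult(
        response=response,
        records=usable,
        loo_pred=preds,
        loo_residuals=resid,
        se_cv=se_cv,
        max_cv_error=float(np.max(np.abs(resid))),
    )


def predict(fit: ModelFit, metal: str, ligand: str, chi: ChiTable) -> float:
    """Model estimate for any supported (metal, ligand), measured or not."""
    if metal not in MODEL_METALS:
        raise ExcludedMetalError(
            f"{metal} is outside the simultaneous model (supported: "
            f"{MODEL_METALS}); Cu is excluded because its complexes deviate "
            "from the quadratic trend of the series"
        )
    x, yref = _feature_xy(metal, ligand, chi, fit.response)
    return fit.a1 * x * x + fit.a2 * x + fit.a3 * yref + fit.intercept


def fit_linear_per_metal(
    records: Iterable[StabilityRecord], chi: ChiTable, response: str, metal: str
) -> tuple[float, float, float]:
    """Least-squares line of the response against chi for one metal.

    Returns (slope, intercept, r).  All five metals are allowed here,
    Cu included — only the simultaneous model excludes it.  The slope is
    negative for every metal: stability falls from glycine to leucine.
    """
    attr = _RESPONSE_ATTR[response]
    species = _SPECIES[response]
    pts = [
        (chi[(metal, r.ligand, species)], getattr(r, attr))
        for r in records
        if r.metal == metal and getattr(r, attr) is not None
    ]
    if len(pts) < 2:
        raise ValueError(f"need >= 2 points for {metal}, got {len(pts)}")
    xs, ys = map(np.asarray, zip(*pts))
    slope, intercept = np.polyfit(xs, ys, 1)
    r = float(np.corrcoef(xs, ys)[0, 1])
    return float(slope), float(intercept), r


def fit_quadratic_per_ligand(
    records: Iterable[StabilityRecord], chi: ChiTable, response: str, ligand: str
) -> tuple[np.ndarray, float | None]:
    """Quadratic fit of the response vs chi across the non-Cu metals of a ligand.

    Returns ``(coeffs, cu_deviation)`` with ``coeffs = (c2, c1, c0)`` in
    numpy polynomial order, and the deviation of the observed Cu value
    from the extrapolated quadratic (positive: Cu more stable than the
    trend), or ``None`` if Cu has no measurement for the ligand.
    """
    attr = _RESPONSE_ATTR[response]
    species = _SPECIES[response]
    pts = [
        (chi[(r.metal, ligand, species)], getattr(r, attr))
        for r in records
        if r.ligand == ligand and r.metal in MODEL_METALS
        and getattr(r, attr) is not None
    ]
    if len(pts) < 3:
        raise ValueError(
            f"need >= 3 non-Cu metals with log{response} for {ligand}, "
            f"got {len(pts)}"
        )
    xs, ys = map(np.asarray, zip(*pts))
    coeffs = np.polyfit(xs, ys, 2)
    cu = [
        getattr(r, attr) for r in records
        if r.metal == "Cu" and r.ligand == ligand and getattr(r, attr) is not None
    ]
    deviation = None
    if cu:
        x_cu = chi[("Cu", ligand, species)]
        deviation = float(cu[0] - np.polyval(coeffs, x_cu))
    return coeffs, deviation
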