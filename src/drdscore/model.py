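"""The 14-feature linear risk score for platinum resistance.

The published predictor is a linear combination of the 14 genomic features

    score = -0.00133*HRD + 0.000969*MHID + 0.0003*CN_load
            - 0.00078*DUP_1_100KB - 0.00024*SNV_load + 0.000013*NEOANTIGENS
            - 0.000085*AC1 + 0.00046*AC4 - 0.0013*AC7 + 0.00138*AC10
            + 0.00041*AC12 + 0.000678*AC18 - 0.00093*AC20 - 0.00081356*AC24

with scores strictly above the threshold 0.7584 predicting platinum
resistance.  The formula is applied verbatim on raw feature scales, with a
configurable intercept defaulting to 0.

Note on scale: the published coefficient magnitudes (~1e-3) times typical
feature scales (10-10^3) give scores of order +/-0.1, while the published
threshold is 0.7584; the two cannot both be literal without an unprinted
intercept or transformation.  The score is implemented exactly as printed
and the intercept left to the user; refitting (below) yields an internally
consistent score/threshold pair.

Refitting is L1-penalized (LASSO) logistic regression of resistance on the
14 features, the penalty chosen by leave-one-out cross-validation
maximizing mean held-out log-likelihood.  Features are standardized
internally for the fit and the coefficients returned on the raw feature
scale.  The statsmodels-style surface is :class:`DRDModel` (data in) /
:class:`DRDResults` (estimates, CV report, ``summary()``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .features import FEATURE_FIELDS, FIELD_TO_COLUMN, COLUMN_TO_FIELD, FeatureVector
from .io import FEATURE_COLUMNS, CohortTable, ValidationError

__all__ = ["DRDCoefficients", "DRDResult", "DRDModel", "DRDResults",
           "drdscore", "classify", "fit_lasso_loocv",
           "PUBLISHED_WEIGHTS", "PUBLISHED_THRESHOLD"]

# Published regression coefficients, keyed by internal field name.
PUBLISHED_WEIGHTS = {
    "hrd": -0.00133,
    "mhid": 0.000969,
    "cn_load": 0.0003,
    "dup_1_100kb": -0.00078,
    "snv_load": -0.00024,
    "neoantigens": 0.000013,
    "ac1": -0.000085,
    "ac4": 0.00046,
    "ac7": -0.0013,
    "ac10": 0.00138,
    "ac12": 0.00041,
    "ac18": 0.000678,
    "ac20": -0.00093,
    "ac24": -0.00081356,
}
PUBLISHED_THRESHOLD = 0.7584


@dataclass(frozen=True)
class DRDCoefficients:
    """One weight per feature, an optional intercept and the decision threshold."""

    weights: dict[str, float]
    intercept: float = 0.0
    threshold: float = PUBLISHED_THRESHOLD

    def __post_init__(self) -> None:
        if list(self.weights) != FEATURE_FIELDS:
            missing = [f for f in FEATURE_FIELDS if f not in self.weights]
            extra = [f for f in self.weights if f not in FEATURE_FIELDS]
            raise ValidationError(
                f"weights must cover exactly the 14 features in order; "
                f"missing {missing}, unexpected {extra}"
            )
        if not np.isfinite(self.threshold):
            raise ValidationError("threshold must be finite")

    @classmethod
    def published(cls) -> "DRDCoefficients":
        return cls(weights=dict(PUBLISHED_WEIGHTS))

    def as_array(self) -> np.ndarray:
        return np.array([self.weights[f] for f in FEATURE_FIELDS])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "weights": {FIELD_TO_COLUMN[k]: v for k, v in self.weights.items()},
            "intercept": self.intercept,
            "threshold": self.threshold,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DRDCoefficients":
        payload = json.loads(Path(path).read_text())
        weights = {COLUMN_TO_FIELD[k]: float(v)
                   for k, v in payload["weights"].items()}
        weights = {f: weights[f] for f in FEATURE_FIELDS}
        return cls(weights=weights,
                   intercept=float(payload.get("intercept", 0.0)),
                   threshold=float(payload.get("threshold", PUBLISHED_THRESHOLD)))


@dataclass(frozen=True)
class DRDResult:
    """A score and its thresholded call for one patient."""

    score: float
    label: Literal["resistant-predicted", "sensitive-predicted"]


def drdscore(features: FeatureVector, coeffs: DRDCoefficients | None = None) -> float:
    """The linear predictor: intercept + sum of coefficient * feature.

    Exactly linear at full floating precision; non-finite features are
    rejected by :class:`FeatureVector` construction.
    """
    if coeffs is None:
        coeffs = DRDCoefficients.published()
    return float(coeffs.intercept + coeffs.as_array() @ features.as_array())


def classify(score: float, coeffs: DRDCoefficients | None = None) -> DRDResult:
    """Resistant-predicted iff the score is strictly above the threshold.

    Ties at the threshold resolve to sensitive-predicted (the published
    rule counts patients *above* the cutoff).
    """
    if coeffs is None:
        coeffs = DRDCoefficients.published()
    label = ("resistant-predicted" if score > coeffs.threshold
             else "sensitive-predicted")
    return DRDResult(score=float(score), label=label)


class DRDModel:
    """Risk-score model bound to a cohort feature table.

    Parameters
    ----------
    features : DataFrame
        One row per patient, the 14 feature columns (canonical CSV naming
        ``HRD`` .. ``AC24`` or internal lower-case naming).
    groups : sequence of str
        Per-patient labels, ``sensitive`` or ``resistant`` (resistant is
        the positive class).
    """

    def __init__(self, features: pd.DataFrame, groups: Sequence[str]):
        features = features.copy()
        if set(FEATURE_COLUMNS) <= set(features.columns):
            features = features[FEATURE_COLUMNS].rename(columns=COLUMN_TO_FIELD)
        missing = [f for f in FEATURE_FIELDS if f not in features.columns]
        if missing:
            raise ValidationError("missing: " + ", ".join(missing))
        self.exog = features[FEATURE_FIELDS].astype(float)
        if self.exog.isna().any().any():
            raise ValidationError("missing feature values are not allowed")
        groups = pd.Series(list(groups), index=self.exog.index, dtype=str).str.lower()
        bad = set(groups.unique()) - {"sensitive", "resistant"}
        if bad:
            raise ValidationError(f"unrecognized group labels: {sorted(bad)}")
        self.groups = groups
        self.endog = (groups == "resistant").astype(int).to_numpy()
        counts = np.bincount(self.endog, minlength=2)
        if counts.min() == 0:
            raise ValidationError("cohort must contain both classes")
        if counts.min() < 2:
            raise ValidationError("need at least 2 patients per class")

    @classmethod
    def from_cohort(cls, cohort: CohortTable) -> "DRDModel":
        if cohort.groups.isna().any():
            raise ValidationError("group labels must be non-missing for fitting")
        return cls(cohort.features, cohort.groups)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group_col: str = "group") -> "DRDModel":
        return cls(df, df[group_col])

    # -- scoring with fixed (e.g. published) coefficients ------------------

    def score(self, coeffs: DRDCoefficients | None = None) -> pd.Series:
        """Apply a fixed coefficient vector to every patient (raw scales)."""
        if coeffs is None:
            coeffs = DRDCoefficients.published()
        vals = coeffs.intercept + self.exog.to_numpy() @ coeffs.as_array()
        return pd.Series(vals, index=self.exog.index, name="drdscore")

    # -- refitting ---------------------------------------------------------

    def _standardize(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        X = self.exog.to_numpy()
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        constant = sd == 0
        if constant.any():
            names = [FEATURE_FIELDS[i] for i in np.where(constant)[0]]
            warnings.warn(f"constant features retained unscaled: {names}",
                          stacklevel=3)
            sd = np.where(constant, 1.0, sd)
        return (X - mean) / sd, mean, sd

    def fit(
        self,
        penalties: Sequence[float] | None = None,
        seed: int = 0,
        threshold: float = PUBLISHED_THRESHOLD,
    ) -> "DRDResults":
        """LASSO-logistic refit with leave-one-out cross-validation.

        ``penalties`` is a grid of inverse regularization strengths C
        (sklearn convention; smaller C = stronger L1 penalty), default
        ``logspace(-2, 3, 11)``.  The C maximizing mean held-out
        log-likelihood wins; ties go to the smaller C (sparser model).
        Deterministic given seed and grid.
        """
        if penalties is None:
            penalties = np.logspace(-2, 3, 11)
        penalties = np.asarray(sorted(penalties), dtype=float)
        Xs, mean, sd = self._standardize()
        y = self.endog
        n = len(y)

        def make(C: float) -> LogisticRegression:
            return LogisticRegression(
                l1_ratio=1.0, C=C, solver="saga", max_iter=20_000,
                tol=1e-8, random_state=seed,
            )

        eps = 1e-12
        cv_ll = np.zeros(len(penalties))
        with warnings.catch_warnings():
            # weakly penalized grid points may stop at max_iter; that only
            # blurs their CV score, so keep the exploratory fits quiet
            from sklearn.exceptions import ConvergenceWarning
            warnings.simplefilter("ignore", ConvergenceWarning)
            for j, C in enumerate(penalties):
                ll = 0.0
                for i in range(n):
                    mask = np.ones(n, dtype=bool)
                    mask[i] = False
                    if len(np.unique(y[mask])) < 2:
                        raise ValidationError(
                            "leave-one-out fold lost a class; need >= 2 per class"
                        )
                    clf = make(C).fit(Xs[mask], y[mask])
                    if np.all(clf.coef_ == 0):
                        # all-slopes-zero solution: the unpenalized intercept's
                        # exact optimum is the class log-odds (saga stalls here
                        # because the loss term is scaled by C)
                        p = float(y[mask].mean())
                    else:
                        p = clf.predict_proba(Xs[i:i + 1])[0, 1]
                    p = min(max(p, eps), 1 - eps)
                    ll += np.log(p) if y[i] == 1 else np.log(1 - p)
                cv_ll[j] = ll / n
        # ties at the max go to the smallest C (grid is sorted ascending)
        best = int(np.flatnonzero(np.isclose(cv_ll, cv_ll.max()))[0])
        C_best = float(penalties[best])

        clf = make(C_best).fit(Xs, y)
        beta_std = clf.coef_[0]
        b0_std = float(clf.intercept_[0])
        if np.all(beta_std == 0):
            b0_std = float(np.log(y.mean() / (1.0 - y.mean())))
        beta_raw = beta_std / sd
        intercept_raw = b0_std - float((beta_std * mean / sd).sum())
        coeffs = DRDCoefficients(
            weights={f: float(b) for f, b in zip(FEATURE_FIELDS, beta_raw)},
            intercept=intercept_raw,
            threshold=threshold,
        )
        cv_table = pd.DataFrame({"C": penalties, "mean_heldout_loglik": cv_ll})
        return DRDResults(model=self, coefficients=coeffs, cv_table=cv_table,
                          penalty=C_best, seed=seed)


@dataclass
class DRDResults:
    """Fit results: raw-scale coefficients, CV report, scoring helpers."""

    model: DRDModel
    coefficients: DRDCoefficients
    cv_table: pd.DataFrame = field(repr=False)
    penalty: float
    seed: int

    @property
    def params(self) -> pd.Series:
        s = pd.Series(self.coefficients.weights, dtype=float)
        s["intercept"] = self.coefficients.intercept
        return s

    def predict(self, features: pd.DataFrame | None = None) -> pd.Series:
        """Linear predictor on new (or the training) feature table."""
        if features is None:
            return self.model.score(self.coefficients)
        sub = DRDModel.__new__(DRDModel)
        feats = features.copy()
        if set(FEATURE_COLUMNS) <= set(feats.columns):
            feats = feats[FEATURE_COLUMNS].rename(columns=COLUMN_TO_FIELD)
        vals = (self.coefficients.intercept
                + feats[FEATURE_FIELDS].to_numpy() @ self.coefficients.as_array())
        return pd.Series(vals, index=feats.index, name="drdscore")

    def predict_proba(self, features: pd.DataFrame | None = None) -> pd.Series:
        """Logistic probability of resistance from the refitted coefficients."""
        eta = self.predict(features)
        return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=eta.index,
                         name="p_resistant")

    def summary(self) -> str:
        n = len(self.model.endog)
        n_res = int(self.model.endog.sum())
        lines = [
            "Platinum-resistance risk score: LASSO-logistic refit",
            "=" * 56,
            f"patients: {n} ({n - n_res} sensitive / {n_res} resistant)",
            f"selected penalty C: {self.penalty:g} "
            f"(LOO mean held-out log-likelihood)",
            f"intercept: {self.coefficients.intercept:+.6g}",
            "-" * 56,
            f"{'feature':<14}{'coefficient':>16}",
        ]
        for name, w in self.coefficients.weights.items():
            lines.append(f"{FIELD_TO_COLUMN[name]:<14}{w:>+16.6g}")
        lines.append("-" * 56)
        nz = sum(1 for w in self.coefficients.weights.values() if w != 0)
        lines.append(f"non-zero coefficients: {nz}/14")
        return "\n".join(lines)


def fit_lasso_loocv(
    cohort: CohortTable,
    penalties: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[DRDCoefficients, pd.DataFrame]:
    """Refit the risk score on a cohort; returns coefficients and the CV report."""
    results = DRDModel.from_cohort(cohort).fit(penalties=penalties, seed=seed)
    return results.coefficients, results.cv_table
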