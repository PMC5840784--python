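"""Scikit-learn style estimators wrapping the scoring and derivation code.

:class:`CovariateCoder` is a stateless transformer taking raw registry
records (or a canonical-schema DataFrame) to the coded design columns of
one model equation; :class:`TraumaSurvivalModel` is a logistic
classifier over those columns, either fitted by weighted IRLS or
pre-loaded with a published coefficient set.  Both compose with sklearn
pipelines and model selection.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .exceptions import ModelInputError
from .models import (
    MODEL_COVARIATES,
    CoefficientSet,
    build_covariates,
    survival_probability,
)
from .registry import NOT_MEASURABLE, Injury, PatientRecord, parse_packed_injuries


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    """Build records from a canonical-schema DataFrame (as written by
    :func:`trisskit.registry.write_registry` / read by pandas)."""

    def val(row, col, default=None):
        v = row.get(col, default)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return v

    records = []
    for _, row in frame.iterrows():
        spo2 = val(row, "spo2_pct")
        if isinstance(spo2, str):
            spo2 = NOT_MEASURABLE if spo2 == "NM" else float(spo2)
        inj = row.get("injuries", "")
        if isinstance(inj, str):
            injuries: tuple[Injury, ...] = parse_packed_injuries(inj)
        elif inj is None or (isinstance(inj, float) and np.isnan(inj)):
            injuries = ()
        else:
            injuries = tuple(inj)
        gcs = val(row, "gcs_total")
        bmr = val(row, "bmr")
        surv = val(row, "survived")
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                site=str(val(row, "site", "unknown") or "unknown"),
                age_years=float(row["age_years"]),
                mechanism=str(val(row, "mechanism") or "unknown"),
                gcs_total=None if gcs is None else int(gcs),
                bmr=None if bmr is None else int(bmr),
                sbp_mmhg=val(row, "sbp_mmhg"),
                rr_bpm=val(row, "rr_bpm"),
                spo2_pct=spo2,
                injuries=injuries,
                hours_from_event=val(row, "hours_from_event"),
                transferred=bool(val(row, "transferred") or False),
                survived=None if surv is None else bool(surv),
            )
        )
    return records


class CovariateCoder(TransformerMixin, BaseEstimator):
    """Code raw patient records into one model's covariate columns.

    Parameters
    ----------
    model_id : which equation's covariates to emit.
    rts_scale : "weighted" (0-7.8408 RTS) or "trts" (0-12 sum).
    missing_policy : missing-SpO2 handling (see
        :func:`trisskit.registry.resolve_missing`).

    ``transform`` accepts a sequence of :class:`PatientRecord` or a
    canonical-schema DataFrame and returns a DataFrame with one column
    per covariate, ``NaN`` marking records the model cannot score.
    """

    def __init__(
        self,
        model_id: str = "ntriss_like",
        rts_scale: str = "weighted",
        missing_policy: str = "spo2-zero-if-unmeasurable-only",
    ):
        self.model_id = model_id
        self.rts_scale = rts_scale
        self.missing_policy = missing_policy

    def fit(self, X, y=None):  # stateless
        if self.model_id not in MODEL_COVARIATES:
            raise ModelInputError(f"unknown model_id {self.model_id!r}")
        self.feature_names_out_ = list(MODEL_COVARIATES[self.model_id])
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "feature_names_out_")
        records: Sequence[PatientRecord]
        if isinstance(X, pd.DataFrame):
            records = frame_to_records(X)
        else:
            records = list(X)
        rows = []
        for r in records:
            cov, _ = build_covariates(
                r,
                self.model_id,
                rts_scale=self.rts_scale,
                missing_policy=self.missing_policy,
            )
            rows.append({k: (np.nan if v is None else float(v)) for k, v in cov.items()})
        return pd.DataFrame(rows, columns=self.feature_names_out_)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_out_")
        return np.asarray(self.feature_names_out_, dtype=object)


class TraumaSurvivalModel(ClassifierMixin, BaseEstimator):
    """Logistic survival model Ps = 1/(1 + e^-b) over coded covariates.

    ``fit`` runs the weighted IRLS of
    :func:`trisskit.derivation.fit_weighted_logistic` (``sample_weight``
    carries the site-balancing weights); alternatively
    :meth:`from_coefficients` returns an estimator pre-loaded with a
    packaged coefficient set.  ``predict_proba`` columns follow
    ``classes_ = [0, 1]`` (died, survived).

    Fitted attributes: ``intercept_``, ``coef_``, ``se_``,
    ``converged_``, ``n_iter_``, ``log_likelihood_``,
    ``coefficient_set_``.
    """

    def __init__(
        self,
        model_id: str = "ntriss_like",
        mechanism: str = "blunt",
        tol: float = 1e-8,
        ll_tol: float = 1e-10,
        max_iter: int = 100,
    ):
        self.model_id = model_id
        self.mechanism = mechanism
        self.tol = tol
        self.ll_tol = ll_tol
        self.max_iter = max_iter

    # ------------------------------------------------------------------
    def fit(self, X, y, sample_weight: Optional[np.ndarray] = None):
        from .derivation import fit_weighted_logistic  # avoid import cycle

        names = None
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
        Xv = check_array(X, dtype=float)
        yv = np.asarray(y, dtype=float).ravel()
        res = fit_weighted_logistic(
            Xv,
            yv,
            sample_weight,
            column_names=names,
            model_id=self.model_id,
            mechanism=self.mechanism,
            tol=self.tol,
            ll_tol=self.ll_tol,
            max_iter=self.max_iter,
        )
        self._set_fitted(res.coefficient_set)
        self.se_ = np.asarray(res.standard_errors)
        self.converged_ = res.converged
        self.n_iter_ = res.iterations
        self.log_likelihood_ = res.log_likelihood
        self.diagnostic_ = res.diagnostic
        self.fit_result_ = res
        return self

    def _set_fitted(self, cs: CoefficientSet) -> None:
        self.coefficient_set_ = cs
        self.intercept_ = np.array([cs.intercept])
        self.coef_ = np.asarray(cs.slopes, dtype=float)[None, :]
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = len(cs.slopes)
        self.feature_names_in_ = np.asarray(cs.covariate_order, dtype=object)

    @classmethod
    def from_coefficients(cls, cs: CoefficientSet) -> "TraumaSurvivalModel":
        """A pre-fitted estimator carrying a published coefficient set."""
        est = cls(model_id=cs.model_id, mechanism=cs.mechanism)
        est._set_fitted(cs)
        est.converged_ = True
        est.n_iter_ = 0
        est.se_ = np.full(len(cs.slopes) + 1, np.nan)
        est.log_likelihood_ = np.nan
        est.diagnostic_ = None
        return est

    # ------------------------------------------------------------------
    def decision_function(self, X) -> np.ndarray:
        """Linear predictor b for each row."""
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame):
            order = list(self.feature_names_in_)
            missing = [c for c in order if c not in X.columns]
            if missing:
                raise ModelInputError(f"missing covariate column(s) {missing}")
            X = X[order]
        Xv = check_array(X, dtype=float)
        if Xv.shape[1] != self.n_features_in_:
            raise ModelInputError(
                f"expected {self.n_features_in_} covariates, got {Xv.shape[1]}"
            )
        return self.intercept_[0] + Xv @ self.coef_[0]

    def predict_proba(self, X) -> np.ndarray:
        b = self.decision_function(X)
        ps = np.array([survival_probability(v) for v in b])
        return np.column_stack([1.0 - ps, ps])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


__all__ = ["CovariateCoder", "TraumaSurvivalModel", "frame_to_records"]
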