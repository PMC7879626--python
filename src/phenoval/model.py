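"""Gradient-boosted probability model for T1D case status.

A LightGBM classifier trained on the screened binary feature matrix; the
predicted probability per patient ("predictive value of being a true
patient") is what the probabilistic confusion matrix consumes.  Ten-fold
stratified cross-validated AUC is computed inside the training data, and
gain-based variable importance (normalised to sum to one) is exposed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import lightgbm as lgb

from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

#: defaults: 500 trees, depth 4, learning rate 0.05, early stopping on a
#: 10% stratified validation split
DEFAULT_PARAMS = {
    "n_estimators": 500,
    "max_depth": 4,
    "num_leaves": 15,
    "learning_rate": 0.05,
    "min_child_samples": 10,
    "early_stopping_rounds": 50,
    "validation_fraction": 0.1,
}


class TrainingError(ValueError):
    pass


class ScoringError(ValueError):
    pass


@dataclass
class ModelBundle:
    booster: lgb.Booster
    feature_names: list[str]
    seed: int
    params: dict
    cv_auc: list[float]

    @property
    def mean_cv_auc(self) -> float:
        return float(np.mean(self.cv_auc)) if self.cv_auc else float("nan")

    def importance(self) -> pd.DataFrame:
        """Gain-based importance, normalised to sum to 1, descending."""
        gain = self.booster.feature_importance(importance_type="gain").astype(float)
        total = gain.sum()
        if total > 0:
            gain = gain / total
        return (
            pd.DataFrame({"feature": self.feature_names, "importance": gain})
            .sort_values(["importance", "feature"], ascending=[False, True])
            .reset_index(drop=True)
        )

    def save(self, path: str | Path) -> None:
        obj = {
            "model": self.booster.model_to_string(),
            "feature_names": self.feature_names,
            "seed": self.seed,
            "params": self.params,
            "cv_auc": self.cv_auc,
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        obj = json.loads(Path(path).read_text())
        return cls(
            booster=lgb.Booster(model_str=obj["model"]),
            feature_names=obj["feature_names"],
            seed=obj["seed"],
            params=obj["params"],
            cv_auc=obj["cv_auc"],
        )


def _sanitize(names) -> list[str]:
    # LightGBM forbids JSON-special characters in feature names; the
    # canonical "namespace:code" names are kept in the bundle and restored
    # in importance tables.
    return [str(n).replace(":", "__") for n in names]


def _lgb_params(params: dict, seed: int) -> dict:
    return {
        "objective": "binary",
        "max_depth": params["max_depth"],
        "num_leaves": params["num_leaves"],
        "learning_rate": params["learning_rate"],
        "min_child_samples": params["min_child_samples"],
        "seed": seed,
        "deterministic": True,
        "force_row_wise": True,
        "verbosity": -1,
        "num_threads": 1,
    }


def _fit_booster(
    X: pd.DataFrame, y: np.ndarray, params: dict, seed: int
) -> lgb.Booster:
    frac = params["validation_fraction"]
    stop = params["early_stopping_rounds"]
    callbacks = [lgb.log_evaluation(period=0)]
    if frac and stop:
        X_tr, X_val, y_tr, y_val = train_test_split(
            X, y, test_size=frac, stratify=y, random_state=seed
        )
        train_set = lgb.Dataset(X_tr, label=y_tr)
        valid = [lgb.Dataset(X_val, label=y_val, reference=train_set)]
        callbacks.append(lgb.early_stopping(stop, verbose=False))
    else:
        train_set = lgb.Dataset(X, label=y)
        valid = []
    return lgb.train(
        _lgb_params(params, seed),
        train_set,
        num_boost_round=params["n_estimators"],
        valid_sets=valid,
        callbacks=callbacks,
    )


def train(
    features: FeatureMatrix,
    labels: pd.Series,
    seed: int = 0,
    params: dict | None = None,
    cv_folds: int = 10,
) -> ModelBundle:
    """Fit the boosted-tree model; deterministic given the seed.

    ``labels`` is a 0/1 Series indexed by patient_id covering the feature
    rows.  Fold-wise AUC from stratified ``cv_folds``-fold cross-validation
    is stored in the bundle (``cv_folds=0`` skips it).
    """
    params = {**DEFAULT_PARAMS, **(params or {})}
    X = features.matrix.astype(float)
    canonical = list(X.columns)
    X.columns = _sanitize(canonical)
    y = labels.loc[X.index].to_numpy().astype(int)
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise TrainingError("need at least two patients of each class")

    cv_auc: list[float] = []
    if cv_folds:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            booster = _fit_booster(X.iloc[tr], y[tr], params, seed + fold)
            pred = booster.predict(X.iloc[te])
            cv_auc.append(float(roc_auc_score(y[te], pred)))

    booster = _fit_booster(X, y, params, seed)
    return ModelBundle(
        booster=booster,
        feature_names=canonical,
        seed=seed,
        params=params,
        cv_auc=cv_auc,
    )


def score(bundle: ModelBundle, features: FeatureMatrix) -> pd.DataFrame:
    """Per-patient case probability; columns aligned to the training set.

    Columns the model never saw are dropped (with a warning); training
    columns absent here are filled with zeros.
    """
    X = features.matrix
    extra = [c for c in X.columns if c not in bundle.feature_names]
    if extra:
        logger.warning("dropping %d feature(s) unseen in training", len(extra))
    overlap = [c for c in bundle.feature_names if c in X.columns]
    if not overlap:
        raise ScoringError("no overlap between scoring and training features")
    aligned = X.reindex(columns=bundle.feature_names, fill_value=0).astype(float)
    aligned.columns = _sanitize(bundle.feature_names)
    p = bundle.booster.predict(aligned)
    return pd.DataFrame(
        {"patient_id": list(X.index), "p_case": np.clip(p, 0.0, 1.0)}
    )


def calibration_slope(scores: pd.DataFrame, truth: pd.Series) -> float:
    """Logistic recalibration slope of the scores against known status.

    Slope 1 means the predicted log-odds are on the right scale; the
    evaluation pipeline logs a warning when the slope leaves [0.8, 1.2],
    since the probabilistic confusion matrix assumes usable calibration.
    """
    from sklearn.linear_model import LogisticRegression

    p = np.clip(scores.set_index("patient_id")["p_case"].loc[truth.index], 1e-6, 1 - 1e-6)
    logit = np.log(p / (1 - p)).to_numpy().reshape(-1, 1)
    y = truth.to_numpy().astype(int)
    fit = LogisticRegression(C=1e6, solver="lbfgs").fit(logit, y)
    return float(fit.coef_[0, 0])
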