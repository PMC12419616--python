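"""Per-horizon gradient-boosted mortality classifiers.

One independent LightGBM binary classifier is trained per prediction
horizon, on that horizon's balanced case-control dataset.  The ensemble
satisfies three contracts relied on downstream: probability and raw-margin
prediction, native routing of missing values, and exact per-feature
additive attribution in margin space (via ``pred_contrib``).

Performance is reported as patient-level 5-fold cross-validated AUROC:
folds partition patients, never rows, so a patient's positive and negative
rows always land in the same fold.  Optional hyperparameter search is a
seeded random search over a boosted-tree space, scored on the validation
patients only; test rows are never touched by selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterSampler

from .labeling import HorizonDataset, build_horizon_dataset, grouped_split
from .preprocess import CohortMatrices

__all__ = [
    "DEFAULT_PARAMS",
    "SEARCH_SPACE",
    "HorizonModel",
    "ModelFamily",
    "train_horizon_model",
    "patient_folds",
    "cv_auroc",
    "train_model_family",
]

# Fast-mode defaults: deterministic mid-size ensembles that train in about
# a second on cohort-scale data; enough boosting rounds to resolve the
# individual contributions of many weak analytes.
DEFAULT_PARAMS: dict = {
    "objective": "binary",
    "n_estimators": 400,
    "learning_rate": 0.05,
    "num_leaves": 31,
    "max_depth": -1,
    "min_child_samples": 20,
    "reg_alpha": 0.0,
    "reg_lambda": 1.0,
    "colsample_bytree": 0.9,
    "n_jobs": 1,
    "deterministic": True,
    "force_row_wise": True,
    "verbosity": -1,
}

# Random-search space over the usual boosted-tree knobs.
SEARCH_SPACE: dict = {
    "learning_rate": [0.02, 0.05, 0.08, 0.1, 0.15],
    "num_leaves": [7, 15, 31, 63],
    "max_depth": [-1, 3, 5, 8],
    "min_child_samples": [5, 10, 20, 40],
    "reg_alpha": [0.0, 0.1, 1.0],
    "reg_lambda": [0.0, 0.1, 1.0, 10.0],
}


@dataclass
class HorizonModel:
    horizon: int
    booster: lgb.LGBMClassifier
    features: list[str]
    params: dict
    seed: int
    cv_mean_auroc: float | None = None
    cv_sd_auroc: float | None = None
    n_patients: int = 0

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.booster.predict_proba(X[self.features])[:, 1]

    def predict_margin(self, X: pd.DataFrame) -> np.ndarray:
        return self.booster.predict(X[self.features], raw_score=True)

    def predict_contrib(self, X: pd.DataFrame) -> np.ndarray:
        """Exact additive attributions; shape (n, P+1), last column = base."""
        return self.booster.predict(X[self.features], pred_contrib=True)


@dataclass
class ModelFamily:
    models: dict[int, HorizonModel] = field(default_factory=dict)
    metrics: pd.DataFrame | None = None

    @property
    def horizons(self) -> list[int]:
        return sorted(self.models)

    def __getitem__(self, horizon: int) -> HorizonModel:
        return self.models[horizon]

    def auroc_horizon_spearman(self) -> float:
        """Spearman correlation between horizon and mean CV AUROC."""
        m = self.metrics
        return float(spearmanr(m["horizon"], m["mean_auroc"]).statistic)


def _fit(X: pd.DataFrame, y: np.ndarray, params: dict,
         seed: int) -> lgb.LGBMClassifier:
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    clf = lgb.LGBMClassifier(random_state=seed, **params)
    clf.fit(X, y)
    return clf


def train_horizon_model(
    dataset: HorizonDataset,
    split: pd.DataFrame,
    search_budget: int = 0,
    seed: int = 0,
    params: dict | None = None,
    refit_with_validation: bool = True,
) -> HorizonModel:
    """Fit one horizon's classifier on its training patients.

    With ``search_budget > 0``, that many random hyperparameter draws are
    scored by AUROC on the validation patients and the best is kept; the
    final model is refit on train (+validation when
    ``refit_with_validation``).  Test rows are never seen.
    """
    base = dict(DEFAULT_PARAMS if params is None else params)
    frame = dataset.frame.merge(split, on="patient_id")
    feats = dataset.features
    tr = frame[frame["assignment"] == "train"]
    va = frame[frame["assignment"] == "validation"]

    if search_budget > 0:
        if len(va) == 0:
            raise ValueError("hyperparameter search needs a validation split")
        best, best_auc = None, -np.inf
        sampler = ParameterSampler(SEARCH_SPACE, n_iter=search_budget,
                                   random_state=seed)
        for cand in sampler:
            trial = {**base, **cand}
            clf = _fit(tr[feats], tr["label"].to_numpy(), trial, seed)
            auc = roc_auc_score(va["label"],
                                clf.predict_proba(va[feats])[:, 1])
            if auc > best_auc:
                best, best_auc = trial, auc
        base = best

    final_rows = pd.concat([tr, va]) if refit_with_validation else tr
    clf = _fit(final_rows[feats], final_rows["label"].to_numpy(), base, seed)
    return HorizonModel(horizon=dataset.horizon, booster=clf, features=feats,
                        params=base, seed=seed,
                        n_patients=dataset.n_patients)


def patient_folds(patients, folds: int, seed: int) -> dict:
    """Shuffle patients and deal them round-robin into ``folds`` folds."""
    patients = np.asarray(sorted(patients))
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(patients)
    return dict(zip(shuffled, np.arange(len(patients)) % folds))


def cv_auroc(
    dataset: HorizonDataset,
    folds: int = 5,
    seed: int = 0,
    params: dict | None = None,
) -> tuple[float, float]:
    """Patient-level k-fold cross-validated AUROC, mean and sd over folds.

    Patients (not rows) are shuffled and partitioned; each fold's model is
    trained on the remaining patients' rows and scored on the held-out rows.
    A fold whose held-out rows are single-class is skipped with a warning
    (cannot occur for balanced horizon datasets).
    """
    patients = dataset.frame["patient_id"].unique()
    if len(patients) < folds:
        raise ValueError(f"need >= {folds} patients for {folds}-fold CV")
    assignments = patient_folds(patients, folds, seed)
    fold_of = dataset.frame["patient_id"].map(assignments).to_numpy()
    feats = dataset.features
    params = dict(DEFAULT_PARAMS if params is None else params)

    aucs = []
    for k in range(folds):
        held = fold_of == k
        y_held = dataset.frame.loc[held, "label"]
        if y_held.nunique() < 2:
            warnings.warn(f"fold {k} held-out rows are single-class; skipped",
                          stacklevel=2)
            continue
        clf = _fit(dataset.frame.loc[~held, feats],
                   dataset.frame.loc[~held, "label"].to_numpy(), params, seed)
        scores = clf.predict_proba(dataset.frame.loc[held, feats])[:, 1]
        aucs.append(roc_auc_score(y_held, scores))
    if not aucs:
        raise ValueError("every fold was single-class")
    return float(np.mean(aucs)), float(np.std(aucs, ddof=1))


def train_model_family(
    matrices: CohortMatrices,
    horizons: list[int] | range = range(1, 91),
    negative_day: int = 168,
    min_observed: int = 1,
    search_budget: int = 0,
    cv_folds: int = 5,
    seed: int = 0,
    params: dict | None = None,
) -> ModelFamily:
    """Train one model per horizon and collect patient-level CV metrics.

    Horizons with an empty dataset are skipped and reported in the metrics
    table with NaN AUROC.  Sparse horizon grids (e.g. every 15 days) are the
    intended fast mode.
    """
    family = ModelFamily()
    records = []
    for n in horizons:
        try:
            ds = build_horizon_dataset(matrices, n, negative_day=negative_day,
                                       min_observed=min_observed)
        except ValueError as err:
            warnings.warn(f"horizon {n} skipped: {err}", stacklevel=2)
            records.append({"horizon": n, "n_patients": 0,
                            "mean_auroc": np.nan, "sd_auroc": np.nan})
            continue
        split = grouped_split(ds, seed=seed)
        model = train_horizon_model(ds, split, search_budget=search_budget,
                                    seed=seed, params=params)
        model.cv_mean_auroc, model.cv_sd_auroc = cv_auroc(
            ds, folds=cv_folds, seed=seed, params=model.params)
        family.models[n] = model
        records.append({"horizon": n, "n_patients": ds.n_patients,
                        "mean_auroc": model.cv_mean_auroc,
                        "sd_auroc": model.cv_sd_auroc})
    family.metrics = pd.DataFrame.from_records(records)
    return family
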