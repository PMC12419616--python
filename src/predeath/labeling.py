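"""Per-horizon case-control datasets from resampled patient matrices.

For a prediction horizon of ``n`` days, the positive example is a patient's
feature vector ``n`` days before death and the negative example is the same
patient's vector at a fixed reference day far from death (default 168 days,
i.e. 24 weeks).  Only patients with data available at both anchor days are
included, which makes every horizon dataset exactly 1:1 balanced by
construction.  Because each patient contributes one positive and one
negative row, all train/validation/test splitting is done at the patient
level to prevent leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import CohortMatrices

__all__ = ["HorizonDataset", "build_horizon_dataset", "grouped_split"]

META_COLUMNS = ["patient_id", "role", "label"]


@dataclass
class HorizonDataset:
    """Feature matrix + labels for one horizon.

    ``frame`` has columns patient_id, role ('positive'/'negative'),
    label (1/0), then one column per feature (NaN = missing).
    """

    horizon: int
    negative_day: int
    frame: pd.DataFrame

    @property
    def features(self) -> list[str]:
        return [c for c in self.frame.columns if c not in META_COLUMNS]

    @property
    def patients(self) -> list[str]:
        return list(self.frame["patient_id"].unique())

    @property
    def n_patients(self) -> int:
        return self.frame["patient_id"].nunique()

    def X(self) -> pd.DataFrame:
        return self.frame[self.features]

    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)


def build_horizon_dataset(
    matrices: CohortMatrices,
    n: int,
    negative_day: int = 168,
    min_observed: int = 1,
) -> HorizonDataset:
    """Assemble the horizon-``n`` dataset.

    A patient is included iff at least ``min_observed`` features are
    unmasked at day ``n`` AND at day ``negative_day`` ("data available at
    both time points").  Raises if no patient qualifies.
    """
    if not 1 <= n < negative_day:
        raise ValueError(f"horizon must satisfy 1 <= n < negative_day "
                         f"({n} vs {negative_day})")
    if negative_day > matrices.t_max:
        raise ValueError(f"negative_day {negative_day} beyond grid "
                         f"({matrices.t_max})")
    pos = matrices.day_frame(n)
    neg = matrices.day_frame(negative_day)
    ok = (pos.notna().sum(axis=1) >= min_observed) & \
         (neg.notna().sum(axis=1) >= min_observed)
    included = pos.index[ok]
    if len(included) == 0:
        raise ValueError(f"no patient has data at both day {n} and day "
                         f"{negative_day}")

    def rows(day_frame: pd.DataFrame, role: str, label: int) -> pd.DataFrame:
        out = day_frame.loc[included].reset_index()
        out.insert(1, "role", role)
        out.insert(2, "label", label)
        return out

    frame = pd.concat([rows(pos, "positive", 1), rows(neg, "negative", 0)],
                      ignore_index=True)
    return HorizonDataset(horizon=n, negative_day=negative_day, frame=frame)


def grouped_split(
    dataset: HorizonDataset,
    test_fraction: float = 0.2,
    validation_fraction_of_train: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Patient-level train/validation/test assignment.

    The cohort is split 80/20 into train and test, and the training portion
    further 4:1 into train and validation.  Both rows of a patient always
    share one assignment.  Returns a frame (patient_id, assignment).
    """
    patients = np.array(sorted(dataset.frame["patient_id"].unique()))
    m = len(patients)
    if m < 5:
        raise ValueError("need at least 5 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    n_test = int(round(m * test_fraction))
    n_val = int(round((m - n_test) * validation_fraction_of_train))
    assignment = np.empty(m, dtype=object)
    assignment[order[:n_test]] = "test"
    assignment[order[n_test:n_test + n_val]] = "validation"
    assignment[order[n_test + n_val:]] = "train"
    if not (assignment == "train").any():
        raise ValueError("split fractions leave no training patients")
    return pd.DataFrame({"patient_id": patients, "assignment": assignment})
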