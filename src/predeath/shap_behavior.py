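"""Attribution trajectories: per-horizon Shapley panels and scaled behaviors.

For each horizon model, every row's prediction decomposes exactly into a
base value plus one additive contribution (phi) per feature, in raw-margin
(log-odds) space.  The analysis then

1. keeps only *correct positives* — rows truly n days before death whose
   predicted death probability clears the classification threshold;
2. averages each feature's signed phi over those rows (m_j);
3. scales the means by the horizon's largest absolute feature mean, so the
   dominant feature's trajectory touches +/-1 at every horizon.

The features x horizons grid of scaled means is the *behavior matrix*: the
temporal trajectory of each analyte's importance to impending death.
Signed means are used (on correct positives attributions are predominantly
risk-increasing); rankings and proportions use absolute values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .labeling import HorizonDataset
from .modeling import HorizonModel, ModelFamily

__all__ = [
    "ShapPanel",
    "ShapBehaviorMatrix",
    "attribute_panel",
    "select_correct_positives",
    "scaled_mean_shap",
    "behavior_matrix",
    "compute_panels",
    "rank_and_proportions",
]

ADDITIVITY_TOL = 1e-6


@dataclass
class ShapPanel:
    """Per-row attributions for one horizon.

    ``phi`` is rows x features (margin units); ``meta`` carries patient_id,
    label, probability, margin and base per row, aligned with ``phi``.
    """

    horizon: int
    phi: pd.DataFrame
    meta: pd.DataFrame

    def __len__(self) -> int:
        return len(self.phi)

    @property
    def features(self) -> list[str]:
        return list(self.phi.columns)

    def additivity_gap(self) -> np.ndarray:
        """|base + sum(phi) - margin| per row; contract: < 1e-6 everywhere."""
        total = self.meta["base"].to_numpy() + self.phi.sum(axis=1).to_numpy()
        return np.abs(total - self.meta["margin"].to_numpy())

    def to_tidy(self) -> pd.DataFrame:
        tidy = self.phi.copy()
        tidy.insert(0, "patient_id", self.meta["patient_id"].to_numpy())
        tidy = tidy.melt(id_vars="patient_id", var_name="feature",
                         value_name="phi")
        tidy.insert(0, "horizon", self.horizon)
        return tidy


@dataclass
class ShapBehaviorMatrix:
    """Scaled mean attributions on a features x horizons grid.

    ``scaled`` holds s_j(n) in [-1, 1] with max_j |s_j(n)| = 1 per horizon;
    ``means`` the unscaled signed means m_j(n); ``scale`` the per-horizon
    divisor max_j |m_j(n)|; ``n_rows`` the retained row count per horizon.
    Horizons with no retained rows are absent from all four.
    """

    scaled: pd.DataFrame
    means: pd.DataFrame
    scale: pd.Series
    n_rows: pd.Series

    @property
    def horizons(self) -> list[int]:
        return list(self.scaled.columns)

    @property
    def features(self) -> list[str]:
        return list(self.scaled.index)

    def rank_at(self, horizon: int) -> pd.Series:
        """1-based importance rank by |s_j| at ``horizon`` (1 = top)."""
        s = self.scaled[horizon].abs()
        order = sorted(s.index, key=lambda f: (-s[f], f))
        return pd.Series(np.arange(1, len(order) + 1), index=order,
                         name=horizon)


def attribute_panel(model: HorizonModel, rows: pd.DataFrame,
                    check_additivity: bool = True) -> ShapPanel:
    """Exact tree-Shapley attributions for ``rows`` of the model's horizon.

    ``rows`` must carry patient_id, label and the model's feature columns
    (typically a held-out subset of the horizon dataset's frame).
    """
    missing = [f for f in model.features if f not in rows.columns]
    if missing:
        raise ValueError(f"rows lack model features {missing}")
    contrib = model.predict_contrib(rows)
    phi = pd.DataFrame(contrib[:, :-1], columns=model.features)
    meta = pd.DataFrame({
        "patient_id": rows["patient_id"].to_numpy(),
        "label": rows["label"].to_numpy(dtype=int),
        "probability": model.predict_proba(rows),
        "margin": model.predict_margin(rows),
        "base": contrib[:, -1],
    })
    panel = ShapPanel(horizon=model.horizon, phi=phi, meta=meta)
    if check_additivity:
        gap = panel.additivity_gap()
        if len(gap) and gap.max() > ADDITIVITY_TOL:
            raise AssertionError(
                f"additivity violated: max gap {gap.max():.2e}")
    return panel


def select_correct_positives(panel: ShapPanel,
                             threshold: float = 0.5) -> ShapPanel:
    """Keep rows with true label 1 and predicted probability >= threshold."""
    keep = ((panel.meta["label"] == 1) &
            (panel.meta["probability"] >= threshold)).to_numpy()
    return ShapPanel(horizon=panel.horizon,
                     phi=panel.phi.loc[keep].reset_index(drop=True),
                     meta=panel.meta.loc[keep].reset_index(drop=True))


def scaled_mean_shap(panel: ShapPanel) -> tuple[pd.Series, float]:
    """Signed per-feature mean attributions, max-scaled.

    Returns ``(s, scale)`` with ``s_j = m_j / max_k |m_k|`` and ``scale``
    the divisor.  Raises on an empty panel or all-zero attributions.
    """
    if len(panel) == 0:
        raise ValueError("empty panel: no correct positives retained")
    m = panel.phi.mean(axis=0)
    scale = float(m.abs().max())
    if scale == 0.0:
        raise ValueError("all mean attributions are zero; scale undefined")
    return m / scale, scale


def behavior_matrix(panels: dict[int, ShapPanel],
                    threshold: float = 0.5,
                    already_filtered: bool = False) -> ShapBehaviorMatrix:
    """Assemble the behavior matrix from per-horizon panels.

    Each panel is restricted to correct positives (unless
    ``already_filtered``); horizons whose filtered panel is empty are left
    out of the matrix rather than recorded as zeros.
    """
    scaled_cols, mean_cols, scales, counts = {}, {}, {}, {}
    for n in sorted(panels):
        panel = panels[n] if already_filtered else \
            select_correct_positives(panels[n], threshold=threshold)
        if len(panel) == 0:
            continue
        s, scale = scaled_mean_shap(panel)
        scaled_cols[n] = s
        mean_cols[n] = panel.phi.mean(axis=0)
        scales[n] = scale
        counts[n] = len(panel)
    if not scaled_cols:
        raise ValueError("no horizon retained any correct positives")
    return ShapBehaviorMatrix(
        scaled=pd.DataFrame(scaled_cols),
        means=pd.DataFrame(mean_cols),
        scale=pd.Series(scales, name="scale"),
        n_rows=pd.Series(counts, name="n_rows"),
    )


def compute_panels(
    family: ModelFamily,
    datasets: dict[int, HorizonDataset],
    split: pd.DataFrame | None = None,
    subset: str = "test",
) -> dict[int, ShapPanel]:
    """Attribution panels for every trained horizon.

    By default only held-out test rows are attributed; pass ``subset="all"``
    (small synthetic runs) to attribute the whole cohort.
    """
    panels: dict[int, ShapPanel] = {}
    for n in family.horizons:
        frame = datasets[n].frame
        if subset != "all":
            if split is None:
                raise ValueError("a split plan is required for subset!='all'")
            keep = frame["patient_id"].isin(
                split.loc[split["assignment"] == subset, "patient_id"])
            frame = frame[keep]
        panels[n] = attribute_panel(family[n], frame)
    return panels


def rank_and_proportions(
    matrix: ShapBehaviorMatrix,
    horizon: int,
    k: int = 10,
    focus: list[str] | None = None,
) -> tuple[list[str], pd.Series]:
    """Top-k features and importance shares at one horizon.

    The top-k list orders features by |s_j| descending (ties broken
    lexicographically).  Proportions are percentages of each feature's
    |mean attribution| relative to the total over all features; when
    ``focus`` is given, non-focus features are pooled into ``"others"``.
    The shares always sum to 100.
    """
    if horizon not in matrix.scaled.columns:
        raise ValueError(f"horizon {horizon} not available")
    s = matrix.scaled[horizon]
    if k > len(s):
        warnings.warn(f"k={k} exceeds feature count {len(s)}; truncating",
                      stacklevel=2)
        k = len(s)
    top = sorted(s.index, key=lambda f: (-abs(s[f]), f))[:k]

    absm = matrix.means[horizon].abs()
    shares = 100.0 * absm / absm.sum()
    if focus is not None:
        pooled = shares.loc[[f for f in shares.index if f in set(focus)]]
        others = shares.drop(pooled.index).sum()
        shares = pd.concat([pooled, pd.Series({"others": others})])
    return top, shares
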