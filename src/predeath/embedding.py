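"""2D embeddings of time-stacked patient-state vectors.

Rows are (patient, horizon) pairs restricted to correct positives, stacked
across all used horizons into one matrix so that movement over time is
meaningful in a shared coordinate frame.  Two paired variants are built on
an identical row index: attribution vectors, and per-feature standardized
raw lab values.  Dimensionality reduction needs complete rows, so features
with too much grid missingness (default: >= 10% masked patients at any used
horizon) are removed first, and remaining incomplete (patient, horizon)
rows are then dropped.

The claim under test — temporal structure visible in attribution space but
not in raw-value space — is quantified by the *temporal-separation score*:
the larger of the two absolute Spearman correlations between horizon and an
embedding coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .preprocess import CohortMatrices
from .shap_behavior import ShapPanel

__all__ = [
    "StackedStateMatrix",
    "missingness_filter",
    "stack_state_matrices",
    "embed_2d",
    "temporal_separation_score",
    "UMAP_DEFAULTS",
]

# Embedding hyperparameters used throughout: euclidean metric,
# 10 neighbors, min_dist 0.5, seed 0.
UMAP_DEFAULTS: dict = {"n_neighbors": 10, "min_dist": 0.5,
                       "metric": "euclidean"}


@dataclass
class StackedStateMatrix:
    """Complete (patient, horizon) x feature matrices, attribution and raw.

    ``attribution`` and ``raw`` share an identical (patient_id, horizon)
    row index; ``raw`` is standardized per feature (zero mean, unit
    variance over the stacked rows).
    """

    attribution: pd.DataFrame
    raw: pd.DataFrame

    @property
    def horizons(self) -> np.ndarray:
        return self.attribution.index.get_level_values("horizon").to_numpy()


def missingness_filter(
    matrices: CohortMatrices,
    horizons: list[int] | range = range(1, 91),
    max_missing: float = 0.10,
) -> list[str]:
    """Features whose masked fraction is below ``max_missing`` at every horizon.

    Raises with advice when nothing survives the cap.
    """
    kept = list(matrices.parameters)
    for t in horizons:
        frac = matrices.missing_fraction(t)
        kept = [f for f in kept if frac[f] < max_missing]
    if not kept:
        raise ValueError(
            f"no feature has < {max_missing:.0%} missingness at every "
            f"horizon; relax max_missing")
    return kept


def stack_state_matrices(
    matrices: CohortMatrices,
    panels: dict[int, ShapPanel],
    features: list[str],
) -> StackedStateMatrix:
    """Build the paired attribution / standardized-raw stacked matrices.

    ``panels`` must already be restricted to correct positives; each
    panel's rows give the (patient, horizon) pairs to stack.  Rows with any
    missing raw value on ``features`` are excluded from both variants.
    """
    attr_rows, raw_rows, index = [], [], []
    for n in sorted(panels):
        panel = panels[n]
        day = matrices.day_frame(n)
        for i, pid in enumerate(panel.meta["patient_id"]):
            raw_vec = day.loc[pid, features]
            if raw_vec.isna().any():
                continue
            attr_rows.append(panel.phi.iloc[i][features].to_numpy())
            raw_rows.append(raw_vec.to_numpy(dtype=float))
            index.append((pid, n))
    if not index:
        raise ValueError("no complete (patient, horizon) rows to stack")
    idx = pd.MultiIndex.from_tuples(index, names=["patient_id", "horizon"])
    attribution = pd.DataFrame(attr_rows, index=idx, columns=features)
    raw = pd.DataFrame(raw_rows, index=idx, columns=features)
    raw = (raw - raw.mean()) / raw.std(ddof=0)
    return StackedStateMatrix(attribution=attribution, raw=raw)


def embed_2d(
    X: pd.DataFrame,
    method: str = "umap",
    seed: int = 0,
    params: dict | None = None,
) -> pd.DataFrame:
    """2D coordinates for the stacked rows; deterministic under a fixed seed.

    Methods: ``umap`` (defaults per :data:`UMAP_DEFAULTS`), ``tsne``,
    ``pca`` (components ordered by explained variance).
    """
    if X.isna().any().any():
        raise ValueError("embedding input must be complete")
    values = X.to_numpy(dtype=float)
    opts = dict(params or {})
    if method == "umap":
        import umap  # deferred: numba compilation is slow

        conf = {**UMAP_DEFAULTS, **opts}
        if len(values) <= conf["n_neighbors"]:
            raise ValueError("fewer rows than the UMAP neighborhood size")
        coords = umap.UMAP(n_components=2, random_state=seed,
                           **conf).fit_transform(values)
    elif method == "tsne":
        perplexity = opts.pop("perplexity", min(30.0, (len(values) - 1) / 3))
        coords = TSNE(n_components=2, random_state=seed,
                      perplexity=perplexity, **opts).fit_transform(values)
    elif method == "pca":
        coords = PCA(n_components=2, random_state=seed,
                     **opts).fit_transform(values)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(np.asarray(coords, dtype=float), index=X.index,
                        columns=["dim1", "dim2"])


def temporal_separation_score(coords: pd.DataFrame) -> float:
    """max over the two axes of |Spearman(horizon, coordinate)|.

    High values mean the embedding lays the pre-death timeline out along a
    direction; near zero means time is invisible in the plot.
    """
    horizon = coords.index.get_level_values("horizon").to_numpy()
    if len(np.unique(horizon)) < 2:
        raise ValueError("need at least two distinct horizons")
    rhos = [abs(spearmanr(horizon, coords[c]).statistic)
            for c in ("dim1", "dim2")]
    return float(max(rhos))


def plot_embedding(coords: pd.DataFrame, path: str | None = None):
    """Scatter colored navy->yellow by horizon (closest to death = yellow)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    horizon = coords.index.get_level_values("horizon").to_numpy()
    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(coords["dim1"], coords["dim2"], c=-horizon,
                    cmap="cividis", s=8)
    fig.colorbar(sc, ax=ax, label="days before death (negated)")
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
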