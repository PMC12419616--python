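"""Attribution-based patient stratification and subtype characterization.

Patients are clustered on their day-1 (one day before death) attribution
vectors with Ward-linkage agglomerative clustering under the Euclidean
distance.  The number of clusters is chosen as the silhouette argmax over a
candidate range, with the elbow curve (total within-cluster variance per k)
reported alongside for inspection; a fixed k can be forced to reproduce a
manual dendrogram cut.  A comparison arm clusters per-feature standardized
day-1 raw values with the identical procedure.

Subtypes are characterized by median/IQR lab summaries and rank-based
hypothesis tests: Kruskal-Wallis omnibus per lab, pairwise Mann-Whitney
follow-ups only where the omnibus rejects, chi-square (or Fisher's exact
for 2x2 tables with small expected counts) for categorical attributes.
Holm correction is applied across the omnibus family and again within each
lab's pairwise family, controlling the family-wise error at alpha
(default 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import chi2_contingency, fisher_exact, kruskal, mannwhitneyu
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .shap_behavior import ShapBehaviorMatrix, ShapPanel, behavior_matrix

__all__ = [
    "SubtypeResult",
    "cluster_and_select_k",
    "cluster_raw_values",
    "subtype_summary_and_tests",
    "subtype_behaviors",
    "compare_partitions",
]


@dataclass
class SubtypeResult:
    linkage_tree: np.ndarray
    k: int
    labels: pd.Series           # patient_id -> subtype (1..k)
    silhouette: pd.Series       # k -> mean silhouette width
    within_variance: pd.Series  # k -> total within-cluster sum of squares
    space: str                  # "attribution" or "raw-value"

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def _within_cluster_ss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        block = X[labels == c]
        total += ((block - block.mean(axis=0)) ** 2).sum()
    return float(total)


def _cluster(X: pd.DataFrame, k_range: range, k: int | None,
             space: str, standardize: bool = True) -> SubtypeResult:
    if X.isna().any().any():
        raise ValueError("clustering input must have no missing cells")
    if standardize:
        X = (X - X.mean()) / X.std(ddof=0)
        X = X.dropna(axis=1)  # constant dims carry no distance information
    values = X.to_numpy(dtype=float)
    k_candidates = list(k_range)
    if len(values) < 2 * min(k_candidates):
        raise ValueError("too few patients to stratify")
    tree = linkage(values, method="ward", metric="euclidean")

    sil, wss = {}, {}
    for kk in k_candidates:
        if kk >= len(values):
            continue
        lab = fcluster(tree, t=kk, criterion="maxclust")
        wss[kk] = _within_cluster_ss(values, lab)
        sil[kk] = (silhouette_score(values, lab)
                   if len(np.unique(lab)) > 1 else np.nan)
    sil = pd.Series(sil).sort_index()
    wss = pd.Series(wss).sort_index()
    chosen = int(k) if k is not None else int(sil.idxmax())
    labels = pd.Series(fcluster(tree, t=chosen, criterion="maxclust"),
                       index=X.index, name="subtype")
    return SubtypeResult(linkage_tree=tree, k=chosen, labels=labels,
                         silhouette=sil, within_variance=wss, space=space)


def cluster_and_select_k(
    day1_panel: ShapPanel,
    k_range: range = range(2, 11),
    k: int | None = None,
    standardize: bool = True,
) -> SubtypeResult:
    """Ward/Euclidean clustering of day-1 attribution vectors.

    ``day1_panel`` must already be restricted to correct positives.  k is
    the silhouette argmax over ``k_range`` unless forced.  By default each
    attribution dimension is standardized first (never-used features drop
    out); boosted ensembles spread credit unevenly across near-equivalent
    features, and unstandardized Euclidean distance would inherit that
    arbitrary weighting.
    """
    X = day1_panel.phi.copy()
    X.index = pd.Index(day1_panel.meta["patient_id"], name="patient_id")
    return _cluster(X, k_range, k, space="attribution",
                    standardize=standardize)


def cluster_raw_values(
    day1_values: pd.DataFrame,
    k_range: range = range(2, 11),
    k: int | None = None,
) -> SubtypeResult:
    """Comparison arm: identical procedure on standardized day-1 raw labs.

    ``day1_values`` is patients x features; rows with missing values are
    dropped, then each feature is standardized before clustering.
    """
    X = day1_values.dropna()
    return _cluster(X, k_range, k, space="raw-value", standardize=True)


def compare_partitions(a: pd.Series, b: pd.Series) -> float:
    """Adjusted Rand index between two labelings on their common patients."""
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no common patients between partitions")
    return float(adjusted_rand_score(a.loc[common], b.loc[common]))


def _holm(pvals: pd.Series) -> pd.Series:
    """Holm step-down adjusted p-values."""
    p = pvals.to_numpy(dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return pd.Series(adj, index=pvals.index)


@dataclass
class SubtypeSummary:
    sizes: pd.Series
    lab_summary: pd.DataFrame   # subtype x lab -> "median (q1-q3)"
    tests: pd.DataFrame         # variable, comparison, statistic, p, p_corrected, significant
    alpha: float
    skipped_subtypes: list = field(default_factory=list)


def _median_iqr(x: pd.Series) -> str:
    q1, med, q3 = np.percentile(x.dropna(), [25, 50, 75])
    return f"{med:g} ({q1:g}-{q3:g})"


def subtype_summary_and_tests(
    labels: pd.Series,
    day1_labs: pd.DataFrame,
    attributes: pd.DataFrame | None = None,
    alpha: float = 0.01,
) -> SubtypeSummary:
    """Per-subtype lab summaries plus corrected hypothesis tests.

    ``labels`` maps patient_id to subtype; ``day1_labs`` (patients x labs)
    and optional categorical ``attributes`` (patients x columns) are
    aligned on patient id.  Subtypes with fewer than 3 patients are
    excluded from testing and reported in ``skipped_subtypes``.
    """
    labs = day1_labs.loc[day1_labs.index.intersection(labels.index)]
    lab_labels = labels.loc[labs.index]
    sizes = labels.value_counts().sort_index()
    testable = [s for s in sizes.index if (lab_labels == s).sum() >= 3]
    skipped = [s for s in sizes.index if s not in testable]

    summary = pd.DataFrame({
        lab: {s: _median_iqr(labs.loc[lab_labels == s, lab])
              for s in sizes.index}
        for lab in labs.columns
    })
    summary.index.name = "subtype"

    records = []
    omnibus_p = {}
    for lab in labs.columns:
        groups = [labs.loc[lab_labels == s, lab].dropna() for s in testable]
        groups = [g for g in groups if len(g) > 0]
        if len(groups) < 2:
            continue
        try:
            stat, p = kruskal(*groups)
        except ValueError:  # all values identical
            stat, p = np.nan, 1.0
        omnibus_p[("lab", lab)] = (stat, p)

    if attributes is not None:
        attrs = attributes.loc[attributes.index.intersection(labels.index)]
        attr_labels = labels.loc[attrs.index]
        for col in attrs.columns:
            sub = attr_labels[attr_labels.isin(testable)]
            table = pd.crosstab(sub, attrs.loc[sub.index, col])
            if table.shape[0] < 2 or table.shape[1] < 2:
                continue
            expected = (table.sum(1).to_numpy()[:, None]
                        * table.sum(0).to_numpy()[None, :]) / table.to_numpy().sum()
            if table.shape == (2, 2) and expected.min() < 5:
                stat, p = fisher_exact(table)
            else:
                stat, p, _, _ = chi2_contingency(table)
            omnibus_p[("categorical", col)] = (stat, p)

    raw = pd.Series({k: v[1] for k, v in omnibus_p.items()})
    corrected = _holm(raw) if len(raw) else raw
    for key in raw.index:
        kind, var = key
        records.append({
            "variable": var, "comparison": "omnibus",
            "statistic": omnibus_p[key][0], "p": raw[key],
            "p_corrected": corrected[key],
            "significant": bool(corrected[key] < alpha),
        })

    # pairwise follow-ups only where the omnibus rejected
    for key in raw.index:
        kind, var = key
        if kind != "lab" or corrected[key] >= alpha:
            continue
        pair_p, pair_stat = {}, {}
        for a, b in combinations(testable, 2):
            ga = labs.loc[lab_labels == a, var].dropna()
            gb = labs.loc[lab_labels == b, var].dropna()
            if len(ga) == 0 or len(gb) == 0:
                continue
            stat, p = mannwhitneyu(ga, gb, alternative="two-sided")
            pair_p[(a, b)] = p
            pair_stat[(a, b)] = stat
        adj = _holm(pd.Series(pair_p)) if pair_p else pd.Series(dtype=float)
        for pair in adj.index:
            records.append({
                "variable": var, "comparison": f"{pair[0]} vs {pair[1]}",
                "statistic": pair_stat[pair], "p": pair_p[pair],
                "p_corrected": adj[pair],
                "significant": bool(adj[pair] < alpha),
            })

    tests = pd.DataFrame.from_records(
        records, columns=["variable", "comparison", "statistic", "p",
                          "p_corrected", "significant"])
    return SubtypeSummary(sizes=sizes, lab_summary=summary, tests=tests,
                          alpha=alpha, skipped_subtypes=skipped)


def subtype_behaviors(
    labels: pd.Series,
    panels: dict[int, ShapPanel],
    threshold: float = 0.5,
) -> dict[int, ShapBehaviorMatrix]:
    """Behavior matrix per subtype, restricting each horizon to its patients.

    A subtype absent at a horizon simply lacks that column in its matrix.
    """
    out: dict[int, ShapBehaviorMatrix] = {}
    for subtype in sorted(labels.unique()):
        members = set(labels.index[labels == subtype])
        restricted: dict[int, ShapPanel] = {}
        for n, panel in panels.items():
            keep = panel.meta["patient_id"].isin(members).to_numpy()
            if not keep.any():
                continue
            restricted[n] = ShapPanel(
                horizon=panel.horizon,
                phi=panel.phi.loc[keep].reset_index(drop=True),
                meta=panel.meta.loc[keep].reset_index(drop=True))
        if restricted:
            out[int(subtype)] = behavior_matrix(restricted,
                                                threshold=threshold)
    return out
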