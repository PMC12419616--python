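"""Ward stratification, subtype summaries, and corrected hypothesis tests."""

import numpy as np
import pandas as pd
import pytest

from predeath.shap_behavior import ShapPanel, behavior_matrix
from predeath.stratify import (cluster_and_select_k, cluster_raw_values,
                               compare_partitions, subtype_behaviors,
                               subtype_summary_and_tests, _median_iqr)


def blob_panel(centers, n_per=30, spread=0.1, seed=0):
    rng = np.random.default_rng(seed)
    phi_rows, ids = [], []
    for c, center in enumerate(centers):
        for i in range(n_per):
            ids.append(f"c{c}_p{i:02d}")
            phi_rows.append(np.asarray(center) + rng.normal(0, spread,
                                                            len(center)))
    phi = pd.DataFrame(phi_rows,
                       columns=[f"f{j}" for j in range(len(centers[0]))])
    meta = pd.DataFrame({"patient_id": ids, "label": 1, "probability": 0.9,
                         "margin": phi.sum(axis=1), "base": 0.0})
    return ShapPanel(horizon=1, phi=phi, meta=meta)


class TestClusterSelection:
    def test_two_separated_blobs_recovered_exactly(self):
        panel = blob_panel([(0.0, 0.0), (4.0, 4.0)])
        result = cluster_and_select_k(panel)
        assert result.k == 2
        truth = pd.Series([0] * 30 + [1] * 30,
                          index=result.labels.index)
        assert compare_partitions(result.labels, truth) == 1.0

    def test_duplicating_every_patient_is_stable(self):
        panel = blob_panel([(0.0, 0.0), (4.0, 4.0)], n_per=20)
        doubled_phi = pd.concat([panel.phi, panel.phi], ignore_index=True)
        meta2 = panel.meta.copy()
        meta2["patient_id"] = meta2["patient_id"] + "_dup"
        doubled_meta = pd.concat([panel.meta, meta2], ignore_index=True)
        doubled = ShapPanel(horizon=1, phi=doubled_phi, meta=doubled_meta)
        r1 = cluster_and_select_k(panel)
        r2 = cluster_and_select_k(doubled)
        assert r2.k == r1.k
        originals = r2.labels[~r2.labels.index.str.endswith("_dup")]
        dups = r2.labels[r2.labels.index.str.endswith("_dup")]
        dups.index = dups.index.str.removesuffix("_dup")
        assert compare_partitions(originals, dups) == 1.0

    def test_forced_k_overrides_silhouette(self):
        panel = blob_panel([(0.0, 0.0), (4.0, 4.0)])
        assert cluster_and_select_k(panel, k=4).k == 4

    def test_ward_merge_heights_monotone(self):
        panel = blob_panel([(0.0, 0.0), (2.0, 1.0), (4.0, 4.0)], seed=3)
        heights = cluster_and_select_k(panel).linkage_tree[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            cluster_and_select_k(blob_panel([(0.0, 0.0)], n_per=3))

    def test_raw_arm_runs_same_procedure_on_standardized_values(self):
        rng = np.random.default_rng(1)
        day1 = pd.DataFrame(
            {"x": np.r_[rng.normal(0, 1, 30), rng.normal(30, 1, 30)],
             "y": np.r_[rng.normal(0, 1, 30), rng.normal(8, 1, 30)]},
            index=[f"p{i}" for i in range(60)])
        result = cluster_raw_values(day1)
        assert result.space == "raw-value" and result.k == 2


class TestSubtypeSummary:
    def test_median_iqr_order_statistics(self):
        assert _median_iqr(pd.Series([1, 2, 3, 4, 5])) == "3 (2-4)"

    def test_null_data_yields_no_significance(self):
        rng = np.random.default_rng(2)
        labels = pd.Series(rng.integers(1, 4, 120),
                           index=[f"p{i}" for i in range(120)])
        labs = pd.DataFrame(rng.normal(size=(120, 3)),
                            columns=["alb", "crp", "bun"],
                            index=labels.index)
        attrs = pd.DataFrame({"sex": rng.choice(["m", "f"], 120)},
                             index=labels.index)
        summary = subtype_summary_and_tests(labels, labs, attrs, alpha=0.01)
        assert not summary.tests["significant"].any()

    def test_planted_shift_detected_and_localized(self):
        rng = np.random.default_rng(5)
        labels = pd.Series([1] * 100 + [2] * 100 + [3] * 100,
                           index=[f"p{i}" for i in range(300)])
        labs = pd.DataFrame({"alb": rng.normal(3.5, 0.5, 300)},
                            index=labels.index)
        labs.loc[labels == 2, "alb"] -= 1.0
        summary = subtype_summary_and_tests(labels, labs, alpha=0.01)
        omnibus = summary.tests[summary.tests["comparison"] == "omnibus"]
        assert omnibus["significant"].all()
        pairwise = summary.tests[summary.tests["comparison"] != "omnibus"]
        involving2 = pairwise["comparison"].str.contains("2")
        assert pairwise.loc[involving2, "significant"].all()
        assert not pairwise.loc[~involving2, "significant"].any()

    def test_tiny_subtype_skipped_and_flagged(self):
        labels = pd.Series([1] * 50 + [2] * 50 + [3] * 2,
                           index=[f"p{i}" for i in range(102)])
        rng = np.random.default_rng(0)
        labs = pd.DataFrame({"alb": rng.normal(size=102)},
                            index=labels.index)
        summary = subtype_summary_and_tests(labels, labs)
        assert summary.skipped_subtypes == [3]
        assert summary.sizes.sum() == 102


class TestSubtypeBehaviors:
    def test_single_subtype_reproduces_global_matrix(self,
                                                     study_correct_panels,
                                                     study_behavior):
        any_panel = study_correct_panels[1]
        labels = pd.Series(1, index=pd.Index(any_panel.meta["patient_id"],
                                             name="patient_id"))
        per_sub = subtype_behaviors(labels, {1: study_correct_panels[1]})
        pd.testing.assert_series_equal(per_sub[1].scaled[1],
                                       study_behavior.scaled[1])

    def test_patient_weighted_recombination_is_exact(self,
                                                     study_correct_panels):
        panel = study_correct_panels[1]
        rng = np.random.default_rng(0)
        ids = pd.Index(panel.meta["patient_id"], name="patient_id")
        labels = pd.Series(rng.integers(1, 4, len(ids)), index=ids)
        per_sub = subtype_behaviors(labels, {1: panel})
        global_mean = behavior_matrix({1: panel},
                                      already_filtered=True).means[1]
        combined = sum(per_sub[s].means[1] * per_sub[s].n_rows[1]
                       for s in per_sub) / len(panel)
        np.testing.assert_allclose(combined, global_mean, atol=1e-9)
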