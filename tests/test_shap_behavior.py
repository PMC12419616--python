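"""Attribution panels and behavior matrices: exactness and normalization."""

import lightgbm as lgb
import numpy as np
import pandas as pd
import pytest

from predeath.labeling import grouped_split
from predeath.modeling import DEFAULT_PARAMS, HorizonModel, train_horizon_model
from predeath.shap_behavior import (ShapPanel, attribute_panel,
                                    behavior_matrix, rank_and_proportions,
                                    scaled_mean_shap,
                                    select_correct_positives)
from test_modeling import FAST, make_dataset
from _oracles import brute_force_tree_shap


def panel_from_phi(phi_rows, labels=None, probs=None, features=None):
    phi = pd.DataFrame(phi_rows, columns=features or
                       [f"f{j}" for j in range(len(phi_rows[0]))])
    n = len(phi)
    meta = pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(n)],
        "label": labels if labels is not None else [1] * n,
        "probability": probs if probs is not None else [0.9] * n,
        "margin": phi.sum(axis=1),
        "base": [0.0] * n,
    })
    return ShapPanel(horizon=1, phi=phi, meta=meta)


class TestAttributionExactness:
    def test_additivity_on_fitted_model(self):
        ds = make_dataset(80, seed=0)
        model = train_horizon_model(ds, grouped_split(ds, seed=0), seed=0,
                                    params=FAST)
        panel = attribute_panel(model, ds.frame)
        assert panel.additivity_gap().max() < 1e-6

    def test_single_stump_gives_zero_credit_elsewhere(self):
        ds = make_dataset(80, signal=5.0, seed=1)
        params = dict(FAST, n_estimators=1, num_leaves=2)
        model = train_horizon_model(ds, grouped_split(ds, seed=0), seed=0,
                                    params=params)
        panel = attribute_panel(model, ds.frame)
        assert (panel.phi["f1"] == 0).all() and (panel.phi["f2"] == 0).all()
        assert panel.phi["f0"].abs().max() > 0

    def test_matches_exhaustive_shapley_on_depth2_tree(self):
        # one depth-2 tree over 3 binary features; oracle enumerates all
        # feature coalitions with cover-weighted tree expectations
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, size=(400, 3)).astype(float)
        y = ((X[:, 0] + X[:, 1]) >= 1).astype(int)
        clf = lgb.LGBMClassifier(n_estimators=1, max_depth=2, num_leaves=4,
                                 min_child_samples=5, n_jobs=1,
                                 deterministic=True, verbosity=-1,
                                 random_state=0)
        clf.fit(X, y)
        for x in [np.array(v, dtype=float) for v in
                  [(0, 0, 0), (0, 1, 0), (1, 0, 1), (1, 1, 1)]]:
            expected = brute_force_tree_shap(clf.booster_, x)
            got = clf.predict(x.reshape(1, -1), pred_contrib=True)[0]
            np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_feature_mismatch_rejected(self):
        ds = make_dataset(30, seed=2)
        model = train_horizon_model(ds, grouped_split(ds, seed=0), seed=0,
                                    params=FAST)
        bad = ds.frame.rename(columns={"f2": "other"})
        with pytest.raises(ValueError, match="lack model features"):
            attribute_panel(model, bad)


class TestCorrectPositiveFilter:
    def test_retention_matches_hand_count(self):
        panel = panel_from_phi([[1.0], [1.0], [1.0], [1.0]],
                               labels=[1, 1, 0, 1],
                               probs=[0.9, 0.4, 0.9, 0.5])
        kept = select_correct_positives(panel, threshold=0.5)
        assert len(kept) == 2  # labels 1 with probability >= 0.5

    def test_unreachable_threshold_leaves_empty_panel(self):
        panel = panel_from_phi([[1.0]], labels=[1], probs=[0.97])
        kept = select_correct_positives(panel, threshold=1.0)
        assert len(kept) == 0
        with pytest.raises(ValueError, match="empty panel"):
            scaled_mean_shap(kept)

    def test_perfect_model_keeps_positive_half(self):
        panel = panel_from_phi([[1.0]] * 6, labels=[1, 0] * 3,
                               probs=[0.99, 0.01] * 3)
        assert len(select_correct_positives(panel)) == 3


class TestScaledMeans:
    def test_direct_arithmetic(self):
        panel = panel_from_phi([[2.0, 1.0, -0.5]] * 4)
        s, scale = scaled_mean_shap(panel)
        np.testing.assert_allclose(s, [1.0, 0.5, -0.25])
        assert scale == pytest.approx(2.0)

    def test_single_feature_self_scales(self):
        s, _ = scaled_mean_shap(panel_from_phi([[-0.3], [-0.5]]))
        assert s.iloc[0] == -1.0

    def test_scaling_is_idempotent(self):
        panel = panel_from_phi([[2.0, 1.0, -0.5]] * 4)
        s1, _ = scaled_mean_shap(panel)
        s2, scale2 = scaled_mean_shap(panel_from_phi([s1.to_numpy()]))
        np.testing.assert_allclose(s2, s1)
        assert scale2 == pytest.approx(1.0)

    def test_column_permutation_equivariance(self):
        phi = [[2.0, 1.0, -0.5]] * 3
        s, _ = scaled_mean_shap(panel_from_phi(phi, features=["a", "b", "c"]))
        perm = [[row[2], row[0], row[1]] for row in phi]
        sp, _ = scaled_mean_shap(panel_from_phi(perm,
                                                features=["c", "a", "b"]))
        for f in "abc":
            assert sp[f] == s[f]

    def test_all_zero_attributions_rejected(self):
        with pytest.raises(ValueError, match="scale undefined"):
            scaled_mean_shap(panel_from_phi([[0.0, 0.0]]))


class TestBehaviorMatrix:
    def test_every_column_touches_unit_magnitude(self, study_behavior):
        peak = study_behavior.scaled.abs().max(axis=0)
        np.testing.assert_allclose(peak.to_numpy(), 1.0, atol=1e-12)
        assert (study_behavior.scaled.abs() <= 1 + 1e-12).all().all()

    def test_planted_drivers_outrank_nuisance_at_day1(self, study_behavior):
        s1 = study_behavior.scaled[1]
        top = s1.abs().idxmax()
        assert not top.startswith(("nui", "sparse"))
        nuisance = [f for f in study_behavior.features
                    if f.startswith(("nui", "sparse"))]
        assert s1[nuisance].abs().max() < 0.3

    def test_empty_horizon_left_out_not_zeroed(self):
        full = panel_from_phi([[1.0, 0.5]], labels=[1], probs=[0.9])
        empty = panel_from_phi([[1.0, 0.5]], labels=[0], probs=[0.9])
        bm = behavior_matrix({1: full, 30: empty})
        assert bm.horizons == [1]

    def test_late_onset_feature_climbs_ranks_near_death(self,
                                                        study_behavior):
        ranks = {h: study_behavior.rank_at(h)["bun"] for h in (60, 5, 1)}
        assert ranks[5] < ranks[60]
        assert ranks[1] <= ranks[5]


class TestRanksAndProportions:
    def test_proportions_sum_to_100_at_every_horizon(self, study_behavior):
        for h in study_behavior.horizons:
            _, shares = rank_and_proportions(study_behavior, h, k=10,
                                             focus=["alb", "crp", "bun",
                                                    "ldh"])
            assert shares.sum() == pytest.approx(100.0, abs=1e-9)

    def test_full_k_returns_all_features_ordered(self, study_behavior):
        top, _ = rank_and_proportions(study_behavior, 1,
                                      k=len(study_behavior.features))
        s = study_behavior.scaled[1].abs()
        assert len(top) == len(study_behavior.features)
        assert all(s[top[i]] >= s[top[i + 1]] for i in range(len(top) - 1))

    def test_oversized_k_warns_and_truncates(self, study_behavior):
        with pytest.warns(UserWarning):
            top, _ = rank_and_proportions(study_behavior, 1, k=10_000)
        assert len(top) == len(study_behavior.features)
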