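"""Training-set splitting, forest training, ranking and evaluation metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from saapqa.features import FEATURE_NAMES
from saapqa.qa import (auc_rank, evaluate, filter_targets, kfold_by_target,
                       load_model, predict, rank_and_loss, roc_points, save_model,
                       split_by_target, train)


def synthetic_rows(n_targets: int = 10, models_per_target: int = 20,
                   noise_sigma: float = 5.0, seed: int = 0) -> pd.DataFrame:
    """Descriptor rows where true GDT is a noisy monotone function of SAAP_p."""
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_targets):
        for m in range(models_per_target):
            saap = float(rng.uniform(0, 100))
            gdt = float(np.clip(95 - 0.85 * saap + rng.normal(0, noise_sigma), 0, 100))
            loop_frac = float(np.clip(0.2 + saap / 200 + rng.normal(0, 0.05), 0, 1))
            helix = (1 - loop_frac) * 0.7
            sheet = (1 - loop_frac) * 0.3
            loop_content = int(round(loop_frac * 120))
            rows.append({
                "target_id": f"T{t:02d}", "model_id": f"T{t:02d}_m{m:03d}",
                "saap_p": saap, "helix_fraction": helix, "sheet_fraction": sheet,
                "loop_fraction": loop_frac, "loop_content": loop_content,
                "saap_loop_ratio": saap / max(loop_content, 1),
                "true_gdt": gdt, "valid": True,
            })
    return pd.DataFrame(rows)


class TestSplitting:
    def test_70_30_counts_and_disjoint(self):
        rows = synthetic_rows(10)
        ts = split_by_target(rows, train_fraction=0.7, seed=3)
        train_t = {t for t, v in ts.split_assignment.items() if v == "train"}
        test_t = {t for t, v in ts.split_assignment.items() if v == "test"}
        assert len(train_t) == 7 and len(test_t) == 3
        assert not train_t & test_t

    def test_deterministic_given_seed(self):
        rows = synthetic_rows(10)
        a = split_by_target(rows, seed=5).split_assignment
        b = split_by_target(rows, seed=5).split_assignment
        assert a == b
        c = split_by_target(rows, seed=6).split_assignment
        assert any(a[t] != c[t] for t in a)

    def test_threefold_on_nine_targets(self):
        rows = synthetic_rows(9)
        ts = kfold_by_target(rows, k=3, seed=1)
        folds = {}
        for t, f in ts.split_assignment.items():
            folds.setdefault(f, set()).add(t)
        assert sorted(len(v) for v in folds.values()) == [3, 3, 3]
        assert not (folds[0] & folds[1] or folds[0] & folds[2] or folds[1] & folds[2])

    def test_single_target_rejected(self):
        with pytest.raises(ValueError):
            split_by_target(synthetic_rows(1))


class TestTrainPredict:
    def test_constant_labels_predict_constant(self):
        rows = synthetic_rows(4, 20)
        rows["true_gdt"] = 60.0
        m = train(rows, seed=0)
        preds = predict(m, rows.head(10))
        np.testing.assert_allclose(preds, 60.0)

    def test_recovers_monotone_signal_on_heldout_targets(self):
        rows = synthetic_rows(20, 50, noise_sigma=5.0, seed=2)
        ts = split_by_target(rows, seed=2)
        tr, te = ts.subset("train"), ts.subset("test")
        m = train(tr, seed=2)
        preds = predict(m, te)
        pcc = stats.pearsonr(te["true_gdt"], preds).statistic
        assert pcc >= 0.8

    def test_retrain_identical(self):
        rows = synthetic_rows(6, 20)
        m1 = train(rows, seed=7)
        m2 = train(rows, seed=7)
        np.testing.assert_array_equal(predict(m1, rows), predict(m2, rows))

    def test_contract_recorded(self):
        rows = synthetic_rows(4, 20)
        m = train(rows, seed=1)
        assert m.n_trees == 700 and m.features_per_split == 2
        assert m.feature_order == FEATURE_NAMES
        lo, hi = m.training_target_range
        preds = predict(m, rows)
        assert preds.min() >= lo - 1e-9 and preds.max() <= hi + 1e-9

    def test_permutation_equivariance_and_range(self):
        rows = synthetic_rows(4, 15)
        m = train(rows, seed=3)
        sub = rows.sample(frac=1.0, random_state=1)
        np.testing.assert_allclose(predict(m, sub),
                                   predict(m, rows)[sub.index.to_numpy()])
        assert ((predict(m, rows) >= 0) & (predict(m, rows) <= 100)).all()

    def test_serialization_round_trip(self, tmp_path):
        rows = synthetic_rows(4, 15)
        m = train(rows, seed=4)
        path = tmp_path / "model.joblib"
        save_model(m, path)
        m2 = load_model(path)
        np.testing.assert_array_equal(predict(m, rows), predict(m2, rows))
        assert m2.feature_order == m.feature_order

    def test_invalid_rows_rejected(self):
        rows = synthetic_rows(4, 15)
        rows.loc[rows.index[:3], "valid"] = False
        with pytest.raises(ValueError, match="invalid"):
            train(rows, seed=0)

    def test_nan_features_rejected(self):
        rows = synthetic_rows(4, 15)
        m = train(rows, seed=0)
        rows.loc[rows.index[0], "saap_p"] = np.nan
        with pytest.raises(ValueError):
            predict(m, rows)


class TestRankAndLoss:
    def pool(self, gdts, ids=None):
        ids = ids or [f"m{i}" for i in range(len(gdts))]
        return pd.DataFrame({"model_id": ids, "true_gdt": gdts})

    def test_definition(self):
        pool = self.pool([80.0, 70.0, 60.0])
        preds = np.array([0.5, 0.9, 0.1])       # predictor picks the 70 model
        assert rank_and_loss(pool, preds, k=1) == pytest.approx(10.0)

    def test_perfect_predictor_zero_loss(self):
        pool = self.pool([80.0, 70.0, 60.0])
        preds = pool["true_gdt"].to_numpy()
        for k in (1, 2, 3):
            assert rank_and_loss(pool, preds, k=k) == 0.0

    def test_non_increasing_in_k(self):
        rng = np.random.default_rng(1)
        pool = self.pool(rng.uniform(10, 90, 12).tolist())
        preds = rng.uniform(0, 100, 12)
        losses = [rank_and_loss(pool, preds, k=k) for k in (1, 5, 10)]
        assert losses[0] >= losses[1] >= losses[2]

    def test_tie_break_by_model_id(self):
        pool = self.pool([50.0, 90.0], ids=["b", "a"])
        preds = np.array([70.0, 70.0])
        # tie: 'a' (true 90) ranked before 'b' -> zero loss at k=1
        assert rank_and_loss(pool, preds, k=1) == 0.0

    def test_small_pool_warns(self, caplog):
        import logging
        pool = self.pool([50.0, 60.0])
        with caplog.at_level(logging.WARNING):
            loss = rank_and_loss(pool, np.array([1.0, 2.0]), k=10)
        assert loss == 0.0
        assert any("smaller" in m for m in caplog.messages)


class TestEvaluate:
    def test_perfect_predictions(self):
        rows = synthetic_rows(4, 15)
        rep = evaluate(rows, rows["true_gdt"].to_numpy())
        assert rep.global_pcc == pytest.approx(1.0)
        assert rep.auc == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in rep.per_target_pcc.values())
        assert all(v == 0.0 for v in rep.gdt_loss[1].values())

    def test_anti_predictions(self):
        rows = synthetic_rows(3, 15)
        rep = evaluate(rows, -rows["true_gdt"].to_numpy())
        assert rep.global_pcc == pytest.approx(-1.0)
        assert rep.auc == pytest.approx(0.0)

    def test_hand_case(self):
        rows = pd.DataFrame({
            "target_id": ["t"] * 4,
            "model_id": list("abcd"),
            "true_gdt": [40.0, 45.0, 55.0, 60.0],
        })
        preds = np.array([41.0, 44.0, 56.0, 59.0])
        rep = evaluate(rows, preds)
        assert rep.auc == pytest.approx(1.0)
        # direct arithmetic Pearson oracle
        t = rows["true_gdt"].to_numpy()
        num = np.sum((t - t.mean()) * (preds - preds.mean()))
        den = np.sqrt(np.sum((t - t.mean()) ** 2) * np.sum((preds - preds.mean()) ** 2))
        assert rep.global_pcc == pytest.approx(num / den)

    def test_single_class_auc_undefined(self):
        rows = pd.DataFrame({"target_id": ["t"] * 3, "model_id": list("abc"),
                             "true_gdt": [60.0, 70.0, 80.0]})
        rep = evaluate(rows, np.array([1.0, 2.0, 3.0]))
        assert np.isnan(rep.auc)

    def test_rank_auc_equals_trapezoid(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=200)
        labels = rng.random(200) < 0.4
        fpr, tpr = roc_points(scores, labels)
        assert auc_rank(scores, labels) == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-9)


class TestFilterTargets:
    def table(self, **kw):
        base = {"target_id": ["t"], "length": [150], "agg_fraction": [0.5]}
        base.update({k: [v] for k, v in kw.items()})
        return pd.DataFrame(base)

    def test_casp_short_domain_excluded(self):
        assert len(filter_targets(self.table(length=99), "casp")) == 0
        assert len(filter_targets(self.table(length=100), "casp")) == 1

    def test_casp_small_patch_excluded_boundary(self):
        assert len(filter_targets(self.table(agg_fraction=0.19), "casp")) == 0
        assert len(filter_targets(self.table(agg_fraction=0.20), "casp")) == 1

    def test_cameo_length_window(self):
        assert len(filter_targets(self.table(length=49), "cameo")) == 0
        assert len(filter_targets(self.table(length=501), "cameo")) == 0
        assert len(filter_targets(self.table(length=50), "cameo")) == 1
        assert len(filter_targets(self.table(length=500), "cameo")) == 1
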