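"""SAAP-QA: random-forest GDT regression, decoy ranking and evaluation.

A regression forest (700 trees, 2 candidate features per split) maps the
six structural descriptors to GDT.  Splits are always at the target level
— no target contributes models to more than one split or fold — so the
evaluation measures generalisation to unseen proteins.  Evaluation metrics
follow the field's conventions: per-target and global Pearson correlation
between predicted and true GDT, ROC/AUC for separating high-quality models
(true GDT > 50), and top-k GDT loss (best true GDT in the pool minus the
best true GDT among the k models ranked highest by predicted GDT).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from . import config
from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass
class TrainingSet:
    """Descriptor rows with GDT labels and a target-level split assignment.

    ``rows`` needs columns: target_id, model_id, the six features, true_gdt.
    ``split_assignment`` maps target_id to 'train'/'test' or a fold index.
    """

    rows: pd.DataFrame
    split_assignment: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ("target_id", "model_id", "true_gdt", *FEATURE_NAMES)
                   if c not in self.rows.columns]
        if missing:
            raise ValueError(f"training rows missing columns: {missing}")

    def subset(self, label: object) -> pd.DataFrame:
        targets = {t for t, v in self.split_assignment.items() if v == label}
        return self.rows[self.rows["target_id"].isin(targets)]

    def assert_target_disjoint(self) -> None:
        per_target = {}
        for t, v in self.split_assignment.items():
            per_target.setdefault(t, set()).add(v)
        multi = {t for t, v in per_target.items() if len(v) > 1}
        if multi:
            raise AssertionError(f"targets in more than one split: {sorted(multi)}")


def split_by_target(rows: pd.DataFrame, train_fraction: float = config.TRAIN_FRACTION,
                    seed: int = 0) -> TrainingSet:
    """Random target-level 70/30 (by default) partition, deterministic by seed."""
    targets = sorted(rows["target_id"].unique())
    if len(targets) < 2:
        raise ValueError("need at least 2 targets to split")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(targets))
    n_train = int(round(train_fraction * len(targets)))
    n_train = min(max(n_train, 1), len(targets) - 1)
    assignment: dict[str, object] = {t: "train" for t in order[:n_train]}
    assignment.update({t: "test" for t in order[n_train:]})
    ts = TrainingSet(rows=rows, split_assignment=assignment)
    ts.assert_target_disjoint()
    return ts


def kfold_by_target(rows: pd.DataFrame, k: int = 3, seed: int = 0) -> TrainingSet:
    """Target-disjoint k-fold assignment (folds as even as possible)."""
    targets = sorted(rows["target_id"].unique())
    if len(targets) < k:
        raise ValueError(f"need at least {k} targets for {k}-fold assignment")
    rng = np.random.default_rng(seed)
    order = rng.permutation(targets)
    assignment = {t: int(i % k) for i, t in enumerate(order)}
    ts = TrainingSet(rows=rows, split_assignment=assignment)
    ts.assert_target_disjoint()
    return ts


@dataclass
class QaModel:
    """Trained regression forest plus its input contract and provenance."""

    forest: RandomForestRegressor
    feature_order: tuple[str, ...]
    training_target_range: tuple[float, float]
    seed: int
    n_trees: int = config.RF_N_TREES
    features_per_split: int = config.RF_FEATURES_PER_SPLIT


def _feature_matrix(rows: pd.DataFrame, feature_order: Sequence[str]) -> np.ndarray:
    x = rows.loc[:, list(feature_order)].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        bad = rows.loc[~np.isfinite(x).all(axis=1), "model_id"].tolist()
        raise ValueError(f"non-finite features for models: {bad[:10]}")
    return x


def train(rows: pd.DataFrame, seed: int = 0,
          cfg: config.RunConfig = config.DEFAULT_CONFIG) -> QaModel:
    """Fit the regression forest on valid descriptor rows.

    Requires at least 50 rows; rows flagged invalid (undefined SAAP_p)
    must be filtered out upstream and raise here if present.  Constant
    labels are degenerate but allowed (the forest predicts the constant).
    """
    if "valid" in rows.columns and not rows["valid"].astype(bool).all():
        bad = rows.loc[~rows["valid"].astype(bool), "model_id"].tolist()
        raise ValueError(f"invalid descriptor rows (undefined SAAP_p): {bad[:10]}")
    if len(rows) < 50:
        raise ValueError(f"need at least 50 training rows, got {len(rows)}")
    y = rows["true_gdt"].to_numpy(dtype=float)
    if np.unique(y).size < 2:
        logger.warning("training labels are constant (%.2f); forest will predict it", y[0])
    x = _feature_matrix(rows, FEATURE_NAMES)
    forest = RandomForestRegressor(
        n_estimators=cfg.rf_n_trees,
        max_features=cfg.rf_features_per_split,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(x, y)
    return QaModel(forest=forest, feature_order=tuple(FEATURE_NAMES),
                   training_target_range=(float(y.min()), float(y.max())),
                   seed=seed, n_trees=cfg.rf_n_trees,
                   features_per_split=cfg.rf_features_per_split)


def predict(m: QaModel, rows: pd.DataFrame) -> np.ndarray:
    """Predicted GDT per row (pointwise; order-preserving)."""
    x = _feature_matrix(rows, m.feature_order)
    return m.forest.predict(x)


def save_model(m: QaModel, path: str | Path) -> None:
    joblib.dump({
        "format_version": MODEL_FORMAT_VERSION,
        "feature_order": list(m.feature_order),
        "training_target_range": list(m.training_target_range),
        "seed": m.seed,
        "n_trees": m.n_trees,
        "features_per_split": m.features_per_split,
        "forest": m.forest,
    }, path)


def load_model(path: str | Path) -> QaModel:
    blob = joblib.load(path)
    if blob.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {blob.get('format_version')}")
    return QaModel(forest=blob["forest"], feature_order=tuple(blob["feature_order"]),
                   training_target_range=tuple(blob["training_target_range"]),
                   seed=blob["seed"], n_trees=blob["n_trees"],
                   features_per_split=blob["features_per_split"])


# ---------------------------------------------------------------------------
# Ranking and evaluation
# ---------------------------------------------------------------------------

def rank_and_loss(pool: pd.DataFrame, predictions: np.ndarray,
                  k: int = 1) -> float:
    """Top-k GDT loss for one decoy pool.

    Models are ranked by predicted GDT descending (ties broken by
    model_id); the loss is the pool's best true GDT minus the best true
    GDT among the top-k ranked models.  Pools smaller than k are scored
    over the available models with a warning.
    """
    if len(pool) == 0:
        raise ValueError("empty pool")
    if len(pool) < k:
        logger.warning("pool of %d models smaller than k=%d", len(pool), k)
    order = sorted(range(len(pool)),
                   key=lambda i: (-predictions[i], str(pool["model_id"].iloc[i])))
    top = order[:k]
    true = pool["true_gdt"].to_numpy(dtype=float)
    return float(true.max() - true[top].max())


def roc_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC (FPR, TPR) swept over all score thresholds."""
    order = np.argsort(-scores, kind="stable")
    labels = labels[order].astype(bool)
    tp = np.cumsum(labels)
    fp = np.cumsum(~labels)
    # collapse tied scores onto one threshold point
    s = scores[order]
    keep = np.append(s[1:] != s[:-1], True)
    tpr = np.concatenate([[0.0], tp[keep] / max(labels.sum(), 1)])
    fpr = np.concatenate([[0.0], fp[keep] / max((~labels).sum(), 1)])
    return fpr, tpr


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank statistic (ties averaged).

    Returns nan when only one class is present.
    """
    labels = labels.astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class EvaluationReport:
    per_target_pcc: dict[str, float]
    global_pcc: float
    auc: float                                   # nan when single-class
    gdt_loss: dict[int, dict[str, float]]        # k -> target -> loss
    mean_gdt_loss: dict[int, float]

    @property
    def mean_per_target_pcc(self) -> float:
        vals = [v for v in self.per_target_pcc.values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")


def evaluate(rows: pd.DataFrame, predictions: np.ndarray,
             gdt_cutoff: float = config.GDT_QUALITY_CUTOFF,
             ks: tuple[int, ...] = (1, 5, 10)) -> EvaluationReport:
    """Full evaluation: correlations, ROC/AUC and per-target top-k losses.

    ``rows`` needs target_id, model_id and true_gdt, aligned with
    ``predictions``.
    """
    rows = rows.reset_index(drop=True)
    predictions = np.asarray(predictions, dtype=float)
    truths = rows["true_gdt"].to_numpy(dtype=float)
    per_target_pcc: dict[str, float] = {}
    losses: dict[int, dict[str, float]] = {k: {} for k in ks}
    for target, idx in rows.groupby("target_id").groups.items():
        idx = np.asarray(idx)
        if len(idx) < 2:
            logger.warning("target %s has <2 models; PCC undefined", target)
            per_target_pcc[str(target)] = float("nan")
        else:
            t, p = truths[idx], predictions[idx]
            if np.std(t) == 0 or np.std(p) == 0:
                per_target_pcc[str(target)] = float("nan")
            else:
                per_target_pcc[str(target)] = float(stats.pearsonr(t, p).statistic)
        pool = rows.iloc[idx]
        for k in ks:
            losses[k][str(target)] = rank_and_loss(pool, predictions[idx], k=k)
    global_pcc = float(stats.pearsonr(truths, predictions).statistic) \
        if np.std(truths) > 0 and np.std(predictions) > 0 else float("nan")
    auc = auc_rank(predictions, truths > gdt_cutoff)
    mean_loss = {k: float(np.mean(list(v.values()))) for k, v in losses.items()}
    return EvaluationReport(per_target_pcc=per_target_pcc, global_pcc=global_pcc,
                            auc=auc, gdt_loss=losses, mean_gdt_loss=mean_loss)


# ---------------------------------------------------------------------------
# Target admission
# ---------------------------------------------------------------------------

def filter_targets(targets: pd.DataFrame, mode: str = "casp") -> pd.DataFrame:
    """Admission rules for benchmark targets.

    ``targets`` needs columns target_id, length and (for CASP mode)
    agg_fraction — the aggregation-prone fraction of the sequence.
    CASP-domain mode drops domains shorter than 100 residues (no
    significant hydrophobic core) or with aggregation-prone fraction below
    0.20; CAMEO mode drops targets shorter than 50 or longer than 500
    residues.  Dropped targets are logged with the reason.
    """
    keep = []
    for _, row in targets.iterrows():
        reason = None
        if mode == "casp":
            if row["length"] < config.CASP_MIN_DOMAIN_LENGTH:
                reason = f"length {row['length']} < {config.CASP_MIN_DOMAIN_LENGTH}"
            elif row["agg_fraction"] < config.CASP_MIN_AGG_FRACTION:
                reason = f"aggregation fraction {row['agg_fraction']:.2f} < " \
                         f"{config.CASP_MIN_AGG_FRACTION}"
        elif mode == "cameo":
            if row["length"] < config.CAMEO_MIN_LENGTH:
                reason = f"length {row['length']} < {config.CAMEO_MIN_LENGTH}"
            elif row["length"] > config.CAMEO_MAX_LENGTH:
                reason = f"length {row['length']} > {config.CAMEO_MAX_LENGTH}"
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if reason:
            logger.info("dropping target %s: %s", row["target_id"], reason)
        else:
            keep.append(row)
    return pd.DataFrame(keep, columns=targets.columns).reset_index(drop=True)
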