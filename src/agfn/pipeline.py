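"""End-to-end orchestration: the fold-wise training and evaluation loop.

For each fold: stratified patient-level partitioning; preprocessing fitted
on the training partition only; outcome-onset censoring (each patient is
censored at the *earliest* onset among their positive outcomes, the most
conservative choice for a shared-trunk multi-label model); supervised
contrastive embedding retrained on training patients; DA-KNN graph built on
training embeddings and frozen for held-out attachment; fusion-model
training with early stopping on the internal validation subset; and
held-out evaluation through frozen preprocessing and graph statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .embed import EmbedConfig, summary_features, train_encoder
from .evaluate import FoldPlan, make_folds, mean_auc
from .fusion import FusionConfig, ModelState, predict_heldout, train_fold
from .graph import GraphConfig, build_graph
from .preprocess import fit as fit_preprocessor
from .preprocess import transform
from .synthetic import OUTCOME_NAMES, CohortTable

__all__ = ["StudyConfig", "FoldResult", "label_matrix", "censor_map",
           "run_fold", "run_study", "logistic_baseline_auc"]


@dataclass(frozen=True)
class StudyConfig:
    n_folds: int = 5
    alpha: float = 0.7          # imputation decay
    horizon: int = 72
    seed: int = 0
    censoring: bool = True      # outcome-onset censoring on/off (leakage audit)
    embed: EmbedConfig = field(default_factory=EmbedConfig)
    graph: GraphConfig = field(default_factory=GraphConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)


@dataclass
class FoldResult:
    fold_id: int
    state: ModelState
    test_ids: np.ndarray
    y_test: np.ndarray
    p_test: np.ndarray
    y_val: np.ndarray
    p_val: np.ndarray
    test_auc: float
    val_auc: float


def label_matrix(cohort: CohortTable) -> tuple[np.ndarray, np.ndarray]:
    """(patient_ids, [N, 6] binary labels) in OUTCOME_NAMES order."""
    piv = cohort.outcomes.pivot(index="patient_id", columns="outcome",
                                values="label")
    piv = piv[list(OUTCOME_NAMES)]
    return piv.index.to_numpy(), piv.to_numpy().astype(int)


def censor_map(cohort: CohortTable) -> dict[int, float]:
    """patient_id -> earliest onset hour among positive outcomes."""
    pos = cohort.outcomes[cohort.outcomes["label"] == 1]
    return pos.groupby("patient_id")["onset_t_hours"].min().to_dict()


def _subset(cohort: CohortTable, ids: np.ndarray) -> CohortTable:
    ids = set(ids.tolist())
    return CohortTable(
        timeseries=cohort.timeseries[
            cohort.timeseries["patient_id"].isin(ids)].reset_index(drop=True),
        statics=cohort.statics[
            cohort.statics["patient_id"].isin(ids)].reset_index(drop=True),
        outcomes=cohort.outcomes[
            cohort.outcomes["patient_id"].isin(ids)].reset_index(drop=True))


def run_fold(cohort: CohortTable, train_ids: np.ndarray, val_ids: np.ndarray,
             test_ids: np.ndarray | None, config: StudyConfig,
             fold_id: int = 0) -> FoldResult:
    """Train and evaluate one fold with all statistics fit on train only."""
    pids, Y = label_matrix(cohort)
    y_of = dict(zip(pids.tolist(), Y))
    cmap = censor_map(cohort) if config.censoring else {}

    pre = fit_preprocessor(_subset(cohort, train_ids), alpha=config.alpha,
                           horizon=config.horizon, fold_id=fold_id)

    def tensors_for(ids):
        tdict = transform(_subset(cohort, ids), pre,
                          {p: cmap[p] for p in ids if p in cmap})
        return [tdict[p] for p in ids]

    tr = tensors_for(train_ids)
    va = tensors_for(val_ids)
    y_tr = np.array([y_of[p] for p in train_ids])
    y_va = np.array([y_of[p] for p in val_ids])

    emb_cfg = EmbedConfig(**{**config.embed.__dict__, "seed": config.seed})
    encoder, emb = train_encoder(summary_features(tr), y_tr, emb_cfg)
    graph = build_graph(emb, config.graph)
    graph._encoder = encoder  # frozen; used to attach held-out nodes

    fus_cfg = FusionConfig(**{**config.fusion.__dict__, "seed": config.seed})
    state = train_fold(tr, y_tr, va, y_va, graph, fus_cfg,
                       preprocessor_hash=pre.content_hash(), fold_id=fold_id)
    state.train_tensors = tr  # convenience for prediction/attribution

    p_va = predict_heldout(state, va, tr)
    res = FoldResult(fold_id=fold_id, state=state,
                     test_ids=np.array([]) if test_ids is None else test_ids,
                     y_test=np.empty((0, Y.shape[1])),
                     p_test=np.empty((0, Y.shape[1])),
                     y_val=y_va, p_val=p_va,
                     test_auc=float("nan"), val_auc=mean_auc(y_va, p_va))
    if test_ids is not None and len(test_ids):
        te = tensors_for(test_ids)
        p_te = predict_heldout(state, te, tr)
        res.y_test = np.array([y_of[p] for p in test_ids])
        res.p_test = p_te
        res.test_auc = mean_auc(res.y_test, p_te)
    return res


def run_study(cohort: CohortTable, config: StudyConfig = StudyConfig()
              ) -> tuple[list[FoldResult], FoldPlan]:
    """Full stratified K-fold cross-validation of the pipeline."""
    pids, Y = label_matrix(cohort)
    plan = make_folds(Y, pids, K=config.n_folds, seed=config.seed)
    plan.audit()
    results = []
    for f in range(config.n_folds):
        tr, va, te = plan.split(f)
        results.append(run_fold(cohort, tr, va, te, config, fold_id=f))
    return results, plan


def sample_fusion_config(rng: np.random.Generator,
                         base: FusionConfig = FusionConfig()) -> FusionConfig:
    """Draw one fusion configuration from the hyperparameter search space
    (heads in {2,4,8}, hidden in {64,128,256}, dropout in [0.1,0.5],
    log-uniform learning rate in [1e-5, 1e-3])."""
    return FusionConfig(
        heads=int(rng.choice([2, 4, 8])),
        hidden=int(rng.choice([64, 128, 256])),
        dropout=float(rng.uniform(0.1, 0.5)),
        lr=float(10 ** rng.uniform(-5, -3)),
        grad_clip=base.grad_clip, max_epochs=base.max_epochs,
        patience=base.patience, weight_decay=base.weight_decay,
        seed=base.seed, st=base.st, lt=base.lt)


def random_search(cohort: CohortTable, train_ids: np.ndarray,
                  val_ids: np.ndarray, config: StudyConfig,
                  n_trials: int = 10, seed: int = 0
                  ) -> tuple[FusionConfig, list[tuple[FusionConfig, float]]]:
    """Simple random search over the fusion search space.

    Each trial retrains the fold with a sampled configuration and scores it
    by internal-validation mean AUC; returns the best configuration and the
    full trial log."""
    rng = np.random.default_rng(seed)
    trials = []
    for _ in range(n_trials):
        fus = sample_fusion_config(rng, config.fusion)
        cfg = StudyConfig(**{**config.__dict__, "fusion": fus})
        res = run_fold(cohort, train_ids, val_ids, None, cfg)
        trials.append((fus, res.val_auc))
    best = max(trials, key=lambda t: t[1])[0]
    return best, trials


def logistic_baseline_auc(cohort: CohortTable, train_ids: np.ndarray,
                          eval_ids: np.ndarray, config: StudyConfig
                          ) -> float:
    """Mean validation AUC of per-outcome logistic regressions fit on the
    same summary features the contrastive encoder consumes."""
    pids, Y = label_matrix(cohort)
    y_of = dict(zip(pids.tolist(), Y))
    cmap = censor_map(cohort) if config.censoring else {}
    pre = fit_preprocessor(_subset(cohort, train_ids), alpha=config.alpha,
                           horizon=config.horizon)
    def feats(ids):
        tdict = transform(_subset(cohort, ids), pre,
                          {p: cmap[p] for p in ids if p in cmap})
        return summary_features([tdict[p] for p in ids])
    X_tr, X_ev = feats(train_ids), feats(eval_ids)
    y_tr = np.array([y_of[p] for p in train_ids])
    y_ev = np.array([y_of[p] for p in eval_ids])
    preds = np.zeros_like(y_ev, dtype=float)
    for k in range(y_tr.shape[1]):
        if len(np.unique(y_tr[:, k])) < 2:
            preds[:, k] = 0.5
            continue
        clf = LogisticRegression(max_iter=2000, C=1.0)
        clf.fit(X_tr, y_tr[:, k])
        preds[:, k] = clf.predict_proba(X_ev)[:, 1]
    return mean_auc(y_ev, preds)
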