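"""Leakage-safe cross-validation orchestration and metric computation.

Folds are built by iterative multi-label stratification over the six
outcomes at the patient level, so every fold preserves each outcome's
prevalence and all of a patient's records stay in one fold.  Within each
training fold, 10% of patients form an internal validation subset used for
early stopping and operating-threshold selection.  Discrimination is
summarized by ROC-AUC (rank statistic, half credit for ties) and AUPRC;
calibration by the Brier score, a 10-bin reliability table, and a logistic
recalibration fit giving the calibration slope and calibration-in-the-large
(intercept with slope fixed at 1).  Confidence intervals are percentile
bootstrap over patient-level resamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import (average_precision_score, brier_score_loss,
                             roc_auc_score)

__all__ = ["FoldPlan", "ConfusionCounts", "make_folds", "confusion_metrics",
           "discrimination", "select_threshold", "calibration", "bootstrap_ci",
           "subgroup_metrics", "mean_auc"]


# --------------------------------------------------------------------------
# folds
# --------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """K patient-disjoint folds plus per-fold internal validation subsets."""

    folds: list[np.ndarray]          # test patient ids per fold
    val_subsets: list[np.ndarray]    # internal validation ids per fold
    patient_ids: np.ndarray
    seed: int

    def split(self, f: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (train_ids, val_ids, test_ids) for fold f."""
        test = self.folds[f]
        val = self.val_subsets[f]
        rest = np.setdiff1d(self.patient_ids, np.concatenate([test, val]))
        return rest, val, test

    def audit(self) -> None:
        """Assert pairwise disjointness and exhaustiveness of every fold."""
        all_test = np.concatenate(self.folds)
        assert len(all_test) == len(self.patient_ids)
        assert len(np.unique(all_test)) == len(all_test)
        for f in range(len(self.folds)):
            tr, va, te = self.split(f)
            for a, b in ((tr, va), (tr, te), (va, te)):
                assert len(np.intersect1d(a, b)) == 0


def make_folds(labels: np.ndarray, patient_ids: np.ndarray | None = None,
               K: int = 5, seed: int = 0, val_frac: float = 0.10) -> FoldPlan:
    """Iterative multi-label stratification into K patient-level folds.

    ``labels`` is [N, L] binary.  Patients carrying the currently rarest
    label are distributed first, each to the fold that most needs that
    label, so per-fold prevalences track cohort prevalences even for rare
    outcomes.
    """
    labels = np.atleast_2d(np.asarray(labels).astype(int))
    n, L = labels.shape
    if K < 2 or n < K:
        raise ValueError("need K >= 2 and at least K patients")
    patient_ids = (np.arange(n) if patient_ids is None
                   else np.asarray(patient_ids))
    for k in range(L):
        if 0 < labels[:, k].sum() < K:
            warnings.warn(f"outcome {k} has fewer than {K} positive patients; "
                          "stratification is best-effort", stacklevel=2)
    rng = np.random.default_rng(seed)
    remaining = np.ones(n, dtype=bool)
    fold_of = np.full(n, -1)
    desired_size = np.full(K, n / K)
    desired = np.tile(labels.sum(axis=0) / K, (K, 1)).astype(float)  # [K, L]
    while remaining.any():
        counts = np.array([labels[remaining, k].sum() for k in range(L)])
        active = np.nonzero(counts > 0)[0]
        if len(active) == 0:
            idxs = np.nonzero(remaining)[0]
            rng.shuffle(idxs)
            for i in idxs:
                f = int(np.argmax(desired_size + rng.random(K) * 1e-9))
                fold_of[i] = f
                desired_size[f] -= 1
                remaining[i] = False
            break
        lab = active[np.argmin(counts[active])]
        idxs = np.nonzero(remaining & (labels[:, lab] == 1))[0]
        rng.shuffle(idxs)
        for i in idxs:
            score = desired[:, lab].copy()
            # tie-breaks: overall remaining capacity, then seeded noise
            f = int(np.lexsort((rng.random(K), -desired_size, -score))[0])
            fold_of[i] = f
            desired[f] -= labels[i]
            desired_size[f] -= 1
            remaining[i] = False
    folds, vals = [], []
    for f in range(K):
        test = patient_ids[fold_of == f]
        folds.append(np.sort(test))
    for f in range(K):
        train_pool = np.setdiff1d(patient_ids, folds[f])
        rng_f = np.random.default_rng(seed + 1000 + f)
        n_val = max(1, int(round(val_frac * len(train_pool))))
        vals.append(np.sort(rng_f.choice(train_pool, n_val, replace=False)))
    return FoldPlan(folds=folds, val_subsets=vals, patient_ids=patient_ids,
                    seed=seed)


# --------------------------------------------------------------------------
# operating-point metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, PPV, NPV and number needed to screen.

    Metrics with a zero denominator come back as nan sentinels.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "nns": ratio(tp + fp, tp),
    }


# --------------------------------------------------------------------------
# discrimination
# --------------------------------------------------------------------------

def select_threshold(y_val: np.ndarray, p_val: np.ndarray,
                     mode: str = "f1", min_sensitivity: float = 0.92) -> float:
    """Operating threshold chosen on the internal validation subset.

    mode "f1": maximize F1.  mode "sens92": the highest threshold whose
    validation sensitivity still meets the floor (high-sensitivity
    screening regime).
    """
    y_val = np.asarray(y_val).astype(int)
    p_val = np.asarray(p_val, dtype=float)
    cand = np.unique(p_val)
    best_t, best_score = 0.5, -np.inf
    if mode == "f1":
        for t in cand:
            pred = p_val >= t
            tp = int((pred & (y_val == 1)).sum())
            fp = int((pred & (y_val == 0)).sum())
            fn = int((~pred & (y_val == 1)).sum())
            f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
            if f1 > best_score:
                best_score, best_t = f1, float(t)
        return best_t
    if mode == "sens92":
        n_pos = (y_val == 1).sum()
        ok = [float(t) for t in cand
              if n_pos and ((p_val >= t) & (y_val == 1)).sum() / n_pos
              >= min_sensitivity]
        return max(ok) if ok else float(cand.min())
    raise ValueError(f"unknown threshold mode {mode!r}")


def discrimination(y_true: np.ndarray, scores: np.ndarray,
                   threshold: float = 0.5) -> dict[str, float]:
    """ROC-AUC, AUPRC and precision/recall/F1 at the given threshold."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        return {"auc": float("nan"), "auprc": float("nan"),
                "precision": float("nan"), "recall": float("nan"),
                "f1": float("nan")}
    auc = float(roc_auc_score(y, s))
    auprc = float(average_precision_score(y, s))
    pred = s >= threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    prec = tp / (tp + fp) if tp + fp else float("nan")
    rec = tp / (tp + fn) if tp + fn else float("nan")
    f1 = (2 * prec * rec / (prec + rec)
          if prec + rec and not np.isnan(prec + rec) else float("nan"))
    return {"auc": auc, "auprc": auprc, "precision": prec, "recall": rec,
            "f1": f1}


def mean_auc(y: np.ndarray, p: np.ndarray) -> float:
    """Arithmetic mean of the per-outcome ROC-AUCs (nan outcomes dropped)."""
    vals = [discrimination(y[:, k], p[:, k])["auc"] for k in range(y.shape[1])]
    vals = [v for v in vals if not np.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

def calibration(y_true: np.ndarray, p: np.ndarray, bins: int = 10
                ) -> dict[str, object]:
    """Brier score, 10-bin reliability table, slope and in-the-large."""
    y = np.asarray(y_true).astype(int)
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    if len(y) < bins:
        raise ValueError("need at least as many samples as bins")
    brier = float(brier_score_loss(y, p))
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, bins - 1)
    table = pd.DataFrame({
        "bin": np.arange(bins),
        "mean_pred": [p[idx == b].mean() if (idx == b).any() else np.nan
                      for b in range(bins)],
        "event_rate": [y[idx == b].mean() if (idx == b).any() else np.nan
                       for b in range(bins)],
        "count": [(idx == b).sum() for b in range(bins)],
    })
    pc = np.clip(p, 1e-9, 1.0 - 1e-9)  # boundary predictions: finite logits
    lp = np.log(pc / (1.0 - pc))
    slope = intercept = itl = float("nan")
    if len(np.unique(y)) == 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, sm.add_constant(lp),
                         family=sm.families.Binomial()).fit()
            intercept, slope = float(fit.params[0]), float(fit.params[1])
            fit0 = sm.GLM(y, np.ones((len(y), 1)), offset=lp,
                          family=sm.families.Binomial()).fit()
            itl = float(fit0.params[0])
    return {"brier": brier, "reliability": table, "slope": slope,
            "intercept": intercept, "in_the_large": itl}


# --------------------------------------------------------------------------
# bootstrap and subgroups
# --------------------------------------------------------------------------

def bootstrap_ci(metric_fn, y: np.ndarray, p: np.ndarray, B: int = 1000,
                 seed: int = 0, alpha: float = 0.05
                 ) -> tuple[float, float]:
    """Percentile bootstrap CI over patient-level resamples."""
    if B < 100:
        raise ValueError("need at least 100 bootstrap resamples")
    y = np.asarray(y)
    p = np.asarray(p)
    rng = np.random.default_rng(seed)
    n = len(y)
    stats = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, n)
        try:
            stats[b] = metric_fn(y[idx], p[idx])
        except Exception:
            stats[b] = np.nan
    bad = np.isnan(stats).mean()
    if bad > 0.10:
        warnings.warn(f"metric undefined on {bad:.0%} of resamples; "
                      "CI reported as NA", stacklevel=2)
        return (float("nan"), float("nan"))
    lo, hi = np.nanpercentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def subgroup_metrics(y_true: np.ndarray, p: np.ndarray, groups: np.ndarray
                     ) -> dict[str, object]:
    """Per-group AUC and Brier plus max absolute deviation from pooled."""
    y = np.asarray(y_true).astype(int)
    p = np.asarray(p, dtype=float)
    groups = np.asarray(groups)
    pooled_auc = discrimination(y, p)["auc"]
    pooled_brier = float(np.mean((p - y) ** 2))
    per_group = {}
    for g in pd.unique(groups):
        m = groups == g
        if m.sum() < 2 or len(np.unique(y[m])) < 2:
            warnings.warn(f"subgroup {g!r} degenerate; skipped", stacklevel=2)
            continue
        per_group[str(g)] = {
            "n": int(m.sum()),
            "auc": discrimination(y[m], p[m])["auc"],
            "brier": float(np.mean((p[m] - y[m]) ** 2)),
        }
    dev_auc = max((abs(v["auc"] - pooled_auc) for v in per_group.values()),
                  default=float("nan"))
    dev_brier = max((abs(v["brier"] - pooled_brier)
                     for v in per_group.values()), default=float("nan"))
    return {"pooled": {"auc": pooled_auc, "brier": pooled_brier},
            "groups": per_group, "max_auc_deviation": dev_auc,
            "max_brier_deviation": dev_brier}
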