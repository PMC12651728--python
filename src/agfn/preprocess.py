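"""Fold-safe preprocessing for irregular clinical time series.

All data-dependent statistics (winsorization bounds at the 0.5th/99.5th
percentiles, per-variable median and IQR for robust scaling, fallback
baselines) are fitted on training-fold patients only and frozen; transforming
held-out partitions never refits.  Missing values are filled by decay-aware
exponential smoothing toward the patient-specific baseline,

    x~_t = m_t * x_t + (1 - m_t) * (alpha * x~_{t-1} + (1 - alpha) * xbar),

so imputations for long gaps revert geometrically to stable patient-level
statistics.  Outcome-onset censoring masks every measurement at or after the
onset time and recomputes the baseline, imputation, slope and delta features
from the pre-onset window only, preventing temporal leakage.

Quantile convention: linear interpolation between order statistics
(numpy default), stated explicitly because winsorization and IQR tests
depend on it.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .synthetic import CohortTable

__all__ = ["FittedPreprocessor", "PatientTensor", "winsorize", "impute_decay",
           "derive_slope", "derive_delta", "robust_scale", "censor_at_onset",
           "fit", "transform"]

SLOPE_SENTINEL = 0.0  # undefined slope: 0 plus a flag, not an arbitrary magnitude


@dataclass(frozen=True)
class FittedPreprocessor:
    """Frozen training-partition statistics for one cross-validation fold."""

    variables: tuple[str, ...]                 # temporal variable order (D)
    winsor_lo: np.ndarray                      # [D] 0.5th percentile
    winsor_hi: np.ndarray                      # [D] 99.5th percentile
    median: np.ndarray                         # [D] of winsorized training values
    iqr: np.ndarray                            # [D]
    fallback_baseline: np.ndarray              # [D] training medians (raw scale)
    static_numeric: tuple[str, ...]
    static_numeric_median: np.ndarray
    static_numeric_iqr: np.ndarray
    static_binary: tuple[str, ...]
    static_levels: dict = field(default_factory=dict)  # categorical level maps
    alpha: float = 0.7
    horizon: int = 72
    fold_id: int = -1

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if np.any(self.winsor_lo > self.winsor_hi):
            raise ValueError("winsor_lo exceeds winsor_hi")
        if np.any(self.iqr < 0):
            raise ValueError("negative IQR")

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for arr in (self.winsor_lo, self.winsor_hi, self.median, self.iqr,
                    self.fallback_baseline, self.static_numeric_median,
                    self.static_numeric_iqr):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(repr((self.variables, self.static_numeric, self.static_binary,
                       sorted(self.static_levels.items()), self.alpha,
                       self.horizon)).encode())
        return h.hexdigest()


@dataclass
class PatientTensor:
    """One patient's aligned hourly grid with values, mask and statics."""

    patient_id: int
    t_grid: np.ndarray       # [T] bin left edges, hours
    raw: np.ndarray          # [T, D] winsorized observed bin means, NaN unobserved
    X: np.ndarray            # [T, D] robust-scaled imputed values
    M: np.ndarray            # [T, D] 1 where observed (pre-censoring)
    xbar: np.ndarray         # [D] patient baseline (raw scale, observed pre-censor)
    statics: np.ndarray      # [S] encoded static vector
    slope: np.ndarray        # [D] per-variable trend, scaled units/hour
    slope_defined: np.ndarray  # [D] 0 where the slope sentinel was used
    delta: np.ndarray        # [T, D] stepwise differences of X (0 at t=0)
    censor_t: float | None = None
    _fit: FittedPreprocessor | None = field(default=None, repr=False)


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------

def winsorize(values, bounds: tuple[float, float]) -> np.ndarray:
    """Clip values to fitted (q0.005, q0.995) bounds, elementwise."""
    if bounds is None:
        raise ValueError("winsorization bounds have not been fitted")
    values = np.asarray(values, dtype=float)
    bad = np.nonzero(~np.isfinite(values))[0]
    if len(bad):
        raise ValueError(f"non-finite input at index {bad[0]}")
    lo, hi = bounds
    return np.clip(values, lo, hi)


def impute_decay(values, mask, alpha: float, xbar: float) -> np.ndarray:
    """Left-to-right decay imputation; the first step decays from xbar."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask)
    out = np.empty_like(values)
    prev = float(xbar)  # x~_0 initialisation: patient baseline
    for t in range(len(values)):
        if mask[t]:
            out[t] = values[t]
        else:
            out[t] = alpha * prev + (1.0 - alpha) * xbar
        prev = out[t]
    return out


def derive_slope(first: tuple[float, float],
                 last: tuple[float, float]) -> tuple[float, bool]:
    """Trend per hour between first and last observation.

    Returns (slope, defined); a degenerate window (t_n == t_1) yields the
    sentinel 0.0 with defined=False so downstream encoders see "no trend
    information" rather than an arbitrary magnitude.
    """
    (t1, x1), (tn, xn) = first, last
    if tn == t1:
        return SLOPE_SENTINEL, False
    return (xn - x1) / (tn - t1), True


def derive_delta(series) -> np.ndarray:
    """Stepwise differences x_t - x_{t-1}; length = len(series) - 1."""
    series = np.asarray(series, dtype=float)
    return np.diff(series)


def robust_scale(values, median: float, iqr: float) -> np.ndarray:
    """(x - median)/IQR; a zero IQR maps everything to 0 with a warning."""
    if median is None or iqr is None:
        raise ValueError("scaling statistics have not been fitted")
    values = np.asarray(values, dtype=float)
    if iqr == 0:
        warnings.warn("zero IQR: scaled values set to 0", stacklevel=2)
        return np.zeros_like(values)
    return (values - median) / iqr


# --------------------------------------------------------------------------
# fit / transform
# --------------------------------------------------------------------------

def fit(cohort: CohortTable, alpha: float = 0.7, horizon: int = 72,
        fold_id: int = -1) -> FittedPreprocessor:
    """Fit all preprocessing statistics on a training cohort."""
    ts = cohort.timeseries
    variables = tuple(sorted(ts["variable"].unique()))
    lo, hi, med, iqr, fallback = [], [], [], [], []
    for v in variables:
        vals = ts.loc[ts["variable"] == v, "value"].to_numpy(float)
        if np.isin(np.unique(vals), (0.0, 1.0)).all():
            # binary channels (interventions, one-hot) pass through unscaled
            lo.append(0.0); hi.append(1.0)
            med.append(0.0); iqr.append(1.0)
            fallback.append(0.0)
            continue
        q_lo, q_hi = np.quantile(vals, [0.005, 0.995])
        w = np.clip(vals, q_lo, q_hi)
        q1, q2, q3 = np.quantile(w, [0.25, 0.5, 0.75])
        lo.append(q_lo); hi.append(q_hi)
        med.append(q2); iqr.append(q3 - q1)
        fallback.append(q2)

    st = cohort.statics.drop(columns=["patient_id"], errors="ignore")
    st = st.drop(columns=["rare"], errors="ignore")  # generator bookkeeping
    numeric, binary, levels = [], [], {}
    for col in st.columns:
        series = st[col]
        if series.dtype == object:
            levels[col] = tuple(sorted(series.dropna().unique()))
        elif set(pd.unique(series.dropna())) <= {0, 1}:
            binary.append(col)
        else:
            numeric.append(col)
    num_med = np.array([st[c].median() for c in numeric])
    num_iqr = np.array([st[c].quantile(0.75) - st[c].quantile(0.25)
                        for c in numeric])
    return FittedPreprocessor(
        variables=variables, winsor_lo=np.array(lo), winsor_hi=np.array(hi),
        median=np.array(med), iqr=np.array(iqr),
        fallback_baseline=np.array(fallback),
        static_numeric=tuple(numeric), static_numeric_median=num_med,
        static_numeric_iqr=num_iqr, static_binary=tuple(binary),
        static_levels=levels, alpha=alpha, horizon=horizon, fold_id=fold_id)


def _finalize(raw: np.ndarray, fitted: FittedPreprocessor
              ) -> tuple[np.ndarray, ...]:
    """Recompute baseline, imputation, scaling and derived features from a
    (possibly censored) raw observation grid."""
    T, D = raw.shape
    M = (~np.isnan(raw)).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(raw, axis=0)
    xbar = np.where(M.sum(0) > 0, np.nan_to_num(col_mean),
                    fitted.fallback_baseline)
    X = np.empty_like(raw)
    slope = np.zeros(D)
    slope_def = np.zeros(D)
    for d in range(D):
        imput = impute_decay(np.nan_to_num(raw[:, d]), M[:, d],
                             fitted.alpha, xbar[d])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            X[:, d] = robust_scale(imput, fitted.median[d], fitted.iqr[d])
        obs = np.nonzero(M[:, d])[0]
        if len(obs) >= 1:
            s, ok = derive_slope((float(obs[0]), X[obs[0], d]),
                                 (float(obs[-1]), X[obs[-1], d]))
            slope[d], slope_def[d] = s, float(ok)
    delta = np.zeros_like(X)
    if T > 1:
        delta[1:] = np.diff(X, axis=0)
    return M, xbar, X, slope, slope_def, delta


def _encode_statics(row: pd.Series, fitted: FittedPreprocessor) -> np.ndarray:
    parts = []
    for c, m, q in zip(fitted.static_numeric, fitted.static_numeric_median,
                       fitted.static_numeric_iqr):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            parts.append(float(robust_scale([row[c]], m, q)[0]))
    for c in fitted.static_binary:
        parts.append(float(row[c]))
    for c, lvls in fitted.static_levels.items():
        onehot = [1.0 if row[c] == lv else 0.0 for lv in lvls]
        parts.extend(onehot)
    return np.array(parts)


def transform(cohort: CohortTable, fitted: FittedPreprocessor,
              censor_times: dict[int, float] | None = None
              ) -> dict[int, PatientTensor]:
    """Apply frozen statistics to a cohort; returns tensors keyed by patient.

    ``censor_times`` maps patient_id -> onset hour; measurements at or after
    that hour are masked before any derived statistic is computed.
    """
    if fitted is None:
        raise ValueError("transform called before fit")
    censor_times = censor_times or {}
    ts = cohort.timeseries
    unknown = set(ts["variable"].unique()) - set(fitted.variables)
    if unknown:
        warnings.warn(f"dropping variables absent from the training fit: "
                      f"{sorted(unknown)}", stacklevel=2)
        ts = ts[~ts["variable"].isin(unknown)]
    T = fitted.horizon
    var_idx = {v: d for d, v in enumerate(fitted.variables)}
    D = len(fitted.variables)

    binned = ts.copy()
    binned["bin"] = np.floor(binned["t_hours"]).astype(int)
    binned = binned[(binned["bin"] >= 0) & (binned["bin"] < T)]
    grouped = binned.groupby(["patient_id", "variable", "bin"])["value"].mean()

    statics = cohort.statics.set_index("patient_id")
    out: dict[int, PatientTensor] = {}
    grid = np.arange(T, dtype=float)
    by_pid = grouped.reset_index().groupby("patient_id")
    groups = {pid: g for pid, g in by_pid}
    for pid in statics.index:
        raw = np.full((T, D), np.nan)
        g = groups.get(pid)
        if g is not None:
            d_idx = g["variable"].map(var_idx).to_numpy()
            vals = np.clip(g["value"].to_numpy(float),
                           fitted.winsor_lo[d_idx], fitted.winsor_hi[d_idx])
            raw[g["bin"].to_numpy(), d_idx] = vals
        ct = censor_times.get(pid)
        if ct is not None:
            raw[grid >= ct] = np.nan
        M, xbar, X, slope, slope_def, delta = _finalize(raw, fitted)
        out[pid] = PatientTensor(
            patient_id=int(pid), t_grid=grid.copy(), raw=raw, X=X, M=M,
            xbar=xbar, statics=_encode_statics(statics.loc[pid], fitted),
            slope=slope, slope_defined=slope_def, delta=delta,
            censor_t=ct, _fit=fitted)
    return out


def censor_at_onset(patient: PatientTensor, onset_t: float | None
                    ) -> PatientTensor:
    """Mask all measurements at or after onset and recompute derived features.

    With onset absent (label 0) the tensor is returned unchanged; statics are
    always retained.
    """
    if onset_t is None:
        return patient
    if patient._fit is None:
        raise ValueError("tensor lacks fitted statistics; censor via transform")
    raw = patient.raw.copy()
    raw[patient.t_grid >= onset_t] = np.nan
    M, xbar, X, slope, slope_def, delta = _finalize(raw, patient._fit)
    return replace(patient, raw=raw, X=X, M=M, xbar=xbar, slope=slope,
                   slope_defined=slope_def, delta=delta, censor_t=onset_t)
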