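"""Synthetic ICU cohort generator.

Emulates the statistical structure of multi-center ICU data that the pipeline
assumes, so every downstream stage is testable without credentialed access to
a real database: sub-hourly vitals, sparsely and *informatively* sampled labs
(sicker patients get more lab draws), static demographics/comorbidities, six
correlated binary outcomes with onset timestamps, and a rare-phenotype
subpopulation occupying a sparse region of feature space.

The data-generating process
---------------------------
Each patient carries a latent severity trajectory on an hourly grid,

    sev(t) = baseline + drift * t/horizon + u(t),    u(t) = 0.95 u(t-1) + e(t),

a first-order autoregressive process whose coefficient 0.95 yields both slow
drifts and acute excursions.  Vitals and labs are noisy linear loadings on
severity; lab observation probability increases with concurrent severity
(informative missingness).  Outcome k is positive when max_t sev(t) plus
independent patient-outcome noise exceeds a threshold calibrated to the
target prevalence, and the onset time is the first threshold crossing; the
six outcomes share the severity process and are therefore correlated but not
identical.  A rare subpopulation draws statics and severity loadings from a
shifted distribution, giving the density-adaptive graph a sparse region to
adapt to.  All randomness flows through one seeded generator per cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "CohortTable", "SimInternals", "simulate_cohort",
           "write_cohort", "read_cohort", "OUTCOME_NAMES"]

OUTCOME_NAMES = ("mortality", "sepsis", "aki", "resp_failure",
                 "cardiac_arrest", "prolonged_stay")

_VITAL_NAMES = ("heart_rate", "map", "spo2", "resp_rate")
_LAB_NAMES = ("lactate", "bilirubin", "creatinine", "ph")
# (intercept, loading on severity, measurement noise sd)
_VITAL_PARAMS = {"heart_rate": (85.0, 12.0, 3.0), "map": (78.0, -9.0, 4.0),
                 "spo2": (96.0, -2.2, 0.8), "resp_rate": (18.0, 4.0, 1.5)}
_LAB_PARAMS = {"lactate": (1.8, 1.4, 0.35), "bilirubin": (1.0, 0.8, 0.25),
               "creatinine": (1.1, 0.7, 0.2), "ph": (7.38, -0.06, 0.02)}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the regime the pipeline is designed for: sub-hourly
    vitals with <5% missingness, labs at a median ~8 h interval with >40%
    missingness for the flagged labs (lactate, bilirubin), a 72 h horizon,
    and six outcome prevalences at realistic ICU rates.
    """

    n_patients: int = 2000
    horizon_hours: int = 72
    n_vitals: int = 4
    n_labs: int = 4
    vital_interval_h: float = 0.5
    lab_interval_h: float = 8.0
    vital_missing_rate: float = 0.03
    lab_missing_rate: float = 0.45
    outcome_prevalences: tuple[float, ...] = (0.10, 0.15, 0.20, 0.15, 0.05, 0.25)
    rare_cluster_fraction: float = 0.05
    seed: int = 0
    # severity process and noise, fixed study conditions
    ar_coef: float = 0.95
    outcome_noise_sd: float = 0.4
    informative_slope: float = 0.8  # logit-slope of lab observation on severity
    include_interventions: bool = True  # vasopressor / ventilation markers

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.horizon_hours <= 0:
            raise ValueError("horizon_hours must be positive")
        if len(self.outcome_prevalences) != 6:
            raise ValueError("exactly six outcome prevalences are required")
        for p in self.outcome_prevalences:
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence {p} outside (0,1)")
        for name in ("vital_missing_rate", "lab_missing_rate",
                     "rare_cluster_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")


@dataclass
class SimInternals:
    """Generator-internal quantities exposed for auditing, never serialized."""

    severity: np.ndarray          # [n_patients, horizon+1] hourly severity
    rare_mask: np.ndarray         # [n_patients] bool
    static_features: np.ndarray   # [n_patients, n_statics] standardized
    lab_draw_severity: np.ndarray  # severity at each scheduled flagged-lab draw
    lab_draw_observed: np.ndarray  # observed flag per scheduled flagged-lab draw


@dataclass
class CohortTable:
    """Long-format time series + per-patient statics + outcome labels."""

    timeseries: pd.DataFrame  # patient_id, variable, t_hours, value
    statics: pd.DataFrame     # patient_id, age, sex, ... comorbidity flags
    outcomes: pd.DataFrame    # patient_id, outcome, label, onset_t_hours
    internals: SimInternals | None = field(default=None, compare=False, repr=False)

    def __eq__(self, other):
        if not isinstance(other, CohortTable):
            return NotImplemented
        return (self.timeseries.equals(other.timeseries)
                and self.statics.equals(other.statics)
                and self.outcomes.equals(other.outcomes))


def _variable_names(config: SimConfig) -> tuple[list[str], list[str]]:
    vitals = [_VITAL_NAMES[i] if i < len(_VITAL_NAMES) else f"vital_{i}"
              for i in range(config.n_vitals)]
    labs = [_LAB_NAMES[i] if i < len(_LAB_NAMES) else f"lab_{i}"
            for i in range(config.n_labs)]
    return vitals, labs


def flagged_labs(config: SimConfig) -> list[str]:
    """Labs subject to the high (informative) missingness regime."""
    _, labs = _variable_names(config)
    n_flagged = max(1, config.n_labs // 2)
    return labs[:n_flagged]


def _var_params(name: str, rng: np.random.Generator) -> tuple[float, float, float]:
    if name in _VITAL_PARAMS:
        return _VITAL_PARAMS[name]
    if name in _LAB_PARAMS:
        return _LAB_PARAMS[name]
    return (float(rng.normal(50, 10)), float(rng.normal(0, 5)), 2.0)


def _calibrate_obs_intercept(sev: np.ndarray, slope: float,
                             target_obs: float) -> float:
    """Bisection for a with mean(logistic(a + slope*sev)) == target_obs."""
    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(mid + slope * sev)))) < target_obs:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(config: SimConfig) -> CohortTable:
    """Generate one cohort; byte-identical output for identical configs."""
    rng = np.random.default_rng(config.seed)
    n, horizon = config.n_patients, config.horizon_hours
    hours = np.arange(horizon + 1, dtype=float)

    # -- latent severity: AR(1) around baseline + linear drift ---------------
    rare = rng.random(n) < config.rare_cluster_fraction
    baseline = rng.normal(0.0, 0.7, n)
    drift = rng.normal(0.0, 0.5, n)
    innov_sd = np.sqrt(1.0 - config.ar_coef ** 2)  # unit stationary variance
    u = np.empty((n, horizon + 1))
    u[:, 0] = rng.normal(0.0, 1.0, n)
    for t in range(1, horizon + 1):
        u[:, t] = config.ar_coef * u[:, t - 1] + rng.normal(0.0, innov_sd, n)
    severity = baseline[:, None] + drift[:, None] * (hours / horizon)[None, :] + u

    # -- statics: demographics + comorbidities; rare cluster shifted ---------
    age = rng.normal(63.4, 14.9, n)
    sex = (rng.random(n) < 0.547).astype(int)  # 1 = male
    bmi = rng.normal(27.0, 5.0, n)
    com = {"diabetes": 0.25, "ckd": 0.15, "copd": 0.12, "cvd": 0.30}
    flags = {k: (rng.random(n) < p).astype(int) for k, p in com.items()}
    age[rare] += 15.0
    bmi[rare] -= 4.0
    flags["ckd"][rare] = (rng.random(int(rare.sum())) < 0.8).astype(int)
    # per-patient severity-loading multiplier; the rare phenotype expresses
    # severity more strongly, shifting it in observable feature space
    load_mult = np.where(rare, rng.normal(1.6, 0.1, n), rng.normal(1.0, 0.1, n))

    statics = pd.DataFrame({
        "patient_id": np.arange(n), "age": age, "sex": sex, "bmi": bmi,
        **flags, "rare": rare.astype(int),
    })
    static_std = statics.drop(columns=["patient_id", "rare"]).to_numpy(float)
    static_std = np.column_stack([static_std, load_mult])
    static_std = (static_std - static_std.mean(0)) / (static_std.std(0) + 1e-12)

    # -- time series ---------------------------------------------------------
    vitals, labs = _variable_names(config)
    flagged = set(flagged_labs(config))
    vital_t = np.arange(0.0, horizon, config.vital_interval_h)
    lab_t = np.arange(0.0, horizon, config.lab_interval_h)

    def sev_at(t: np.ndarray) -> np.ndarray:
        idx = np.clip(t.astype(int), 0, horizon - 1)
        frac = t - idx
        return severity[:, idx] * (1 - frac) + severity[:, idx + 1] * frac

    sev_v = sev_at(vital_t) * load_mult[:, None]      # [n, len(vital_t)]
    sev_l = sev_at(lab_t) * load_mult[:, None]

    frames = []
    lab_draw_sev, lab_draw_obs = [], []
    for name in vitals:
        icpt, load, noise = _var_params(name, rng)
        vals = icpt + load * sev_v + rng.normal(0, noise, sev_v.shape)
        obs = rng.random(sev_v.shape) >= config.vital_missing_rate
        pid, tt = np.nonzero(obs)
        frames.append(pd.DataFrame({"patient_id": pid, "variable": name,
                                    "t_hours": vital_t[tt],
                                    "value": vals[pid, tt]}))
    for name in labs:
        icpt, load, noise = _var_params(name, rng)
        vals = icpt + load * sev_l + rng.normal(0, noise, sev_l.shape)
        miss_rate = config.lab_missing_rate if name in flagged else 0.15
        a = _calibrate_obs_intercept(sev_l.ravel(), config.informative_slope,
                                     1.0 - miss_rate)
        p_obs = 1.0 / (1.0 + np.exp(-(a + config.informative_slope * sev_l)))
        obs = rng.random(sev_l.shape) < p_obs
        if name in flagged:
            lab_draw_sev.append(sev_l.ravel())
            lab_draw_obs.append(obs.ravel())
        pid, tt = np.nonzero(obs)
        frames.append(pd.DataFrame({"patient_id": pid, "variable": name,
                                    "t_hours": lab_t[tt],
                                    "value": vals[pid, tt]}))
    # -- outcomes: thresholded max severity + independent noise --------------
    max_sev = severity.max(axis=1)
    out_rows = []
    min_onset = np.full(n, np.inf)
    for k, (name, prev) in enumerate(zip(OUTCOME_NAMES,
                                         config.outcome_prevalences)):
        eps = rng.normal(0.0, config.outcome_noise_sd, n)
        score = max_sev + eps
        theta = float(np.quantile(score, 1.0 - prev))
        label = score > theta
        # calibration loop: nudge theta if the realized rate is off-target
        tol = max(0.02, 2.0 / np.sqrt(n))
        for _ in range(50):
            realized = label.mean()
            if abs(realized - prev) <= tol:
                break
            theta += 0.01 if realized > prev else -0.01
            label = score > theta
        else:
            raise ValueError(
                f"could not calibrate prevalence {prev} for outcome {name} "
                f"at the configured noise level (realized {label.mean():.3f})")
        # onset: first hour the severity path crosses the patient's margin
        margin = theta - eps  # label=1 iff max_t sev(t) > margin
        crossed = severity > margin[:, None]
        onset = np.where(label, crossed.argmax(axis=1).astype(float), np.nan)
        min_onset = np.fmin(min_onset, np.where(label, onset, np.inf))
        out_rows.append(pd.DataFrame({
            "patient_id": np.arange(n), "outcome": name,
            "label": label.astype(int), "onset_t_hours": onset}))
    outcomes = pd.concat(out_rows, ignore_index=True)

    # therapeutic interventions: binary markers of severe physiological
    # states, plus a treatment-escalation channel administered in response
    # to the first outcome event — recorded only from onset onward, it is
    # exactly the post-onset signal the censoring rule must remove
    if config.include_interventions:
        t_int = np.arange(0.0, float(horizon), 1.0)
        sev_i = sev_at(t_int) * load_mult[:, None]
        chans = {"vasopressor": (sev_i > 1.1).astype(float),
                 "mech_vent": (sev_i > 1.6).astype(float),
                 "treatment_escalation":
                     (t_int[None, :] >= min_onset[:, None]).astype(float)}
        for name, vals in chans.items():
            obs = rng.random(vals.shape) >= 0.03
            pid, tt = np.nonzero(obs)
            frames.append(pd.DataFrame({"patient_id": pid, "variable": name,
                                        "t_hours": t_int[tt],
                                        "value": vals[pid, tt]}))

    timeseries = (pd.concat(frames, ignore_index=True)
                  .sort_values(["patient_id", "variable", "t_hours"],
                               kind="mergesort")
                  .reset_index(drop=True))

    internals = SimInternals(
        severity=severity, rare_mask=rare, static_features=static_std,
        lab_draw_severity=np.concatenate(lab_draw_sev),
        lab_draw_observed=np.concatenate(lab_draw_obs))
    return CohortTable(timeseries=timeseries, statics=statics,
                       outcomes=outcomes, internals=internals)


# -- plain-text persistence ---------------------------------------------------

_FILES = {"timeseries": "timeseries.csv", "statics": "statics.csv",
          "outcomes": "outcomes.csv"}


def write_cohort(cohort: CohortTable, path) -> None:
    """Write the three tables as UTF-8 CSVs with header rows."""
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for attr, fname in _FILES.items():
        # %.17g guarantees bit-exact float64 round trip through text
        getattr(cohort, attr).to_csv(path / fname, index=False,
                                     float_format="%.17g")


def _check_rows(df: pd.DataFrame, fname: str) -> None:
    if "patient_id" in df.columns:
        bad = df.index[df["patient_id"].isna()]
        if len(bad):
            raise ValueError(f"{fname}: missing patient_id at row {bad[0]}")
    if "t_hours" in df.columns:
        bad = df.index[df["t_hours"] < 0]
        if len(bad):
            raise ValueError(f"{fname}: negative t_hours at row {bad[0]}")


def read_cohort(path) -> CohortTable:
    """Read a cohort written by :func:`write_cohort`; validates invariants."""
    from pathlib import Path

    path = Path(path)
    dfs = {}
    for attr, fname in _FILES.items():
        df = pd.read_csv(path / fname, float_precision="round_trip")
        _check_rows(df, fname)
        dfs[attr] = df
    out = dfs["outcomes"]
    if len(out):
        mismatch = (out["label"] == 1) != out["onset_t_hours"].notna()
        if mismatch.any():
            raise ValueError(
                f"outcomes.csv: onset_t_hours must be present iff label=1 "
                f"(row {out.index[mismatch][0]})")
    return CohortTable(timeseries=dfs["timeseries"], statics=dfs["statics"],
                       outcomes=dfs["outcomes"])
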