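"""Seeded synthetic ICU cohorts with latent OSI-trajectory classes.

The generator emulates the structure the downstream analysis assumes: four
latent trajectory classes (low-level stable, ascending, descending,
high-level stable) with class-specific polynomial OSI means on a 6-hourly
grid over 5 days, baseline covariates whose distributions shift with class,
a binary mediator (ARDS) on the class -> death pathway, class-graded ICU
mortality, ventilation durations and 21-day death times.

Defaults are calibrated to the published cohort: class shares
2194/301/700/183 of n=3378, baseline OSI medians 5.22/9.38/12.00/17.07,
ICU mortality 20.69/31.56/21.29/40.98 %, ARDS prevalence
54.9/70.1/68.9/77.1 %.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from osipheno.containers import DEFAULT_GRID_HOURS, TrajectoryMatrix

# ---------------------------------------------------------------------------
# default study conditions (per latent class: low-stable, ascending,
# descending, high-stable)

_N_DEFAULT = 3378
_SHARES_DEFAULT = (2194 / 3378, 301 / 3378, 700 / 3378, 183 / 3378)

#: polynomial mean OSI vs time in days: intercepts at the published baseline
#: medians; ascending rises ~9.4 -> 15, descending falls ~12 -> 7 over 5 days
_COEF_DEFAULT = (
    (5.22, 0.0),
    (9.38, 1.18),
    (12.00, -1.05),
    (17.07, 0.0),
)

#: continuous covariates: per-class means, a common SD, and the loading on a
#: shared patient-level illness-severity factor (creates the within-class
#: covariate correlation seen in real cohorts).  Between-class gaps are kept
#: moderate relative to the SD so every class retains support everywhere in
#: covariate space (positivity); class directions follow the observed cohort.
_CONTINUOUS_DEFAULT = {
    "age": {"means": (62.13, 58.63, 60.63, 57.63), "sd": 15.0, "severity_loading": 0.0},
    "bmi": {"means": (28.09, 29.99, 29.59, 31.99), "sd": 7.0, "severity_loading": 0.3},
    "paco2": {"means": (41.01, 43.56, 44.06, 45.56), "sd": 10.0, "severity_loading": 0.5},
    "hemoglobin": {"means": (10.77, 10.97, 10.97, 10.97), "sd": 2.0, "severity_loading": 0.0},
    "peep": {"means": (5.91, 6.41, 7.16, 7.91), "sd": 2.5, "severity_loading": 0.5},
    "plateau_pressure": {"means": (19.04, 21.04, 22.04, 23.54), "sd": 5.0, "severity_loading": 0.5},
    "tidal_volume": {"means": (478.8, 488.8, 471.8, 466.3), "sd": 80.0, "severity_loading": 0.0},
    "aps_iii": {"means": (72.89, 76.89, 76.89, 85.89), "sd": 25.0, "severity_loading": 0.6},
}

#: binary covariates: per-class prevalence (same positivity-preserving
#: compression of between-class gaps, directions as observed)
_BINARY_DEFAULT = {
    "gender_male": (0.5624, 0.5957, 0.5794, 0.5856),
    "copd": (0.2034, 0.2262, 0.2199, 0.2224),
    "ckd": (0.0727, 0.0636, 0.0675, 0.0709),
    "aki": (0.4394, 0.4990, 0.5022, 0.5375),
    "malignancy": (0.0674, 0.0602, 0.0729, 0.0555),
    "heart_failure": (0.1919, 0.1908, 0.2078, 0.2017),
    "diabetes": (0.2410, 0.2168, 0.2469, 0.2571),
    "dialysis": (0.1352, 0.1830, 0.1724, 0.2488),
    "nmba": (0.1506, 0.2694, 0.2123, 0.3211),
    "vasopressor": (0.4829, 0.5936, 0.6045, 0.6319),
}

#: ethnicity shared across classes (three levels)
_ETHNICITY_PROBS = (0.109, 0.668, 0.223)
_ETHNICITY_LEVELS = ("black", "white", "other")

#: ARDS (mediator) model: class intercepts at the logit of the published
#: per-class prevalence, plus mild dependence on severity covariates
#: (coefficients on population-standardized scales)
_MEDIATOR_DEFAULT = {
    "prevalence": (0.549, 0.701, 0.689, 0.771),
    "coef": {"aps_iii": 0.25, "peep": 0.15},
}

#: death model: logistic in class (calibrated intercepts), ARDS and
#: severity covariates; ARDS odds ratio ~1.456 as reported for the cohort
_OUTCOME_DEFAULT = {
    "class_mortality": (0.2069, 0.3156, 0.2129, 0.4098),
    "ards_coef": float(np.log(1.456)),
    "coef": {"aps_iii": 0.35, "age": 0.25, "vasopressor": 0.20},
}

#: ventilation duration: 5 d minimum (eligibility) + exponential tail
_VENT_SCALE_DEFAULT = (9.0, 11.0, 10.0, 12.0)

#: daily death hazard (geometric), deaths occur from day 5 onward
_DEATH_HAZARD = 0.15


def _as_ragged_tuple(coefs) -> tuple:
    return tuple(tuple(float(c) for c in row) for row in coefs)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = _N_DEFAULT
    class_shares: tuple = _SHARES_DEFAULT
    class_coefficients: tuple = _COEF_DEFAULT
    residual_sd: float = 2.0
    #: SD of a patient-level random shift around the class curve; gives the
    #: within-phenotype spread of baseline OSI seen in real cohorts
    between_patient_sd: float = 1.0
    grid_hours: tuple = DEFAULT_GRID_HOURS
    continuous_covariates: dict = field(default_factory=lambda: dict(_CONTINUOUS_DEFAULT))
    binary_covariates: dict = field(default_factory=lambda: dict(_BINARY_DEFAULT))
    mediator_model: dict = field(default_factory=lambda: dict(_MEDIATOR_DEFAULT))
    outcome_model: dict = field(default_factory=lambda: dict(_OUTCOME_DEFAULT))
    vent_scale: tuple = _VENT_SCALE_DEFAULT
    vfd_horizon: float = 21.0
    missing_rate: float = 0.0
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return len(self.class_shares)

    def validate(self) -> None:
        shares = np.asarray(self.class_shares, dtype=float)
        if np.any(shares < 0):
            raise ValueError("class_shares: entries must be nonnegative")
        if abs(shares.sum() - 1.0) > 1e-12:
            raise ValueError(f"class_shares: must sum to 1, got {shares.sum()!r}")
        if not self.residual_sd > 0:
            raise ValueError("residual_sd: must be > 0")
        if self.between_patient_sd < 0:
            raise ValueError("between_patient_sd: must be >= 0")
        grid = np.asarray(self.grid_hours, dtype=float)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid_hours: must be strictly increasing")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate: must lie in [0, 1)")
        if len(self.class_coefficients) != self.n_classes:
            raise ValueError("class_coefficients: one coefficient row per class required")
        if self.n_patients < 1:
            raise ValueError("n_patients: must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_coefficients"] = _as_ragged_tuple(self.class_coefficients)
        return d


#: baseline covariates that apply_missingness may blank out (derived columns,
#: identifiers and outcomes are never masked)
MASKABLE_COVARIATES = tuple(_CONTINUOUS_DEFAULT) + tuple(_BINARY_DEFAULT) + ("ethnicity",)

#: the 21 DAG-selected adjustment covariates
DAG_COVARIATES = (
    "age",
    "gender_male",
    "ethnicity",
    "bmi",
    "paco2",
    "hemoglobin",
    "ards",
    "copd",
    "ckd",
    "aki",
    "malignancy",
    "heart_failure",
    "diabetes",
    "peep",
    "plateau_pressure",
    "tidal_volume",
    "osi_baseline",
    "aps_iii",
    "dialysis",
    "nmba",
    "vasopressor",
)


@dataclass
class SyntheticCohort:
    """Generated trajectories + baseline table + ground truth."""

    trajectories: TrajectoryMatrix
    baseline: pd.DataFrame
    true_class: np.ndarray
    config: GeneratorConfig
    map_cmh2o: np.ndarray | None = None
    fio2: np.ndarray | None = None
    spo2: np.ndarray | None = None

    def copy(self) -> "SyntheticCohort":
        return SyntheticCohort(
            self.trajectories.copy(),
            self.baseline.copy(),
            self.true_class.copy(),
            self.config,
            None if self.map_cmh2o is None else self.map_cmh2o.copy(),
            None if self.fio2 is None else self.fio2.copy(),
            None if self.spo2 is None else self.spo2.copy(),
        )

    def write(self, outdir: str | Path) -> None:
        """Write trajectories.csv, baseline.csv and truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        long = self.trajectories.to_long(drop_missing=False)
        for name, arr in (
            ("map_cmh2o", self.map_cmh2o),
            ("fio2_fraction", self.fio2),
            ("spo2_pct", self.spo2),
        ):
            if arr is not None:
                long[name] = arr.ravel()
        # unobserved gridpoints carry no measurements at all
        unobserved = ~self.trajectories.mask.ravel()
        long.loc[unobserved, [c for c in long.columns if c not in ("patient_id", "time_h")]] = (
            np.nan
        )
        long.to_csv(outdir / "trajectories.csv", index=False)
        self.baseline.to_csv(outdir / "baseline.csv", index=False)
        truth = {
            "config": self.config.to_dict(),
            "true_class": [int(c) for c in self.true_class],
        }
        (outdir / "truth.json").write_text(json.dumps(truth, sort_keys=True))


def class_mean_curve(config: GeneratorConfig, k: int) -> np.ndarray:
    """Class-k polynomial mean OSI evaluated on the grid (time in days)."""
    t = np.asarray(config.grid_hours, dtype=float) / 24.0
    coef = np.asarray(config.class_coefficients[k], dtype=float)
    return np.polynomial.polynomial.polyval(t, coef)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _calibrated_bernoulli(rng, target: float, offset: np.ndarray) -> tuple[np.ndarray, float]:
    """Draw Bernoulli(expit(c + offset)) with c chosen so the mean success
    probability equals ``target`` over the given offsets."""

    def gap(c: float) -> float:
        return float(expit(c + offset).mean() - target)

    c = brentq(gap, -20.0, 20.0)
    return (rng.random(len(offset)) < expit(c + offset)).astype(int), float(c)


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate one seeded cohort under the configured study conditions.

    Same config (including seed) twice yields byte-identical cohorts.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, k_classes = config.n_patients, config.n_classes
    grid = np.asarray(config.grid_hours, dtype=float)

    true_class = rng.choice(k_classes, size=n, p=np.asarray(config.class_shares, dtype=float))

    # trajectories: class polynomial mean + iid Gaussian noise, floored at a
    # small positive value (OSI is positive by construction)
    mu = np.stack([class_mean_curve(config, k) for k in range(k_classes)])  # (K, T)
    shift = (
        rng.normal(0.0, config.between_patient_sd, size=(n, 1))
        if config.between_patient_sd > 0
        else np.zeros((n, 1))
    )
    osi = mu[true_class] + shift + rng.normal(0.0, config.residual_sd, size=(n, len(grid)))
    if config.residual_sd > 1e-12 or config.between_patient_sd > 0:
        osi = np.maximum(osi, 0.05)

    # OSI = FiO2 * MAP * 100 / SpO2: decompose into plausible components
    spo2 = np.clip(rng.normal(96.0, 2.0, size=osi.shape), 85.0, 100.0)
    fio2 = np.clip(rng.normal(0.55, 0.12, size=osi.shape), 0.21, 1.0)
    map_cmh2o = osi * spo2 / (100.0 * fio2)

    baseline = pd.DataFrame({"patient_id": np.arange(n)})
    severity = rng.normal(0.0, 1.0, size=n)
    for name, spec in config.continuous_covariates.items():
        means = np.asarray(spec["means"], dtype=float)
        rho = float(spec.get("severity_loading", 0.0))
        noise = rho * severity + np.sqrt(1.0 - rho**2) * rng.normal(0.0, 1.0, size=n)
        baseline[name] = means[true_class] + spec["sd"] * noise
    for name, prev in config.binary_covariates.items():
        p = np.asarray(prev, dtype=float)[true_class]
        baseline[name] = (rng.random(n) < p).astype(int)
    baseline["ethnicity"] = rng.choice(_ETHNICITY_LEVELS, size=n, p=_ETHNICITY_PROBS)
    baseline["osi_baseline"] = osi[:, 0]

    # mediator (ARDS): logistic in class + standardized severity covariates
    med = config.mediator_model
    med_offset = np.zeros(n)
    for name, coef in med["coef"].items():
        med_offset += coef * _standardize(baseline[name].to_numpy(dtype=float))
    prevalence = np.asarray(med["prevalence"], dtype=float)
    ards = np.zeros(n, dtype=int)
    for k in range(k_classes):
        idx = np.flatnonzero(true_class == k)
        if idx.size == 0:
            continue
        # per-class intercept calibrated so E[ARDS | class k] hits target
        sub_rng = np.random.default_rng(rng.integers(2**31))
        ards[idx], _ = _calibrated_bernoulli(sub_rng, prevalence[k], med_offset[idx])
    baseline["ards"] = ards

    # outcome (ICU death): logistic in class intercept (calibrated to the
    # configured class mortality), ARDS, and severity covariates
    out = config.outcome_model
    out_offset = out["ards_coef"] * ards.astype(float)
    for name, coef in out["coef"].items():
        out_offset += coef * _standardize(baseline[name].to_numpy(dtype=float))
    mortality = np.asarray(out["class_mortality"], dtype=float)
    death = np.zeros(n, dtype=int)
    for k in range(k_classes):
        idx = np.flatnonzero(true_class == k)
        if idx.size == 0:
            continue
        sub_rng = np.random.default_rng(rng.integers(2**31))
        death[idx], _ = _calibrated_bernoulli(sub_rng, mortality[k], out_offset[idx])
    baseline["icu_death"] = death

    # ventilation: single spell from admission; >= 5 d by eligibility design
    vent_scale = np.asarray(config.vent_scale, dtype=float)[true_class]
    vent_days = 5.0 + rng.exponential(vent_scale - 5.0)
    vent_days = np.minimum(vent_days, 28.0)

    # death day: geometric daily hazard from day 5 (earlier deaths are
    # excluded by the >= 5 d stay requirement)
    death_day = np.full(n, np.nan)
    geo = rng.geometric(_DEATH_HAZARD, size=n).astype(float)
    death_day[death == 1] = np.minimum(5.0 + geo[death == 1] - 1.0, 30.0)
    # the ventilated spell ends at death for non-survivors
    vent_days = np.where(death == 1, np.minimum(vent_days, death_day), vent_days)

    los = np.where(
        death == 1, death_day, vent_days + rng.exponential(3.0, size=n)
    )
    baseline["vent_start_day"] = 0.0
    baseline["vent_end_day"] = vent_days
    baseline["imv_days"] = vent_days
    baseline["icu_los_days"] = los
    baseline["death_day"] = death_day
    baseline["admission_index"] = 1
    # VFD: days alive and off the ventilator within the horizon
    from osipheno.outcomes import compute_vfd

    horizon = config.vfd_horizon
    baseline["vfd"] = [
        compute_vfd([(0.0, v)], d if np.isfinite(d) else None, horizon)
        for v, d in zip(vent_days, death_day)
    ]

    tm = TrajectoryMatrix(np.arange(n), grid, osi)
    cohort = SyntheticCohort(tm, baseline, true_class, config, map_cmh2o, fio2, spo2)
    if config.missing_rate > 0:
        cohort = apply_missingness(cohort, config.missing_rate, seed=int(rng.integers(2**31)))
    return cohort


def apply_missingness(
    cohort: SyntheticCohort,
    rate: float,
    mechanism: str = "MCAR",
    seed: int = 0,
    targets: tuple = ("trajectories", "baseline"),
) -> SyntheticCohort:
    """Independently blank OSI gridpoints and maskable baseline covariates.

    MCAR only: every cell is removed with probability ``rate`` regardless of
    its value. ``targets`` restricts which tables are affected. Returns a
    new cohort; the input is untouched.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    if mechanism != "MCAR":
        raise ValueError(f"unsupported missingness mechanism: {mechanism!r}")
    out = cohort.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    if "trajectories" in targets:
        drop = rng.random(out.trajectories.osi.shape) < rate
        out.trajectories.osi[drop] = np.nan
        out.trajectories.mask[drop] = False
    if "baseline" not in targets:
        return out
    for col in MASKABLE_COVARIATES:
        if col not in out.baseline.columns:
            continue
        cell_drop = rng.random(len(out.baseline)) < rate
        if out.baseline[col].dtype == object:
            out.baseline.loc[cell_drop, col] = None
        else:
            out.baseline[col] = out.baseline[col].astype(float)
            out.baseline.loc[cell_drop, col] = np.nan
    return out
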