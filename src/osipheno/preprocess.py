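"""Cohort preprocessing: OSI computation, eligibility, imputation.

OSI = FiO2 * mean airway pressure * 100 / SpO2, a noninvasive oxygenation
severity index. Eligibility mirrors the cohort definition: adults, ICU stay
and invasive ventilation of at least five days, a complete day-1..5 OSI
grid, first admission only. Covariates with more than 15% missingness are
dropped; the remainder are imputed by chained equations (linear conditionals
for continuous columns, logistic / multinomial-logistic for binary /
nominal ones) and pooled by Rubin's rules.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LinearRegression, LogisticRegression

from osipheno.containers import TrajectoryMatrix, subset_rows

logger = logging.getLogger(__name__)


def compute_osi(fio2, map_cmh2o, spo2):
    """Oxygen saturation index: FiO2 * MAP * 100 / SpO2.

    FiO2 is canonical as a fraction in (0, 1]; values in (1, 100] are taken
    to be percentages and rescaled with a warning. Accepts scalars or arrays.
    """
    fio2 = np.asarray(fio2, dtype=float)
    map_cmh2o = np.asarray(map_cmh2o, dtype=float)
    spo2 = np.asarray(spo2, dtype=float)
    if np.any(map_cmh2o <= 0):
        raise ValueError("mean airway pressure must be positive")
    if np.any(spo2 <= 0) or np.any(spo2 > 100):
        raise ValueError("SpO2 must lie in (0, 100]")
    pct = fio2 > 1.0
    if np.any(pct):
        if np.any(fio2 > 100):
            raise ValueError("FiO2 must lie in (0, 1] (fraction) or (1, 100] (percent)")
        logger.warning("FiO2 values > 1 interpreted as percentages and divided by 100")
        fio2 = np.where(pct, fio2 / 100.0, fio2)
    if np.any(fio2 <= 0):
        raise ValueError("FiO2 must be positive")
    out = fio2 * map_cmh2o * 100.0 / spo2
    return float(out) if out.ndim == 0 else out


ELIGIBILITY_CRITERIA = ("age", "los", "missing_osi", "imv")


def apply_eligibility(
    trajectories: TrajectoryMatrix,
    baseline: pd.DataFrame,
    min_age: float = 18.0,
    min_los_days: float = 5.0,
    min_imv_days: float = 5.0,
) -> tuple[TrajectoryMatrix, pd.DataFrame, dict]:
    """Apply the cohort exclusion rules in their stated order.

    Retains: first admission per patient with age >= 18, ICU stay >= 5 days,
    invasive ventilation >= 5 days, and a fully observed 5-day OSI grid.
    Returns (trajectories, baseline, tally) where tally counts exclusions per
    criterion in application order (age, los, missing_osi via grid, imv).
    """
    required = {"age", "icu_los_days", "imv_days", "admission_index", "patient_id"}
    missing_cols = required - set(baseline.columns)
    if missing_cols:
        raise KeyError(f"baseline lacks required columns: {sorted(missing_cols)}")
    df = baseline.copy()
    # first recorded admission only (not an exclusion criterion of its own)
    df = df.sort_values(["patient_id", "admission_index"]).drop_duplicates(
        "patient_id", keep="first"
    )
    tally = {c: 0 for c in ELIGIBILITY_CRITERIA}
    keep = pd.Series(True, index=df.index)

    fail_age = keep & (df["age"] < min_age)
    tally["age"] = int(fail_age.sum())
    keep &= ~fail_age

    fail_los = keep & (df["icu_los_days"] < min_los_days)
    tally["los"] = int(fail_los.sum())
    keep &= ~fail_los

    complete = pd.Series(
        trajectories.complete_grid(), index=pd.Index(trajectories.patient_ids)
    ).reindex(df["patient_id"]).fillna(False).to_numpy()
    fail_grid = keep & ~complete
    tally["missing_osi"] = int(fail_grid.sum())
    keep &= ~fail_grid

    fail_imv = keep & (df["imv_days"] < min_imv_days)
    tally["imv"] = int(fail_imv.sum())
    keep &= ~fail_imv

    df = df[keep]
    id_keep = np.isin(trajectories.patient_ids, df["patient_id"].to_numpy())
    return subset_rows(trajectories, id_keep), df.reset_index(drop=True), tally


def drop_high_missingness(
    table: pd.DataFrame, threshold: float = 0.15, protect: tuple = ("patient_id",)
) -> tuple[pd.DataFrame, list]:
    """Remove columns whose missing fraction strictly exceeds ``threshold``."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    frac = table.isna().mean()
    dropped = [c for c in table.columns if c not in protect and frac[c] > threshold]
    out = table.drop(columns=dropped)
    if out.shape[1] == len(protect):
        warnings.warn("all non-protected columns dropped", stacklevel=2)
    return out, dropped


# ---------------------------------------------------------------------------
# chained-equations imputation


def _column_kind(s: pd.Series) -> str:
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
        return "nominal"
    vals = s.dropna().unique()
    if len(vals) <= 2 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
        return "binary"
    return "continuous"


@dataclass
class ImputationResult:
    """m completed datasets plus per-parameter pooled summaries (filled by
    callers that fit a model per dataset and pool with :func:`pool_rubin`)."""

    m: int
    completed: list
    pooled_estimates: dict


class ChainedEquationsImputer:
    """Multiple imputation by chained equations.

    Columns are visited in increasing-missingness order; each incomplete
    column is regressed on all the others (linear conditional for continuous
    columns, logistic for binary, multinomial-logistic for nominal) and its
    missing cells are redrawn from the fitted conditional. The initial fill
    is the column median (mode for binary/nominal). Observed cells are never
    altered.
    """

    def __init__(self, m: int = 10, max_iter: int = 10, seed: int = 0):
        if m < 2:
            raise ValueError("m must be >= 2 for pooling")
        self.m = m
        self.max_iter = max_iter
        self.seed = seed

    def fit_transform(self, table: pd.DataFrame, exclude: tuple = ("patient_id",)) -> ImputationResult:
        work_cols = [c for c in table.columns if c not in exclude]
        sub = table[work_cols]
        all_missing = [c for c in work_cols if sub[c].isna().all()]
        if all_missing:
            raise ValueError(
                f"columns entirely missing: {all_missing}; remove them before imputation"
            )
        completed = [
            self._impute_once(table, work_cols, np.random.default_rng([self.seed, j]))
            for j in range(self.m)
        ]
        return ImputationResult(m=self.m, completed=completed, pooled_estimates={})

    # -- single imputed dataset ------------------------------------------
    def _impute_once(self, table: pd.DataFrame, work_cols: list, rng) -> pd.DataFrame:
        df = table.copy()
        kinds = {c: _column_kind(df[c]) for c in work_cols}
        na_mask = {c: df[c].isna() for c in work_cols}
        incomplete = sorted(
            (c for c in work_cols if na_mask[c].any()), key=lambda c: na_mask[c].mean()
        )
        if not incomplete:
            return df
        # nominal columns are one-hot encoded as predictors
        levels = {
            c: sorted(df[c].dropna().unique()) for c in work_cols if kinds[c] == "nominal"
        }
        for c in work_cols:
            if kinds[c] == "nominal":
                mode = df[c].mode(dropna=True).iloc[0]
                df.loc[na_mask[c], c] = mode
            else:
                fill = df[c].median(skipna=True) if kinds[c] == "continuous" else df[c].mode(dropna=True).iloc[0]
                df.loc[na_mask[c], c] = fill

        def design(exclude_col: str) -> np.ndarray:
            parts = []
            for c in work_cols:
                if c == exclude_col:
                    continue
                if kinds[c] == "nominal":
                    for lev in levels[c][1:]:
                        parts.append((df[c] == lev).to_numpy(dtype=float))
                else:
                    parts.append(df[c].to_numpy(dtype=float))
            return np.column_stack(parts)

        for _ in range(self.max_iter):
            for c in incomplete:
                x = design(c)
                obs = ~na_mask[c]
                mis = na_mask[c].to_numpy()
                if kinds[c] == "continuous":
                    y = df.loc[obs, c].to_numpy(dtype=float)
                    reg = LinearRegression().fit(x[obs.to_numpy()], y)
                    resid_sd = float(np.std(y - reg.predict(x[obs.to_numpy()]), ddof=1))
                    pred = reg.predict(x[mis])
                    df.loc[mis, c] = pred + rng.normal(0.0, resid_sd, size=mis.sum())
                else:
                    y = df.loc[obs, c].to_numpy()
                    if len(np.unique(y)) < 2:
                        continue  # degenerate: keep the mode fill
                    with warnings.catch_warnings():
                        # imputation draws tolerate loose convergence on
                        # collinear dummy predictors
                        warnings.simplefilter("ignore", ConvergenceWarning)
                        clf = LogisticRegression(max_iter=1000).fit(x[obs.to_numpy()], y)
                    proba = clf.predict_proba(x[mis])
                    draws = [
                        clf.classes_[rng.choice(len(clf.classes_), p=p / p.sum())]
                        for p in proba
                    ]
                    df.loc[mis, c] = draws
                if kinds[c] == "binary":
                    df[c] = df[c].astype(float)
        return df


def mice_impute(
    table: pd.DataFrame, m: int = 10, max_iter: int = 10, seed: int = 0, exclude: tuple = ("patient_id",)
) -> ImputationResult:
    """Impute ``table`` with chained equations; see :class:`ChainedEquationsImputer`."""
    return ChainedEquationsImputer(m=m, max_iter=max_iter, seed=seed).fit_transform(
        table, exclude=exclude
    )


def pool_rubin(estimates, variances, complete_df: float = np.inf) -> dict:
    """Pool per-imputation estimates by Rubin's rules.

    Returns estimate (mean), within-variance W, between-variance B, total
    variance T = W + (1 + 1/m) B, SE, and degrees of freedom
    (m - 1)(1 + W / ((1 + 1/m) B))^2, capped at ``complete_df`` when B = 0.
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.shape != var.shape:
        raise ValueError("estimates and variances must have equal length")
    m = len(est)
    if m < 2:
        raise ValueError("need m >= 2 imputations to pool")
    qbar = est.mean()
    w = var.mean()
    b = est.var(ddof=1)
    t = w + (1.0 + 1.0 / m) * b
    if b > 0:
        df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
        df = min(df, complete_df) if np.isfinite(complete_df) else df
    else:
        df = complete_df
    return {
        "estimate": float(qbar),
        "within": float(w),
        "between": float(b),
        "total_variance": float(t),
        "se": float(np.sqrt(t)),
        "df": float(df),
    }
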