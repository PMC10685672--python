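"""Doubly robust estimation of phenotype -> ICU-mortality effects.

The exposure is the (multi-category) trajectory phenotype. Generalized
propensity scores come from multinomial logistic regression or
gradient-boosted trees; inverse-probability-of-treatment weights reweight
the phenotypes toward covariate balance (diagnosed with standardized mean
differences); the doubly robust step is a weighted logistic outcome
regression whose variance treats the weights as fixed (sandwich form).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression

PROPENSITY_CLIP = 1e-3


def _encode_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric design: object/categorical columns one-hot (drop-first)."""
    cat = [c for c in covariates.columns if covariates[c].dtype == object
           or isinstance(covariates[c].dtype, pd.CategoricalDtype)]
    out = pd.get_dummies(covariates, columns=cat, drop_first=True, dtype=float)
    return out.astype(float)


def fit_propensity(
    covariates: pd.DataFrame, phenotype, method: str = "multinomial_logistic", seed: int = 0
) -> np.ndarray:
    """Generalized propensity scores e_ik = P(phenotype k | covariates).

    ``method`` is "multinomial_logistic" (maximum likelihood) or
    "gradient_boosting" (multiclass trees, softmax output). Probabilities
    are clipped to [1e-3, 1 - 1e-3] and row-renormalized.
    """
    x = _encode_covariates(covariates).to_numpy()
    z = np.asarray(phenotype)
    if np.isnan(x).any():
        raise ValueError("covariates must be complete (impute first)")
    classes = np.unique(z)
    if len(classes) < 2:
        raise ValueError("need at least two phenotype classes present")
    if method == "multinomial_logistic":
        # lightly penalized for stability under (near-)separation
        clf = LogisticRegression(C=1e6, max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(x, z)
        proba = clf.predict_proba(x)
    elif method == "gradient_boosting":
        from xgboost import XGBClassifier

        clf = XGBClassifier(
            n_estimators=100,
            max_depth=3,
            learning_rate=0.1,
            objective="multi:softprob" if len(classes) > 2 else "binary:logistic",
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
        z_idx = np.searchsorted(classes, z)
        clf.fit(x, z_idx)
        proba = clf.predict_proba(x)
    else:
        raise ValueError(f"unknown propensity method: {method!r}")
    proba = np.clip(proba, PROPENSITY_CLIP, 1.0 - PROPENSITY_CLIP)
    return proba / proba.sum(axis=1, keepdims=True)


def compute_iptw(
    propensity: np.ndarray, assigned, stabilized: bool = False, truncate_pct: float | None = None
) -> np.ndarray:
    """IPTW weights w_i = 1 / e_{i, Z_i} (optionally stabilized by the
    marginal class share, optionally symmetrically percentile-truncated)."""
    propensity = np.asarray(propensity, dtype=float)
    z = np.asarray(assigned)
    classes, z_idx = np.unique(z, return_inverse=True)
    if propensity.shape[1] != len(classes):
        raise ValueError("propensity columns must match the number of classes present")
    e_assigned = propensity[np.arange(len(z)), z_idx]
    w = 1.0 / e_assigned
    if stabilized:
        shares = np.bincount(z_idx) / len(z)
        w = shares[z_idx] * w
    if truncate_pct is not None:
        lo, hi = np.percentile(w, [truncate_pct, 100.0 - truncate_pct])
        w = np.clip(w, lo, hi)
    return w


def _weighted_mean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    m = float(np.average(x, weights=w))
    v = float(np.average((x - m) ** 2, weights=w))
    # unbiased-style correction for weighted data
    denom = 1.0 - (w**2).sum() / w.sum() ** 2
    return m, (v / denom if denom > 0 else v)


def compute_smd(covariate, groups, weights=None, binary: bool | None = None) -> float:
    """Maximum pairwise standardized mean difference across groups.

    Continuous: |mean_a - mean_b| / pooled SD (average of group variances).
    Binary (0/1): |p_a - p_b| / sqrt((p_a(1-p_a) + p_b(1-p_b)) / 2).
    Returns +inf when the pooled variance is 0 but means differ.
    """
    x = np.asarray(covariate, dtype=float)
    g = np.asarray(groups)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    labels = np.unique(g)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if binary is None:
        binary = set(np.unique(x)) <= {0.0, 1.0}
    worst = 0.0
    for a, b in combinations(labels, 2):
        ia, ib = g == a, g == b
        if binary:
            pa = float(np.average(x[ia], weights=w[ia]))
            pb = float(np.average(x[ib], weights=w[ib]))
            denom2 = (pa * (1 - pa) + pb * (1 - pb)) / 2.0
            diff = abs(pa - pb)
        else:
            ma, va = _weighted_mean_var(x[ia], w[ia])
            mb, vb = _weighted_mean_var(x[ib], w[ib])
            denom2 = (va + vb) / 2.0
            diff = abs(ma - mb)
        if denom2 <= 0:
            smd = 0.0 if diff == 0 else np.inf
        else:
            smd = diff / np.sqrt(denom2)
        worst = max(worst, smd)
    return float(worst)


def smd_table(
    covariates: pd.DataFrame, groups, weights=None
) -> pd.DataFrame:
    """Per-covariate max pairwise SMD with an imbalance flag at > 0.1."""
    enc = _encode_covariates(covariates)
    rows = []
    for col in enc.columns:
        smd = compute_smd(enc[col].to_numpy(), groups, weights)
        rows.append({"covariate": col, "smd": smd, "imbalanced": smd > 0.1})
    return pd.DataFrame(rows).set_index("covariate")


@dataclass
class WeightedCohort:
    """Propensities, IPTW weights and balance diagnostics for one method."""

    propensity: np.ndarray
    weights: np.ndarray
    assigned: np.ndarray
    method: str
    stabilized: bool
    smd_before: pd.DataFrame
    smd_after: pd.DataFrame

    @property
    def unbalanced_covariates(self) -> list:
        """Covariates still imbalanced (SMD > 0.1) after weighting."""
        return list(self.smd_after.index[self.smd_after["imbalanced"]])


def weight_cohort(
    covariates: pd.DataFrame,
    phenotype,
    method: str = "multinomial_logistic",
    stabilized: bool = False,
    truncate_pct: float | None = None,
    seed: int = 0,
) -> WeightedCohort:
    """Fit propensities, derive IPTW weights, and diagnose balance."""
    prop = fit_propensity(covariates, phenotype, method=method, seed=seed)
    w = compute_iptw(prop, phenotype, stabilized=stabilized, truncate_pct=truncate_pct)
    return WeightedCohort(
        propensity=prop,
        weights=w,
        assigned=np.asarray(phenotype),
        method=method,
        stabilized=stabilized,
        smd_before=smd_table(covariates, phenotype),
        smd_after=smd_table(covariates, phenotype, weights=w),
    )


# ---------------------------------------------------------------------------
# weighted outcome regression (the doubly robust step)


@dataclass
class DREstimate:
    """Weighted-logistic effect estimates for each non-reference phenotype."""

    reference: int
    table: pd.DataFrame  # index contrast; columns or, ci_low, ci_high, p, log_or, se
    adjustment: str
    method: str
    vif: pd.DataFrame | None = None
    params: np.ndarray | None = None
    param_names: list = field(default_factory=list)
    cov: np.ndarray | None = None


def _weighted_logistic(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted logistic fit with the weights-fixed sandwich covariance."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, x, family=sm.families.Binomial(), var_weights=w)
        try:
            res = model.fit(cov_type="HC0")
        except Exception:
            # separation / non-convergence: small ridge via regularized fit
            warnings.warn("weighted logistic did not converge; penalized refit", stacklevel=2)
            res = model.fit_regularized(alpha=1e-4, L1_wt=0.0)
            return np.asarray(res.params), None
    return np.asarray(res.params), np.asarray(res.cov_params())


def dr_estimate(
    outcome,
    phenotype,
    weights=None,
    adjustment: pd.DataFrame | None = None,
    reference: int | None = None,
    adjustment_label: str = "none",
    method: str = "multinomial_logistic",
) -> DREstimate:
    """Weighted logistic regression of death on phenotype (+ covariates).

    Odds ratios are relative to the reference class (lowest label by
    default, i.e. the low-OSI phenotype); confidence intervals and p-values
    use a robust sandwich variance with the weights treated as fixed.
    """
    y = np.asarray(outcome, dtype=float)
    z = np.asarray(phenotype)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    classes = list(np.unique(z))
    reference = classes[0] if reference is None else reference
    if reference not in classes:
        raise ValueError("reference class not present")
    contrasts = [c for c in classes if c != reference]
    cols = [np.ones_like(y)]
    names = ["intercept"]
    for c in contrasts:
        cols.append((z == c).astype(float))
        names.append(f"phenotype_{c}")
    if adjustment is not None and adjustment.shape[1] > 0:
        enc = _encode_covariates(adjustment)
        for col in enc.columns:
            v = enc[col].to_numpy()
            sd = v.std()
            cols.append((v - v.mean()) / sd if sd > 0 else v - v.mean())
            names.append(col)
    x = np.column_stack(cols)

    for c in contrasts:
        if y[(z == c)].sum() == 0 or y[(z == reference)].sum() == 0:
            warnings.warn(f"zero events in a phenotype class (contrast {c})", stacklevel=2)
    params, cov = _weighted_logistic(x, y, w)
    if cov is None:
        cov = np.full((len(params), len(params)), np.nan)
    rows = []
    for i, c in enumerate(contrasts, start=1):
        b, se = params[i], np.sqrt(cov[i, i])
        zstat = b / se if se > 0 else np.nan
        rows.append(
            {
                "contrast": f"{c}_vs_{reference}",
                "log_or": b,
                "se": se,
                "or": float(np.exp(b)),
                "ci_low": float(np.exp(b - 1.959964 * se)),
                "ci_high": float(np.exp(b + 1.959964 * se)),
                "p": float(2.0 * stats.norm.sf(abs(zstat))) if np.isfinite(zstat) else np.nan,
            }
        )
    table = pd.DataFrame(rows).set_index("contrast")
    vif = None
    if adjustment is not None and adjustment.shape[1] >= 2:
        vif = vif_check(adjustment)
    return DREstimate(
        reference=reference,
        table=table,
        adjustment=adjustment_label,
        method=method,
        vif=vif,
        params=params,
        param_names=names,
        cov=cov,
    )


def dr_table(
    outcome,
    phenotype,
    covariates: pd.DataFrame,
    wc: WeightedCohort,
    reference: int | None = None,
) -> dict:
    """The three adjustment variants for one weighting method: IPTW only,
    doubly robust with the still-unbalanced covariates, and with all."""
    unbalanced = [c for c in wc.unbalanced_covariates if c in covariates.columns]
    # one-hot SMD rows map back to their source column
    for row in wc.unbalanced_covariates:
        for col in covariates.columns:
            if row.startswith(col + "_") and col not in unbalanced:
                unbalanced.append(col)
    out = {}
    out["iptw"] = dr_estimate(
        outcome, phenotype, wc.weights, None, reference, "none", wc.method
    )
    out["dr_unbalanced"] = dr_estimate(
        outcome,
        phenotype,
        wc.weights,
        covariates[unbalanced] if unbalanced else None,
        reference,
        "unbalanced",
        wc.method,
    )
    out["dr_all"] = dr_estimate(
        outcome, phenotype, wc.weights, covariates, reference, "all", wc.method
    )
    return out


def vif_check(covariates: pd.DataFrame, flag_at: float = 5.0) -> pd.DataFrame:
    """Variance inflation factors VIF_j = 1 / (1 - R^2_j); flags > 5.

    Exactly collinear columns report +inf.
    """
    enc = _encode_covariates(covariates)
    x = enc.to_numpy()
    n, p = x.shape
    if p < 2:
        raise ValueError("need at least two covariates")
    if n <= p:
        raise ValueError("need more observations than covariates")
    rows = []
    for j, col in enumerate(enc.columns):
        others = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        yj = x[:, j]
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        tss = ((yj - yj.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / tss if tss > 0 else 0.0
        vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"covariate": col, "vif": float(vif), "flagged": bool(vif > flag_at)})
    return pd.DataFrame(rows).set_index("covariate")


def subgroup_analysis(
    outcome, phenotype, stratifier, weights=None, reference: int | None = None
) -> dict:
    """Per-stratum weighted ORs plus an interaction likelihood-ratio test.

    The interaction p-value compares pooled weighted logistic models with
    and without phenotype x stratifier terms (pseudo-likelihood under the
    weights, the conventional approximation).
    """
    y = np.asarray(outcome, dtype=float)
    z = np.asarray(phenotype)
    s = np.asarray(stratifier)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    strata = [lev for lev in np.unique(s)]
    if len(strata) < 2:
        raise ValueError("stratifier needs at least two non-empty levels")
    per_stratum = {}
    for lev in strata:
        m = s == lev
        if y[m].sum() == 0 or len(np.unique(z[m])) < 2:
            warnings.warn(f"stratum {lev!r} skipped (no events or single class)", stacklevel=2)
            continue
        per_stratum[lev] = dr_estimate(y[m], z[m], w[m], reference=reference).table

    classes = list(np.unique(z))
    ref = classes[0] if reference is None else reference
    base_cols = [np.ones_like(y)]
    for c in classes:
        if c != ref:
            base_cols.append((z == c).astype(float))
    s_levels = strata[1:]
    for lev in s_levels:
        base_cols.append((s == lev).astype(float))
    x0 = np.column_stack(base_cols)
    inter_cols = [
        (z == c).astype(float) * (s == lev).astype(float)
        for c in classes
        if c != ref
        for lev in s_levels
    ]
    x1 = np.column_stack([x0] + inter_cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ll0 = sm.GLM(y, x0, family=sm.families.Binomial(), var_weights=w).fit().llf
        ll1 = sm.GLM(y, x1, family=sm.families.Binomial(), var_weights=w).fit().llf
    lr = max(2.0 * (ll1 - ll0), 0.0)
    df = len(inter_cols)
    return {
        "per_stratum": per_stratum,
        "interaction_lr": float(lr),
        "interaction_df": df,
        "interaction_p": float(stats.chi2.sf(lr, df)),
    }
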