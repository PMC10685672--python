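"""Early identification of poor-prognosis trajectory phenotypes.

The target is the binary "poor prognosis" grouping (ascending or
high-level-stable phenotype) versus the rest, predicted from baseline
covariates. The training set is class-balanced with SMOTE, features are
screened with L1-penalized (LASSO) logistic regression at the
cross-validated penalty, the final logistic model is rendered as a
nomogram, and discrimination / calibration / clinical utility are
evaluated with ROC-AUC (DeLong CI), calibration deciles with the
Hosmer-Lemeshow test, and decision-curve net benefit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.metrics import log_loss


# ---------------------------------------------------------------------------
# SMOTE


class SMOTESampler(BaseEstimator):
    """Synthetic minority oversampling by nearest-neighbor interpolation.

    New minority points are x + u (x_nn - x) with u ~ Uniform(0, 1), where
    x_nn is one of the k nearest minority neighbors of the seed x under
    Euclidean distance on standardized features. Categorical attributes are
    not interpolated; callers pass numeric features and carry categorical
    values over from the seed record.
    """

    def __init__(self, k: int = 5, seed: int = 0):
        self.k = k
        self.seed = seed

    def fit_resample(self, features, labels):
        x = np.asarray(features, dtype=float)
        y = np.asarray(labels)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("SMOTE here supports binary labels")
        minority = classes[np.argmin(counts)]
        n_needed = int(counts.max() - counts.min())
        if n_needed == 0:
            return x.copy(), y.copy()
        x_min = x[y == minority]
        if len(x_min) < 2:
            raise ValueError("minority class needs at least two members")
        k = self.k
        if len(x_min) <= k:
            k = len(x_min) - 1
            warnings.warn(f"minority class small; k reduced to {k}", stacklevel=2)
        mu, sd = x_min.mean(axis=0), x_min.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        z_min = (x_min - mu) / sd
        nn = NearestNeighbors(n_neighbors=k + 1).fit(z_min)
        _, idx = nn.kneighbors(z_min)  # column 0 is the point itself
        rng = np.random.default_rng(self.seed)
        seeds = rng.integers(0, len(x_min), size=n_needed)
        picks = idx[seeds, rng.integers(1, k + 1, size=n_needed)]
        u = rng.random(n_needed)[:, None]
        synth = x_min[seeds] + u * (x_min[picks] - x_min[seeds])
        x_out = np.vstack([x, synth])
        y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
        return x_out, y_out


def smote(features, labels, k: int = 5, seed: int = 0):
    """Balance a binary training set; see :class:`SMOTESampler`."""
    return SMOTESampler(k=k, seed=seed).fit_resample(features, labels)


# ---------------------------------------------------------------------------
# LASSO screening


def lasso_select(
    features,
    labels,
    lambda_grid=None,
    folds: int = 10,
    seed: int = 0,
    one_se: bool = False,
) -> dict:
    """L1-penalized logistic screening at the cross-validated penalty.

    Features are standardized internally. Returns the selected (nonzero)
    feature indices/names, the chosen lambda, and the coefficient path over
    the log-spaced grid with per-lambda CV deviance.
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        names = [f"x{j}" for j in range(x.shape[1])]
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if n < 2 * folds:
        raise ValueError("need at least 2 observations per CV fold")
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (x - mu) / sd
    if lambda_grid is None:
        lam_max = np.abs(z.T @ (y - y.mean())).max() / n
        lambda_grid = np.geomspace(lam_max, lam_max * 1e-4, 40)
    lambda_grid = np.asarray(sorted(lambda_grid, reverse=True), dtype=float)

    def fit_at(zx, yy, lam):
        # sklearn's C is the inverse of (n * lambda) for mean log-loss;
        # lambda = 0 degenerates to the unpenalized fit
        c = 1.0 / (len(yy) * lam) if lam > 0 else 1e12
        clf = LogisticRegression(
            penalty="l1", C=c, solver="saga", max_iter=5000, tol=1e-6
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(zx, yy)
        return clf

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(z, y))
    cv_dev = np.zeros(len(lambda_grid))
    for tr, te in splits:
        for i, lam in enumerate(lambda_grid):
            clf = fit_at(z[tr], y[tr], lam)
            p = clf.predict_proba(z[te])[:, 1]
            cv_dev[i] += 2.0 * log_loss(y[te], p, labels=[0, 1], normalize=False)
    cv_dev /= n
    cv_se = np.zeros(len(lambda_grid))  # spread of per-fold deviance
    best_i = int(np.argmin(cv_dev))
    if one_se:
        per_fold = np.zeros((folds, len(lambda_grid)))
        for f, (tr, te) in enumerate(splits):
            for i, lam in enumerate(lambda_grid):
                clf = fit_at(z[tr], y[tr], lam)
                p = clf.predict_proba(z[te])[:, 1]
                per_fold[f, i] = 2.0 * log_loss(y[te], p, labels=[0, 1], normalize=False) / len(te)
        cv_se = per_fold.std(axis=0, ddof=1) / np.sqrt(folds)
        threshold = cv_dev[best_i] + cv_se[best_i]
        candidates = np.flatnonzero(cv_dev <= threshold)
        best_i = int(candidates[0])  # largest penalty within one SE
    lam = float(lambda_grid[best_i])
    path = np.stack([fit_at(z, y, l).coef_.ravel() for l in lambda_grid])
    final = fit_at(z, y, lam)
    coefs = final.coef_.ravel()
    selected = [names[j] for j in np.flatnonzero(np.abs(coefs) > 1e-10)]
    return {
        "selected": selected,
        "lambda": lam,
        "lambda_grid": lambda_grid,
        "cv_deviance": cv_dev,
        "cv_se": cv_se,
        "coef_path": path,
        "coef": coefs,
        "intercept": float(final.intercept_[0]),
        "feature_names": names,
        "standardize_mean": mu,
        "standardize_sd": sd,
    }


# ---------------------------------------------------------------------------
# nomogram


@dataclass
class NomogramModel:
    """Point-score rendering of a fitted logistic model.

    Per-feature points are affine: points_j(x) = 100 |beta_j| (x_j - ref_j)
    / max_range, where ref_j is the feature value at which the class puts 0
    points (the end of the range that lowers risk) and max_range is the
    largest |beta_j| * range_j across features. Total points map back
    through the linear predictor to predicted risk.
    """

    feature_names: list
    coef: np.ndarray
    intercept: float
    ref: np.ndarray
    scale: float  # linear-predictor units per point
    ranges: np.ndarray
    risk_curve: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def points(self, x) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return np.abs(self.coef) * (x - self.ref) * np.sign(self.coef) / self.scale

    def total_points(self, x) -> np.ndarray:
        return self.points(x).sum(axis=1)

    def predict_risk(self, x) -> np.ndarray:
        base = self.intercept + self.ref @ self.coef
        return expit(base + self.total_points(x) * self.scale)


def build_nomogram(coef, intercept: float, features: pd.DataFrame) -> NomogramModel:
    """Render a fitted logistic model as a 0-100 point nomogram.

    ``features`` supplies the empirical ranges; zero-range features are
    excluded with a warning.
    """
    coef = np.asarray(coef, dtype=float)
    if not np.all(np.isfinite(coef)) or not np.isfinite(intercept):
        raise ValueError("coefficients must be finite")
    names = list(features.columns)
    x = features.to_numpy(dtype=float)
    lo, hi = x.min(axis=0), x.max(axis=0)
    keep = hi > lo
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"zero-range features excluded from nomogram: {dropped}", stacklevel=2)
    names = [n for n, k in zip(names, keep) if k]
    coef_k, lo, hi = coef[keep], lo[keep], hi[keep]
    ranges = hi - lo
    # reference = the end of each feature's range contributing least risk
    ref = np.where(coef_k >= 0, lo, hi)
    max_contrib = np.abs(coef_k * ranges).max()
    scale = max_contrib / 100.0  # lp units per point; largest feature spans 100
    model = NomogramModel(
        feature_names=names,
        coef=coef_k,
        intercept=float(intercept),
        ref=ref,
        scale=float(scale),
        ranges=ranges,
    )
    total_max = float(np.sum(np.abs(coef_k * ranges)) / scale)
    tp = np.linspace(0.0, total_max, 101)
    base = float(intercept + ref @ coef_k)
    model.risk_curve = pd.DataFrame(
        {"total_points": tp, "risk": expit(base + tp * scale)}
    )
    return model


# ---------------------------------------------------------------------------
# evaluation: AUC/DeLong, calibration + Hosmer-Lemeshow, decision curve


def auc_rank(scores, labels) -> float:
    """AUC by the rank (Mann-Whitney) formula; ties count one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return float((ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0) / (len(pos) * len(neg)))


def delong_ci(scores, labels, alpha: float = 0.05) -> tuple:
    """DeLong variance-based confidence interval for the AUC."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    auc = auc_rank(s, y)
    # placement values
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    se = float(np.sqrt(max(var, 0.0)))
    zq = stats.norm.ppf(1 - alpha / 2)
    return auc, max(auc - zq * se, 0.0), min(auc + zq * se, 1.0), se


def hosmer_lemeshow(probs, labels, g: int = 10) -> dict:
    """Hosmer-Lemeshow goodness-of-fit on g risk-decile bins, df = g - 2.

    Empty bins (tied predictions) are merged with their neighbor.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    edges = np.quantile(p, np.linspace(0, 1, g + 1))
    edges = np.unique(edges)
    bins = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    chi2 = 0.0
    used = 0
    table = []
    for b in np.unique(bins):
        m = bins == b
        n_g = int(m.sum())
        o_g = float(y[m].sum())
        e_g = float(p[m].sum())
        denom = e_g * (1.0 - e_g / n_g)
        if denom <= 0:
            continue
        chi2 += (o_g - e_g) ** 2 / denom
        used += 1
        table.append({"bin": int(b), "n": n_g, "observed": o_g, "expected": e_g})
    df = max(used - 2, 1)
    return {
        "statistic": float(chi2),
        "df": df,
        "p_value": float(stats.chi2.sf(chi2, df)),
        "bins": pd.DataFrame(table),
    }


def decision_curve(probs, labels, thresholds=None) -> pd.DataFrame:
    """Net benefit NB(p_t) = TP/N - FP/N * p_t/(1-p_t) for the model vs the
    treat-all and treat-none policies on a threshold grid."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    prev = y.mean()
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    rows = []
    for pt in thresholds:
        treat = p >= pt
        tp = float((treat & (y == 1)).sum())
        fp = float((treat & (y == 0)).sum())
        odds = pt / (1.0 - pt)
        rows.append(
            {
                "threshold": pt,
                "net_benefit_model": tp / n - fp / n * odds,
                "net_benefit_all": prev - (1.0 - prev) * odds,
                "net_benefit_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


def evaluate(probs, labels, g: int = 10) -> dict:
    """Discrimination, calibration and clinical-utility report."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    auc, lo, hi, se = delong_ci(probs, y)
    p = np.asarray(probs, dtype=float)
    order = np.argsort(p, kind="stable")
    bins = np.array_split(order, g)
    calib = pd.DataFrame(
        {
            "mean_predicted": [p[b].mean() for b in bins if len(b)],
            "observed_rate": [y[b].mean() for b in bins if len(b)],
            "n": [len(b) for b in bins if len(b)],
        }
    )
    return {
        "auc": auc,
        "auc_ci": (lo, hi),
        "auc_se": se,
        "calibration": calib,
        "hosmer_lemeshow": hosmer_lemeshow(p, y, g=g),
        "decision_curve": decision_curve(p, y),
    }


# ---------------------------------------------------------------------------
# end-to-end prediction stack


def train_poor_prognosis_model(
    train_features: pd.DataFrame,
    train_labels,
    valid_features: pd.DataFrame | None = None,
    valid_labels=None,
    k_smote: int = 5,
    folds: int = 10,
    seed: int = 0,
) -> dict:
    """SMOTE-balance the training set, LASSO-screen, fit the final logistic
    model on the selected features, build the nomogram, evaluate.

    SMOTE touches only the training data; validation metrics are computed on
    the untouched validation set.
    """
    enc = _numeric(train_features)
    y_tr = np.asarray(train_labels, dtype=int)
    x_bal, y_bal = smote(enc.to_numpy(), y_tr, k=k_smote, seed=seed)
    bal_df = pd.DataFrame(x_bal, columns=enc.columns)
    sel = lasso_select(bal_df, y_bal, folds=folds, seed=seed)
    chosen = sel["selected"] or list(enc.columns)
    final = LogisticRegression(C=1e6, max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(bal_df[chosen].to_numpy(), y_bal)
    coef, intercept = final.coef_.ravel(), float(final.intercept_[0])
    nomogram = build_nomogram(coef, intercept, bal_df[chosen])
    p_tr = final.predict_proba(enc[chosen].to_numpy())[:, 1]
    report = {
        "selected": chosen,
        "lambda": sel["lambda"],
        "coef": dict(zip(chosen, coef)),
        "intercept": intercept,
        "nomogram": nomogram,
        "lasso": sel,
        "train_eval": evaluate(p_tr, y_tr),
    }
    if valid_features is not None:
        enc_v = _numeric(valid_features)[chosen]
        p_v = final.predict_proba(enc_v.to_numpy())[:, 1]
        report["valid_eval"] = evaluate(p_v, np.asarray(valid_labels, dtype=int))
    return report


def _numeric(features: pd.DataFrame) -> pd.DataFrame:
    from osipheno.causal import _encode_covariates

    return _encode_covariates(features)
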