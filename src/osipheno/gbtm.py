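"""Group-based trajectory modelling of OSI series.

The model is a finite mixture over latent classes k = 1..K:

    y_it | class k  ~  Normal( sum_j beta_kj * t^j ,  sigma^2 ),

with mixture weights pi_k, a per-class polynomial mean in time (days) and a
Gaussian residual whose variance is shared across classes by default.
Fitting is by EM from multiple random starts; patients with partially
missing grids contribute likelihood over their observed points only.

Classes are stored in canonical order of increasing mean fitted OSI over
the grid, so "phenotype 1 = lowest trajectory" is stable across runs and
label permutations.

Model selection follows a two-stage protocol: candidate class counts are
compared with all-quadratic shapes on BIC among admissible candidates
(every average posterior probability >= 0.7 and every class share >= 5%),
then for the chosen K the polynomial shapes are refined downward from cubic
by Wald tests on each class's highest-order term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from osipheno.containers import TrajectoryMatrix

_LOG2PI = float(np.log(2.0 * np.pi))


def _as_matrix(series) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accept a TrajectoryMatrix or an (n, T) array (NaN = missing)."""
    if isinstance(series, TrajectoryMatrix):
        return series.osi, series.mask, series.grid_days
    y = np.asarray(series, dtype=float)
    if y.ndim != 2:
        raise ValueError("expected an (n_patients, n_timepoints) array")
    mask = np.isfinite(y)
    grid_days = np.arange(y.shape[1], dtype=float) * 0.25
    return y, mask, grid_days


def _design(t_centered: np.ndarray, order: int) -> np.ndarray:
    return np.vander(t_centered, order + 1, increasing=True)


def _uncenter(beta_centered: np.ndarray, t0: float) -> np.ndarray:
    """Rewrite a polynomial in (t - t0) as a polynomial in t."""
    p = np.polynomial.polynomial.Polynomial(beta_centered)
    shifted = p(np.polynomial.polynomial.Polynomial([-t0, 1.0]))
    out = np.zeros_like(beta_centered)
    out[: len(shifted.coef)] = shifted.coef
    return out


class TrajectoryGBTM(BaseEstimator):
    """Finite mixture of polynomial trajectories fitted by EM.

    Parameters
    ----------
    n_classes : number of latent classes K
    orders : int or per-class sequence of polynomial orders (0-3)
    n_starts : random initializations; the best log-likelihood wins
    seed : seeds all starts
    tol : relative log-likelihood change declaring convergence
    max_iter : EM iteration cap per start
    shared_sigma : one residual SD across classes (default) or per class

    Fitted attributes (canonical class order = increasing mean fitted OSI):
    ``beta_`` list of per-class coefficient vectors on the day scale,
    ``pi_`` class shares, ``sigma_`` residual SD (scalar or per-class),
    ``posterior_`` (n, K) membership probabilities, ``loglik_``,
    ``n_params_``, ``converged_``, ``n_iter_``, ``orders_``,
    ``beta_se_`` approximate per-coefficient standard errors.
    """

    def __init__(
        self,
        n_classes: int = 4,
        orders=2,
        n_starts: int = 20,
        seed: int = 0,
        tol: float = 1e-7,
        max_iter: int = 500,
        shared_sigma: bool = True,
    ):
        self.n_classes = n_classes
        self.orders = orders
        self.n_starts = n_starts
        self.seed = seed
        self.tol = tol
        self.max_iter = max_iter
        self.shared_sigma = shared_sigma

    # ------------------------------------------------------------------
    def _orders_list(self) -> list[int]:
        if np.isscalar(self.orders):
            return [int(self.orders)] * self.n_classes
        if len(self.orders) != self.n_classes:
            raise ValueError("orders must be scalar or one per class")
        return [int(o) for o in self.orders]

    def fit(self, X, y=None):
        ymat, mask, grid_days = _as_matrix(X)
        k = self.n_classes
        if k < 1:
            raise ValueError("n_classes must be >= 1")
        n, t_len = ymat.shape
        if n == 0:
            raise ValueError("empty trajectory collection")
        orders = self._orders_list()
        if any(o < 0 or o > 3 for o in orders):
            raise ValueError("polynomial orders must lie in 0..3")
        nobs = mask.sum(axis=1)
        if np.any(nobs < max(orders) + 1):
            raise ValueError("every series needs at least order+1 observed points")

        t0 = float(grid_days.mean())
        tc = grid_days - t0
        self._tc_ = tc
        designs = [_design(tc, o) for o in orders]
        y0 = np.where(mask, ymat, 0.0)
        rng = np.random.default_rng(self.seed)

        best = None
        any_converged = False
        for _ in range(max(1, self.n_starts)):
            res = self._em_once(y0, mask, nobs, designs, rng)
            if res is None:
                continue
            any_converged = any_converged or res["converged"]
            if best is None or res["loglik"] > best["loglik"]:
                best = res
        if best is None or not np.isfinite(best["loglik"]):
            raise RuntimeError("no EM start produced a finite log-likelihood")
        if not any_converged:
            raise RuntimeError(
                f"no EM start converged within {self.max_iter} iterations "
                f"(best log-likelihood {best['loglik']:.4f})"
            )

        # canonical class order: increasing mean fitted OSI over the grid
        mu = np.stack([d @ b for d, b in zip(designs, best["beta"])])
        order_idx = np.argsort(mu.mean(axis=1), kind="stable")
        self.orders_ = [orders[j] for j in order_idx]
        self.beta_centered_ = [best["beta"][j] for j in order_idx]
        self.beta_ = [_uncenter(b, t0) for b in self.beta_centered_]
        self.beta_se_ = [best["beta_se"][j] for j in order_idx]
        self.pi_ = best["pi"][order_idx]
        self.posterior_ = best["posterior"][:, order_idx]
        sig = best["sigma"]
        self.sigma_ = float(sig) if self.shared_sigma else np.asarray(sig)[order_idx]
        self.loglik_ = float(best["loglik"])
        self.loglik_path_ = best["path"]
        self.converged_ = bool(best["converged"])
        self.n_iter_ = int(best["n_iter"])
        self.n_params_ = (
            sum(o + 1 for o in self.orders_) + (k - 1) + (1 if self.shared_sigma else k)
        )
        self.t_center_ = t0
        self.grid_days_ = grid_days
        self.n_patients_ = n
        return self

    # ------------------------------------------------------------------
    def _loglik_matrix(self, y0, mask, nobs, designs, beta, sigma):
        """(n, K) per-class Gaussian log-likelihood over observed points."""
        k = len(designs)
        sig = np.full(k, sigma) if np.isscalar(sigma) else np.asarray(sigma)
        ll = np.empty((y0.shape[0], k))
        for j in range(k):
            mu = designs[j] @ beta[j]
            resid2 = ((y0 - mu) ** 2 * mask).sum(axis=1)
            ll[:, j] = -0.5 * nobs * (_LOG2PI + 2.0 * np.log(sig[j])) - resid2 / (
                2.0 * sig[j] ** 2
            )
        return ll

    def _em_once(self, y0, mask, nobs, designs, rng):
        n, t_len = y0.shape
        k = self.n_classes
        beta, sigma = self._initial_params(y0, mask, designs, rng)
        pi = np.full(k, 1.0 / k)
        prev_ll = -np.inf
        path = []
        converged = False
        it = 0
        post = np.full((n, k), 1.0 / k)
        for it in range(1, self.max_iter + 1):
            # E-step
            logjoint = np.log(np.maximum(pi, 1e-300)) + self._loglik_matrix(
                y0, mask, nobs, designs, beta, sigma
            )
            norm = logsumexp(logjoint, axis=1)
            loglik = float(norm.sum())
            post = np.exp(logjoint - norm[:, None])
            path.append(loglik)
            if np.isfinite(prev_ll) and abs(loglik - prev_ll) <= self.tol * (
                abs(prev_ll) + 1.0
            ):
                converged = True
                prev_ll = loglik
                break
            prev_ll = loglik
            # M-step
            pi = np.maximum(post.mean(axis=0), 1e-10)
            pi = pi / pi.sum()
            beta_new, ata = [], []
            for j in range(k):
                c = (post[:, j][:, None] * mask).sum(axis=0)  # per-timepoint weight
                d = (post[:, j][:, None] * mask * y0).sum(axis=0)
                xtx = designs[j].T @ (c[:, None] * designs[j])
                xtx += 1e-10 * np.eye(xtx.shape[0])
                beta_new.append(np.linalg.solve(xtx, designs[j].T @ d))
                ata.append(xtx)
            beta = beta_new
            resid2 = np.zeros(k)
            wobs = np.zeros(k)
            for j in range(k):
                mu = designs[j] @ beta[j]
                resid2[j] = (post[:, j] * ((y0 - mu) ** 2 * mask).sum(axis=1)).sum()
                wobs[j] = (post[:, j] * nobs).sum()
            if self.shared_sigma:
                sigma = float(np.sqrt(max(resid2.sum() / wobs.sum(), 1e-12)))
            else:
                sigma = np.sqrt(np.maximum(resid2 / np.maximum(wobs, 1e-12), 1e-12))
        if not np.isfinite(prev_ll):
            return None
        # posterior-weighted GLS covariance for Wald tests on coefficients
        beta_se = []
        sig = np.full(k, sigma) if np.isscalar(sigma) else np.asarray(sigma)
        for j in range(k):
            c = (post[:, j][:, None] * mask).sum(axis=0)
            xtx = designs[j].T @ (c[:, None] * designs[j]) + 1e-10 * np.eye(designs[j].shape[1])
            cov = sig[j] ** 2 * np.linalg.inv(xtx)
            beta_se.append(np.sqrt(np.maximum(np.diag(cov), 0.0)))
        return {
            "beta": beta,
            "beta_se": beta_se,
            "pi": pi,
            "sigma": sigma,
            "posterior": post,
            "loglik": prev_ll,
            "path": path,
            "converged": converged,
            "n_iter": it,
        }

    def _initial_params(self, y0, mask, designs, rng):
        """Cluster per-patient (level, slope) summaries, then per-cluster
        least squares; k-means seeding randomizes across starts."""
        k = self.n_classes
        n = y0.shape[0]
        nobs = mask.sum(axis=1)
        tc = self._tc_
        patient_mean = y0.sum(axis=1) / np.maximum(nobs, 1)
        # per-patient OLS slope over observed points
        tbar = (mask * tc).sum(axis=1) / np.maximum(nobs, 1)
        tdev = (tc[None, :] - tbar[:, None]) * mask
        denom = (tdev**2).sum(axis=1)
        num = (tdev * (y0 - patient_mean[:, None]) * mask).sum(axis=1)
        slope = np.where(denom > 0, num / np.maximum(denom, 1e-12), 0.0)
        feats = np.column_stack([patient_mean, slope])
        sdev = feats.std(axis=0)
        feats = feats / np.where(sdev > 0, sdev, 1.0)
        if n <= k:
            slice_of = np.arange(n) % k
        else:
            from sklearn.cluster import KMeans

            km = KMeans(
                n_clusters=k, n_init=1, random_state=int(rng.integers(2**31))
            ).fit(feats)
            slice_of = km.labels_
        spread = float(patient_mean.std()) or 1.0
        beta = []
        for j in range(k):
            in_slice = slice_of == j
            w = (in_slice.astype(float)[:, None] * mask).sum(axis=0)
            d = (in_slice.astype(float)[:, None] * mask * y0).sum(axis=0)
            xtx = designs[j].T @ (w[:, None] * designs[j]) + 1e-8 * np.eye(designs[j].shape[1])
            b = np.linalg.solve(xtx, designs[j].T @ d)
            jitter = rng.normal(0.0, 0.05 * spread, size=b.shape)
            jitter[1:] *= 0.3
            beta.append(b + jitter)
        resid = []
        for j in range(k):
            mu = designs[j] @ beta[j]
            in_slice = slice_of == j
            resid.append(((y0 - mu) ** 2 * mask)[in_slice].sum())
        sigma0 = float(np.sqrt(sum(resid) / max(nobs.sum(), 1)))
        sigma0 = max(sigma0, 1e-3)
        return beta, (sigma0 if self.shared_sigma else np.full(k, sigma0))

    # ------------------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        y0m, mask, grid_days = _as_matrix(X)
        tc = grid_days - self.t_center_
        designs = [_design(tc, o) for o in self.orders_]
        nobs = mask.sum(axis=1)
        ll = self._loglik_matrix(
            np.where(mask, y0m, 0.0), mask, nobs, designs, self.beta_centered_, self.sigma_
        )
        logjoint = np.log(np.maximum(self.pi_, 1e-300)) + ll
        return np.exp(logjoint - logsumexp(logjoint, axis=1)[:, None])

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def mean_curves(self) -> np.ndarray:
        """(K, T) fitted class mean OSI on the training grid."""
        tc = self.grid_days_ - self.t_center_
        return np.stack(
            [_design(tc, o) @ b for o, b in zip(self.orders_, self.beta_centered_)]
        )

    def top_term_pvalues(self) -> np.ndarray:
        """Two-sided Wald p-value of each class's highest-order coefficient."""
        out = np.empty(self.n_classes)
        for j in range(self.n_classes):
            b = self.beta_centered_[j][-1]
            se = self.beta_se_[j][-1]
            z = b / se if se > 0 else np.inf
            out[j] = 2.0 * stats.norm.sf(abs(z))
        return out


# ---------------------------------------------------------------------------
# functional surface


def fit_gbtm(
    series,
    n_classes: int,
    orders=2,
    n_starts: int = 20,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 500,
    shared_sigma: bool = True,
) -> TrajectoryGBTM:
    """Fit a K-class trajectory mixture; returns the fitted estimator."""
    return TrajectoryGBTM(
        n_classes=n_classes,
        orders=orders,
        n_starts=n_starts,
        seed=seed,
        tol=tol,
        max_iter=max_iter,
        shared_sigma=shared_sigma,
    ).fit(series)


def diagnostics(fit: TrajectoryGBTM) -> dict:
    """BIC, -2 log-likelihood, relative entropy, per-class APP and share."""
    n, k = fit.posterior_.shape
    post = np.clip(fit.posterior_, 1e-300, 1.0)
    if k == 1:
        entropy = 1.0
    else:
        entropy = 1.0 - float(-(post * np.log(post)).sum()) / (n * np.log(k))
    labels = np.argmax(fit.posterior_, axis=1)
    app = np.full(k, np.nan)
    share = np.zeros(k)
    for j in range(k):
        in_j = labels == j
        share[j] = in_j.mean()
        if in_j.any():
            app[j] = float(fit.posterior_[in_j, j].mean())
    return {
        "bic": float(-2.0 * fit.loglik_ + fit.n_params_ * np.log(n)),
        "minus2ll": float(-2.0 * fit.loglik_),
        "entropy": float(entropy),
        "app": app,
        "share": share,
    }


def admissibility(diag: dict, min_app: float = 0.7, min_share: float = 0.05) -> tuple:
    """Admissibility check on a diagnostics dict.

    Returns ``(admissible, reason)`` where ``reason`` joins the failed rules
    ("share<5%", "APP<0.7") with semicolons, empty when admissible.
    """
    reasons = []
    if np.any(diag["share"] < min_share):
        reasons.append("share<5%")
    if np.any(~np.isfinite(diag["app"])) or np.any(diag["app"] < min_app):
        reasons.append("APP<0.7")
    return (len(reasons) == 0), ";".join(reasons)


@dataclass
class ModelSelectionReport:
    """Audit trail of the two-stage selection protocol."""

    candidates: list = field(default_factory=list)
    chosen_k: int | None = None
    shape_steps: list = field(default_factory=list)
    final_fit: TrajectoryGBTM | None = None

    def to_dict(self) -> dict:
        return {
            "candidates": [
                {
                    key: (val.tolist() if isinstance(val, np.ndarray) else val)
                    for key, val in c.items()
                }
                for c in self.candidates
            ],
            "chosen_k": self.chosen_k,
            "shape_steps": self.shape_steps,
            "final_orders": None if self.final_fit is None else list(self.final_fit.orders_),
        }


def select_model(
    series,
    k_range=(2, 3, 4),
    seed: int = 0,
    n_starts: int = 10,
    alpha: float = 0.05,
    min_app: float = 0.7,
    min_share: float = 0.05,
    max_order: int = 3,
) -> ModelSelectionReport:
    """Two-stage trajectory model selection.

    Stage 1 fits every candidate K with all-quadratic shapes, rejects
    candidates with any class share < 5% or any average posterior
    probability < 0.7, and picks the admissible K with the lowest BIC.
    Stage 2 starts the chosen K from all-cubic shapes and repeatedly drops
    each class's highest-order term while its Wald p-value is >= alpha,
    never below linear.
    """
    report = ModelSelectionReport()
    best_k, best_bic = None, np.inf
    for k in k_range:
        fit = fit_gbtm(series, n_classes=k, orders=2, n_starts=n_starts, seed=seed)
        diag = diagnostics(fit)
        admissible, reason = admissibility(diag, min_app, min_share)
        report.candidates.append(
            {
                "k": int(k),
                "orders": list(fit.orders_),
                "bic": diag["bic"],
                "minus2ll": diag["minus2ll"],
                "entropy": diag["entropy"],
                "app": diag["app"],
                "share": diag["share"],
                "admissible": admissible,
                "rejection_reason": reason,
            }
        )
        if admissible and diag["bic"] < best_bic:
            best_k, best_bic = int(k), diag["bic"]
    if best_k is None:
        raise RuntimeError(
            "no admissible candidate class count; candidates: "
            + repr([(c["k"], c["rejection_reason"]) for c in report.candidates])
        )
    report.chosen_k = best_k

    orders = [max_order] * best_k
    while True:
        fit = fit_gbtm(series, n_classes=best_k, orders=orders, n_starts=n_starts, seed=seed)
        pvals = fit.top_term_pvalues()
        report.shape_steps.append(
            {"orders": list(fit.orders_), "top_term_p": [float(p) for p in pvals]}
        )
        droppable = [
            j for j in range(best_k) if fit.orders_[j] >= 2 and pvals[j] >= alpha
        ]
        if not droppable:
            report.final_fit = fit
            break
        orders = list(fit.orders_)
        for j in droppable:
            orders[j] -= 1
    return report


def assign_phenotypes(fit: TrajectoryGBTM) -> tuple[np.ndarray, np.ndarray]:
    """Modal phenotype labels (0-based, canonical low-to-high OSI order).

    Ties break toward the lower class index (argmax convention). Returns
    (labels, posterior).
    """
    return np.argmax(fit.posterior_, axis=1), fit.posterior_
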