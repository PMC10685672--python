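"""Causal mediation of the phenotype -> mortality effect through ARDS.

Quasi-Bayesian counterfactual simulation: logistic models are fitted for
the mediator (M ~ T + X) and the outcome (Y ~ T + M + X); parameter vectors
are drawn from each fit's asymptotic normal; each draw yields unit-level
counterfactual risks under the four (T, M(T')) regimes, averaged into the
average causal mediation effect (ACME, indirect), average direct effect
(ADE) and total effect. Effects are reported on the risk-difference scale
(on which ACME + ADE = TE exactly) and as odds ratios of the averaged
counterfactual risks. The default treatment contrast is the binary
poor-prognosis indicator (ascending or high-level-stable phenotype).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from osipheno.causal import _encode_covariates


@dataclass
class MediationResult:
    acme: float
    acme_ci: tuple
    ade: float
    ade_ci: tuple
    total: float
    total_ci: tuple
    proportion_mediated: float
    proportion_ci: tuple
    or_indirect: float
    or_direct: float
    n_sim: int
    #: per-draw (acme, ade, total) on the risk-difference scale
    draws: np.ndarray | None = None

    def mc_se(self) -> tuple:
        d = self.draws
        return tuple(float(s) for s in d.std(axis=0) / np.sqrt(len(d)))


def _fit_logit(x: np.ndarray, y: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, x, family=sm.families.Binomial())
        try:
            res = model.fit()
            return np.asarray(res.params), np.asarray(res.cov_params())
        except Exception:
            warnings.warn("separation in mediation model; penalized refit", stacklevel=2)
            res = model.fit_regularized(alpha=1e-4, L1_wt=0.0)
            p = np.asarray(res.params)
            return p, np.eye(len(p)) * 1e-4


def mediate(
    treatment,
    mediator,
    outcome,
    covariates: pd.DataFrame | None = None,
    n_sim: int = 1000,
    seed: int = 0,
    interaction: bool = False,
    alpha: float = 0.05,
) -> MediationResult:
    """Decompose the treatment effect into ACME (through the mediator) and ADE.

    treatment, mediator, outcome : binary 0/1 arrays
    covariates : complete baseline confounders (optional)
    interaction : include a T x M term in the outcome model; effects are then
        averaged over the two treatment arms
    """
    t = np.asarray(treatment, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    for name, v in (("treatment", t), ("mediator", m), ("outcome", y)):
        if set(np.unique(v)) - {0.0, 1.0}:
            raise ValueError(f"{name} must be binary 0/1")
        if len(np.unique(v)) < 2:
            raise ValueError(f"{name} is constant")
    n = len(y)
    if covariates is not None and covariates.shape[1] > 0:
        xc = _encode_covariates(covariates).to_numpy()
        if np.isnan(xc).any():
            raise ValueError("covariate matrix must be complete")
    else:
        xc = np.empty((n, 0))

    ones = np.ones(n)
    xm = np.column_stack([ones, t, xc])
    if interaction:
        xy = np.column_stack([ones, t, m, t * m, xc])
    else:
        xy = np.column_stack([ones, t, m, xc])
    med_params, med_cov = _fit_logit(xm, m)
    out_params, out_cov = _fit_logit(xy, y)

    rng = np.random.default_rng(seed)
    med_draws = rng.multivariate_normal(med_params, med_cov, size=n_sim)
    out_draws = rng.multivariate_normal(out_params, out_cov, size=n_sim)

    def mediator_prob(params, t_val):
        x = np.column_stack([ones, np.full(n, t_val), xc])
        return expit(x @ params)

    def outcome_prob(params, t_val, m_val):
        tt = np.full(n, t_val)
        mm = np.full(n, m_val)
        if interaction:
            x = np.column_stack([ones, tt, mm, tt * mm, xc])
        else:
            x = np.column_stack([ones, tt, mm, xc])
        return expit(x @ params)

    draws = np.empty((n_sim, 3))  # acme, ade, total (risk difference)
    p_cells = np.empty((n_sim, 4))  # mean risk under (t, t') in {(0,0),(0,1),(1,0),(1,1)}
    for s in range(n_sim):
        pm0 = mediator_prob(med_draws[s], 0.0)
        pm1 = mediator_prob(med_draws[s], 1.0)
        risk = {}
        for t_val in (0.0, 1.0):
            py1 = outcome_prob(out_draws[s], t_val, 1.0)
            py0 = outcome_prob(out_draws[s], t_val, 0.0)
            for tp, pm in ((0.0, pm0), (1.0, pm1)):
                risk[(t_val, tp)] = float(np.mean(py1 * pm + py0 * (1.0 - pm)))
        acme = 0.5 * ((risk[(1, 1)] - risk[(1, 0)]) + (risk[(0, 1)] - risk[(0, 0)]))
        ade = 0.5 * ((risk[(1, 1)] - risk[(0, 1)]) + (risk[(1, 0)] - risk[(0, 0)]))
        draws[s] = (acme, ade, risk[(1, 1)] - risk[(0, 0)])
        p_cells[s] = (risk[(0, 0)], risk[(0, 1)], risk[(1, 0)], risk[(1, 1)])

    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    acme, ade, total = draws.mean(axis=0)
    # proportion mediated on the risk-difference scale, per draw
    with np.errstate(divide="ignore", invalid="ignore"):
        prop_draws = draws[:, 0] / draws[:, 2]
    prop = float(acme / total) if total != 0 else np.nan
    p00, p01, p10, p11 = p_cells.mean(axis=0)

    def odds(p):
        return p / (1.0 - p)

    return MediationResult(
        acme=float(acme),
        acme_ci=tuple(np.percentile(draws[:, 0], [lo, hi])),
        ade=float(ade),
        ade_ci=tuple(np.percentile(draws[:, 1], [lo, hi])),
        total=float(total),
        total_ci=tuple(np.percentile(draws[:, 2], [lo, hi])),
        proportion_mediated=prop,
        proportion_ci=tuple(np.nanpercentile(prop_draws, [lo, hi])),
        or_indirect=float(odds(p11) / odds(p10)),
        or_direct=float(odds(p10) / odds(p00)),
        n_sim=n_sim,
        draws=draws,
    )


def poor_prognosis_indicator(labels, poor_classes=(2, 3)) -> np.ndarray:
    """Binary treatment contrast: ascending / high-level-stable vs the rest.

    In canonical (low-to-high mean OSI) 0-based labelling under the default
    trajectory shapes, classes 2 and 3 are the ascending and high-level
    stable phenotypes.
    """
    return np.isin(np.asarray(labels), np.asarray(poor_classes)).astype(int)


def marginal_effects(
    outcome, phenotype, mediator, covariates: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Predicted marginal risk per phenotype x mediator cell (g-computation).

    Fits a logistic model of the outcome on phenotype indicators, the
    mediator and covariates, then averages predicted risk over the empirical
    covariate distribution for each cell; SEs by the delta method.
    """
    y = np.asarray(outcome, dtype=float)
    z = np.asarray(phenotype)
    m = np.asarray(mediator, dtype=float)
    n = len(y)
    classes = list(np.unique(z))
    if covariates is not None and covariates.shape[1] > 0:
        xc = _encode_covariates(covariates).to_numpy()
    else:
        xc = np.empty((n, 0))
    ones = np.ones(n)
    cols = [ones] + [(z == c).astype(float) for c in classes[1:]] + [m]
    x = np.column_stack(cols + [xc])
    params, cov = _fit_logit(x, y)

    rows = []
    for c in classes:
        for m_val in (0.0, 1.0):
            dummies = [np.full(n, 1.0 if c == cc else 0.0) for cc in classes[1:]]
            xg = np.column_stack([ones] + dummies + [np.full(n, m_val), xc])
            eta = xg @ params
            p = expit(eta)
            risk = float(p.mean())
            grad = (p * (1.0 - p))[:, None] * xg
            gbar = grad.mean(axis=0)
            se = float(np.sqrt(gbar @ cov @ gbar))
            rows.append(
                {"phenotype": c, "mediator": int(m_val), "risk": risk, "se": se}
            )
    return pd.DataFrame(rows)
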