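"""Predictive model comparison: WAIC and Pareto-smoothed LOO-CV.

Both criteria are computed from the pointwise posterior log-likelihood
matrix (one column per contest, one row per retained draw).  The headline
number is on the deviance scale, -2 * elpd, so smaller is better.  AIC and
BIC are deliberately not provided: they assume flat priors and maximum a
posteriori estimation, which do not hold for these models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .contest_data import ContestTable
from .errors import UsageError
from .inference import PosteriorDraws
from .model import pointwise_terms

PARETO_K_WARN = 0.7


@dataclass
class InformationCriterion:
    """A WAIC or LOO estimate on the deviance scale.

    ``estimate`` = -2 * elpd; ``p_eff`` is the effective number of
    parameters (p_waic or p_loo); ``pointwise`` holds the per-contest elpd
    contributions, which sum to ``elpd``.
    """

    kind: str
    elpd: float
    estimate: float
    p_eff: float
    se: float
    pointwise: np.ndarray
    pareto_k: Optional[np.ndarray] = None
    warnings: list = field(default_factory=list)

    def to_row(self) -> dict:
        return {
            "kind": self.kind,
            "estimate": self.estimate,
            "elpd": self.elpd,
            "p_eff": self.p_eff,
            "se": self.se,
        }


def pointwise_log_likelihood(
    spec,
    draws: PosteriorDraws,
    data: ContestTable,
) -> np.ndarray:
    """(draw, contest) matrix of log p(observed outcome | draw).

    Vectorized over draws; each entry reuses the same per-contest
    categorical terms as the model log-likelihood, so summing a row
    reproduces that draw's total log-likelihood.
    """
    if data.n_players != len(draws.players):
        raise UsageError("draws and data disagree on the player set")
    i = data.player0_idx()
    j = data.player1_idx()
    if "lambda" in draws.params:
        base = draws.stacked("lambda")  # (D, N)
    else:
        base = draws.stacked("beta") @ draws.player_covariate_matrix.T
    theta0 = base[:, i]
    theta1 = base[:, j]
    if spec.requires_subjects:
        s = data.subject_idx()
        if s is None:
            raise UsageError("model needs subject identifiers in the data")
        if "U" in draws.params:
            U = draws.stacked("U")  # (D, N, S)
            theta0 = theta0 + U[:, i, s]
            theta1 = theta1 + U[:, j, s]
        if "S" in draws.params:
            S_coef = draws.stacked("S")  # (D, N, K)
            M = np.einsum("dnk,sk->dsn", S_coef,
                          draws.subject_covariate_matrix)
            theta0 = theta0 + M[:, s, i]
            theta1 = theta1 + M[:, s, j]
    if spec.has_order_effect:
        z = data.order.astype(float) if data.has_order \
            else np.ones(data.n_contests)
        theta1 = theta1 + draws.stacked("gamma")[:, None] * z
    if spec.handles_ties:
        nu = draws.stacked("nu")[:, None]
        s_tie = nu + 0.5 * (theta0 + theta1)
        scores = np.stack([theta0, theta1, s_tie])
        lse = logsumexp(scores, axis=0)
        return scores[data.result, :, np.arange(data.n_contests)].T - lse
    if data.has_ties:
        raise UsageError("tie outcomes under a bt model")
    d = theta0 - theta1
    sgn = np.where(data.result == 0, 1.0, -1.0)
    return -np.logaddexp(0.0, -sgn[None, :] * d)


def waic(pointwise: np.ndarray) -> InformationCriterion:
    """Widely applicable information criterion from a (draw, contest) matrix.

    lppd_n = log mean_d exp(ll[d, n]); the penalty p_waic is the pointwise
    posterior variance of the log-likelihood.  The log-mean-exp is computed
    with max-shift stabilization.
    """
    ll = np.asarray(pointwise, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise UsageError("waic needs a (draws, contests) matrix with >= 2 draws")
    n_draws, n_obs = ll.shape
    lppd = logsumexp(ll, axis=0) - np.log(n_draws)
    p_waic = ll.var(axis=0, ddof=1)
    warnings = []
    elpd_n = lppd - p_waic
    elpd = float(elpd_n.sum())
    se = float(np.sqrt(n_obs * elpd_n.var(ddof=1))) if n_obs > 1 else 0.0
    if np.any(p_waic > 0.4):
        warnings.append(
            f"{int(np.sum(p_waic > 0.4))} observation(s) with p_waic > 0.4; "
            "WAIC may be unreliable for them")
    return InformationCriterion(
        kind="WAIC", elpd=elpd, estimate=-2.0 * elpd,
        p_eff=float(p_waic.sum()), se=2.0 * se, pointwise=elpd_n,
        warnings=warnings)


def loo_psis(pointwise: np.ndarray, seed: Optional[int] = None
             ) -> InformationCriterion:
    """Pareto-smoothed importance-sampling LOO-CV.

    Importance ratios 1/p(y_n | draw) are Pareto-smoothed per observation;
    shape estimates k > 0.7 flag unreliable contributions.  The procedure
    is deterministic; ``seed`` is accepted for interface symmetry with the
    samplers and ignored.
    """
    from arviz.stats import psislw

    ll = np.asarray(pointwise, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise UsageError("loo needs a (draws, contests) matrix with >= 2 draws")
    n_draws, n_obs = ll.shape
    if ll.var(axis=0).max() == 0.0:
        # degenerate posterior: all draws identical, weights uniform
        elpd_n = ll[0]
        k = np.full(n_obs, -np.inf)
    else:
        log_weights, k = psislw(-ll.T)  # (n_obs, n_draws), normalized
        log_weights = np.asarray(log_weights)
        k = np.asarray(k)
        elpd_n = logsumexp(log_weights + ll.T, axis=1)
    lppd = logsumexp(ll, axis=0) - np.log(n_draws)
    elpd = float(elpd_n.sum())
    se = float(np.sqrt(n_obs * elpd_n.var(ddof=1))) if n_obs > 1 else 0.0
    warnings = []
    n_bad = int(np.sum(k > PARETO_K_WARN))
    if n_bad:
        warnings.append(
            f"{n_bad} observation(s) with Pareto k > {PARETO_K_WARN}; their "
            "LOO contributions are unreliable")
    return InformationCriterion(
        kind="LOO", elpd=elpd, estimate=-2.0 * elpd,
        p_eff=float(lppd.sum() - elpd), se=2.0 * se, pointwise=elpd_n,
        pareto_k=k, warnings=warnings)


def compare_models(criteria: dict) -> pd.DataFrame:
    """One row per model, sorted by the deviance-scale estimate (best first)."""
    rows = []
    for name, ic in criteria.items():
        row = {"model": name}
        row.update(ic.to_row())
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("estimate").reset_index(drop=True)
    df["delta_estimate"] = df["estimate"] - df["estimate"].iloc[0]
    return df
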