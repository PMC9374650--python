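"""Model composition: Bradley-Terry / Davidson bases and their extensions.

A model is a base (``bt`` for win/lose outcomes, ``davidson`` for
win/lose/tie) plus any subset of four extensions:

``ordereffect``
    a multiplicative advantage/disadvantage gamma attached to the
    second-listed player (additive on the log scale): P[i beats j] =
    exp(lambda_i) / (exp(lambda_i) + exp(lambda_j + gamma * z)).
``generalized``
    player log-abilities are replaced by a linear combination of player
    covariates, lambda_i = sum_k X[i,k] beta_k (no free intercepts; an
    intercept would not be identified).
``U``
    subject random effects: lambda_{i,s} = lambda_i + U[i,s] with
    U[i,s] ~ N(0, U_std^2) and a half-normal hyperprior on U_std.
``subjectpredictors``
    subject covariates with player-specific coefficients:
    lambda_{i,s} = lambda_i + sum_k x[s,k] S[i,k], giving N*K coefficients.

Model names use the dash grammar ``base[-ext]...`` (e.g.
``davidson-generalized-U``); extensions may appear in any order and are
normalized to a canonical one.

All probabilities are evaluated through differences on the log scale
(stable logistic / log-sum-exp), so abilities up to |theta| ~ 700 do not
overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import special, stats

from .contest_data import (
    RESULT_TIE,
    RESULT_WIN0,
    RESULT_WIN1,
    ContestTable,
    CovariateTable,
)
from .errors import ConfigurationError, DataError, UsageError

BASE_MODELS = ("bt", "davidson")
EXTENSIONS = ("ordereffect", "generalized", "U", "subjectpredictors")

#: Prior standard deviations used throughout: variance 3.0 for abilities,
#: covariate coefficients and the random-effect hyper-scale (weakly
#: informative while keeping the soft identification constraint), and
#: variance 1.0 for the tie and order-effect parameters.
DEFAULT_ABILITY_SD = math.sqrt(3.0)


@dataclass(frozen=True)
class PriorConfig:
    """Standard deviations of the zero-mean normal priors.

    ``U_sd`` is the scale of the half-normal hyperprior on the
    random-effect standard deviation U_std.
    """

    lambda_sd: float = DEFAULT_ABILITY_SD
    nu_sd: float = 1.0
    gamma_sd: float = 1.0
    beta_sd: float = DEFAULT_ABILITY_SD
    U_sd: float = DEFAULT_ABILITY_SD
    S_sd: float = DEFAULT_ABILITY_SD

    def __post_init__(self):
        for name in ("lambda_sd", "nu_sd", "gamma_sd", "beta_sd", "U_sd", "S_sd"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"prior scale {name} must be positive")

    def to_dict(self) -> dict:
        return {
            "lambda_sd": self.lambda_sd,
            "nu_sd": self.nu_sd,
            "gamma_sd": self.gamma_sd,
            "beta_sd": self.beta_sd,
            "U_sd": self.U_sd,
            "S_sd": self.S_sd,
        }


@dataclass(frozen=True)
class ModelSpec:
    """A concrete base-model x extension combination plus prior scales.

    Dimensions (number of players N, subjects S, covariates K) are bound
    when the spec meets data; they may be None for a spec parsed from a
    bare model string.
    """

    base: str
    extensions: tuple = ()
    priors: PriorConfig = field(default_factory=PriorConfig)
    n_players: Optional[int] = None
    n_subjects: Optional[int] = None
    n_covariates: Optional[int] = None

    def __post_init__(self):
        if self.base not in BASE_MODELS:
            raise ConfigurationError(
                f"unknown base model {self.base!r}; valid bases: {BASE_MODELS}"
            )
        canon = tuple(e for e in EXTENSIONS if e in self.extensions)
        unknown = set(self.extensions) - set(EXTENSIONS)
        if unknown:
            raise ConfigurationError(
                f"unknown extensions {sorted(unknown)}; valid extensions: "
                f"{list(EXTENSIONS)}"
            )
        if len(set(self.extensions)) != len(self.extensions):
            raise ConfigurationError("duplicate extension in model name")
        object.__setattr__(self, "extensions", canon)

    # -- grammar -----------------------------------------------------------

    @classmethod
    def from_string(cls, name: str, priors: Optional[PriorConfig] = None,
                    **dims) -> "ModelSpec":
        parts = name.split("-")
        return cls(base=parts[0], extensions=tuple(parts[1:]),
                   priors=priors or PriorConfig(), **dims)

    @property
    def name(self) -> str:
        return "-".join((self.base,) + self.extensions)

    def __str__(self) -> str:
        return self.name

    # -- feature flags -----------------------------------------------------

    @property
    def handles_ties(self) -> bool:
        return self.base == "davidson"

    @property
    def has_order_effect(self) -> bool:
        return "ordereffect" in self.extensions

    @property
    def is_generalized(self) -> bool:
        return "generalized" in self.extensions

    @property
    def has_random_effects(self) -> bool:
        return "U" in self.extensions

    @property
    def has_subject_predictors(self) -> bool:
        return "subjectpredictors" in self.extensions

    @property
    def requires_subjects(self) -> bool:
        return self.has_random_effects or self.has_subject_predictors

    @property
    def subject_varying(self) -> bool:
        """Do effective abilities depend on the subject?"""
        return self.requires_subjects

    def with_dimensions(self, n_players: int, n_subjects: Optional[int] = None,
                        n_covariates: Optional[int] = None) -> "ModelSpec":
        return replace(self, n_players=n_players, n_subjects=n_subjects,
                       n_covariates=n_covariates)

    def bind(self, data: ContestTable,
             player_covariates: Optional[CovariateTable] = None,
             subject_covariates: Optional[CovariateTable] = None) -> "ModelSpec":
        """Attach dimensions from data, checking compatibility."""
        if self.requires_subjects and not data.has_subjects:
            raise DataError(
                f"model {self.name!r} needs a subject column but the data "
                "carry none"
            )
        n_cov = None
        if self.is_generalized:
            if player_covariates is None:
                raise ConfigurationError(
                    "generalized models need a player covariate table")
            n_cov = player_covariates.n_covariates
        if self.has_subject_predictors:
            if subject_covariates is None:
                raise ConfigurationError(
                    "subjectpredictors models need a subject covariate table")
            if n_cov is not None and subject_covariates.n_covariates != n_cov:
                raise ConfigurationError(
                    "player and subject covariate tables disagree on K")
            n_cov = subject_covariates.n_covariates
        return self.with_dimensions(
            n_players=data.n_players,
            n_subjects=data.n_subjects,
            n_covariates=n_cov,
        )


@dataclass
class ParameterSet:
    """One concrete assignment of all parameters active in a ModelSpec.

    Only the fields the spec activates are set; the rest stay None.
    ``U`` is the N x S matrix of realized random effects, ``U_std`` its
    scale, ``S_coef`` the N x K subject-predictor coefficient matrix.
    """

    lam: Optional[np.ndarray] = None
    nu: Optional[float] = None
    gamma: Optional[float] = None
    beta: Optional[np.ndarray] = None
    U: Optional[np.ndarray] = None
    U_std: Optional[float] = None
    S_coef: Optional[np.ndarray] = None

    def validate(self, spec: ModelSpec) -> None:
        if spec.is_generalized:
            if self.beta is None:
                raise UsageError("generalized spec needs beta")
            if self.lam is not None:
                raise UsageError(
                    "generalized models replace free lambda by X @ beta; "
                    "both cannot be set"
                )
        elif self.lam is None:
            raise UsageError("spec needs a lambda vector")
        if spec.handles_ties and self.nu is None:
            raise UsageError("davidson spec needs nu")
        if spec.has_order_effect and self.gamma is None:
            raise UsageError("order-effect spec needs gamma")
        if spec.has_random_effects:
            if self.U is None or self.U_std is None:
                raise UsageError("random-effects spec needs U and U_std")
            if not self.U_std > 0:
                raise UsageError("U_std must be positive")
        if spec.has_subject_predictors and self.S_coef is None:
            raise UsageError("subjectpredictors spec needs S_coef")


# ---------------------------------------------------------------------------
# Probability kernels
# ---------------------------------------------------------------------------


def bt_win_probability(theta_i, theta_j, gamma=None, z=None):
    """P[i beats j] = exp(theta_i) / (exp(theta_i) + exp(theta_j + gamma*z)).

    Computed as a logistic of the ability difference, so the complement
    identity P(i,j) + P(j,i) = 1 holds exactly and large |theta| saturate
    smoothly.  ``z`` defaults to 1 when ``gamma`` is given (an order effect
    with no per-contest indicator applies to every contest).
    """
    d = np.asarray(theta_i, dtype=float) - np.asarray(theta_j, dtype=float)
    if gamma is not None:
        zz = 1.0 if z is None else np.asarray(z, dtype=float)
        d = d - np.asarray(gamma, dtype=float) * zz
    # evaluate the logistic on |d| (result in [0.5, 1), whose complement
    # 1 - p is exact), so P(i,j) + P(j,i) == 1 holds bit-for-bit
    p_hi = special.expit(np.abs(d))
    out = np.where(d >= 0, p_hi, 1.0 - p_hi)
    return out[()] if out.ndim == 0 else out


def davidson_probabilities(theta_i, theta_j, nu, gamma=None, z=None):
    """Three-outcome Davidson probabilities (win-i, win-j, tie).

    The tie weight is exp(nu + (theta_i + theta_j')/2), the geometric mean
    of the two (order-adjusted) ability weights scaled by exp(nu); the
    order-effect shift enters theta_j everywhere it appears, including the
    tie term, so the three probabilities stay normalized.
    """
    ti = np.asarray(theta_i, dtype=float)
    tj = np.asarray(theta_j, dtype=float)
    if gamma is not None:
        zz = 1.0 if z is None else np.asarray(z, dtype=float)
        tj = tj + np.asarray(gamma, dtype=float) * zz
    scores = np.stack(np.broadcast_arrays(
        ti, tj, np.asarray(nu, dtype=float) + 0.5 * (ti + tj)))
    probs = special.softmax(scores, axis=0)
    return probs[0], probs[1], probs[2]


# ---------------------------------------------------------------------------
# Effective abilities
# ---------------------------------------------------------------------------


def ability_vector(
    spec: ModelSpec,
    params: ParameterSet,
    subject: Optional[int] = None,
    player_covariates: Optional[np.ndarray] = None,
    subject_covariates: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Effective log-abilities of all players, for one subject if needed.

    Covariate arguments are plain matrices already aligned to the player /
    subject index order (see ``CovariateTable.matrix``).
    """
    if spec.is_generalized:
        if player_covariates is None:
            raise UsageError("generalized spec needs the player covariate matrix")
        base = np.asarray(player_covariates, dtype=float) @ np.asarray(
            params.beta, dtype=float)
    else:
        base = np.asarray(params.lam, dtype=float).copy()
    if spec.requires_subjects:
        if subject is None:
            raise UsageError(
                "effective abilities vary by subject for this model; pass a "
                "subject index"
            )
        if spec.has_random_effects:
            base = base + np.asarray(params.U, dtype=float)[:, subject]
        if spec.has_subject_predictors:
            if subject_covariates is None:
                raise UsageError(
                    "subjectpredictors spec needs the subject covariate matrix")
            x_s = np.asarray(subject_covariates, dtype=float)[subject]
            base = base + np.asarray(params.S_coef, dtype=float) @ x_s
    return base


def effective_ability(
    spec: ModelSpec,
    params: ParameterSet,
    player: int,
    subject: Optional[int] = None,
    player_covariates: Optional[np.ndarray] = None,
    subject_covariates: Optional[np.ndarray] = None,
) -> float:
    """theta for one player (0-based index), for one subject if required."""
    vec = ability_vector(spec, params, subject=subject,
                         player_covariates=player_covariates,
                         subject_covariates=subject_covariates)
    return float(vec[player])


# ---------------------------------------------------------------------------
# Log-likelihood and log-prior
# ---------------------------------------------------------------------------


def _contest_thetas(spec, params, data, player_covariates, subject_covariates):
    """Per-contest effective abilities (theta0, theta1) and order column."""
    i = data.player0_idx()
    j = data.player1_idx()
    if spec.is_generalized:
        if player_covariates is None:
            raise UsageError("generalized spec needs the player covariate matrix")
        base = np.asarray(player_covariates, dtype=float) @ np.asarray(
            params.beta, dtype=float)
    else:
        base = np.asarray(params.lam, dtype=float)
    theta0 = base[i].astype(float)
    theta1 = base[j].astype(float)
    if spec.requires_subjects:
        s = data.subject_idx()
        if s is None:
            raise DataError(f"model {spec.name!r} needs subject identifiers")
        if spec.has_random_effects:
            U = np.asarray(params.U, dtype=float)
            theta0 = theta0 + U[i, s]
            theta1 = theta1 + U[j, s]
        if spec.has_subject_predictors:
            if subject_covariates is None:
                raise UsageError(
                    "subjectpredictors spec needs the subject covariate matrix")
            x = np.asarray(subject_covariates, dtype=float)
            M = x @ np.asarray(params.S_coef, dtype=float).T  # (S, N)
            theta0 = theta0 + M[s, i]
            theta1 = theta1 + M[s, j]
    if spec.has_order_effect:
        z = data.order.astype(float) if data.has_order else np.ones(data.n_contests)
        theta1 = theta1 + float(params.gamma) * z
    return theta0, theta1


def pointwise_terms(
    spec: ModelSpec,
    params: ParameterSet,
    data: ContestTable,
    player_covariates: Optional[np.ndarray] = None,
    subject_covariates: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Log probability of each contest's observed outcome.

    Under ``bt`` each term is the Bernoulli log-probability of the observed
    winner; under ``davidson`` it is the log of the three-outcome
    categorical probability (win-0 / win-1 / tie).
    """
    params.validate(spec)
    if data.has_ties and not spec.handles_ties:
        row = int(np.flatnonzero(data.result == RESULT_TIE)[0]) + 1
        raise DataError(
            f"row {row}: tie result under base model 'bt'; use a davidson "
            "model or drop/recode ties explicitly"
        )
    theta0, theta1 = _contest_thetas(spec, params, data,
                                     player_covariates, subject_covariates)
    res = data.result
    if not spec.handles_ties:
        d = theta0 - theta1
        sgn = np.where(res == RESULT_WIN0, 1.0, -1.0)
        return -np.logaddexp(0.0, -sgn * d)
    s_tie = float(params.nu) + 0.5 * (theta0 + theta1)
    scores = np.stack([theta0, theta1, s_tie])  # rows match result codes 0,1,2
    lse = special.logsumexp(scores, axis=0)
    return scores[res, np.arange(data.n_contests)] - lse


def log_likelihood(
    spec: ModelSpec,
    params: ParameterSet,
    data: ContestTable,
    player_covariates: Optional[np.ndarray] = None,
    subject_covariates: Optional[np.ndarray] = None,
) -> tuple:
    """(total, pointwise) log-likelihood of the data under one ParameterSet."""
    pw = pointwise_terms(spec, params, data,
                         player_covariates=player_covariates,
                         subject_covariates=subject_covariates)
    return float(pw.sum()), pw


def log_prior(spec: ModelSpec, params: ParameterSet) -> float:
    """Sum of the log prior densities of all active parameters.

    Independent zero-mean normals for lambda (or beta), nu, gamma and the
    subject-predictor coefficients; hierarchical normals for the random
    effects, U[i,s] ~ N(0, U_std^2), with a half-normal hyperprior on
    U_std.
    """
    params.validate(spec)
    pri = spec.priors
    total = 0.0
    if spec.is_generalized:
        total += stats.norm.logpdf(params.beta, 0.0, pri.beta_sd).sum()
    else:
        total += stats.norm.logpdf(params.lam, 0.0, pri.lambda_sd).sum()
    if spec.handles_ties:
        total += stats.norm.logpdf(params.nu, 0.0, pri.nu_sd)
    if spec.has_order_effect:
        total += stats.norm.logpdf(params.gamma, 0.0, pri.gamma_sd)
    if spec.has_random_effects:
        if not params.U_std > 0:
            raise UsageError("U_std must be positive")
        total += stats.norm.logpdf(params.U, 0.0, params.U_std).sum()
        total += stats.halfnorm.logpdf(params.U_std, scale=pri.U_sd)
    if spec.has_subject_predictors:
        total += stats.norm.logpdf(params.S_coef, 0.0, pri.S_sd).sum()
    return float(total)
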