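"""Posterior sampling and MCMC convergence diagnostics.

``sample_posterior`` runs the NUTS sampler on the composed log posterior
(likelihood + priors) of any model combination and returns a
``PosteriorDraws`` container.  Diagnostics follow standard Hamiltonian
Monte Carlo practice: rank-normalized split R-hat (< 1.01 required),
effective sample size (>= 200 per parameter as a rule of thumb for
estimating means), zero divergent transitions, E-BFMI >= 0.2, and
maximum-treedepth hits reported as an efficiency warning rather than a
validity failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._logdensity import ModelLogDensity
from .contest_data import ContestTable, CovariateTable
from .errors import ConfigurationError, InitializationError, UsageError
from .model import ModelSpec, ParameterSet
from .nuts import sample_chain

RHAT_THRESHOLD = 1.01
ESS_THRESHOLD = 200.0
EBFMI_THRESHOLD = 0.2


@dataclass(frozen=True)
class SamplerConfig:
    """NUTS run configuration.

    ``iterations`` counts all iterations per chain including warmup, so
    each chain retains ``iterations - warmup`` draws.
    """

    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    target_accept: float = 0.9
    max_treedepth: int = 10
    seed: int = 0
    metric: str = "auto"

    def __post_init__(self):
        if self.chains < 1 or self.iterations < 1 or self.warmup < 0:
            raise ConfigurationError("chains, iterations and warmup must be positive")
        if self.warmup >= self.iterations:
            raise ConfigurationError("warmup must be smaller than iterations")
        if not 0 < self.target_accept < 1:
            raise ConfigurationError("target_accept must lie in (0, 1)")
        if self.metric not in ("auto", "diag", "dense"):
            raise ConfigurationError("metric must be 'auto', 'diag' or 'dense'")

    def to_dict(self) -> dict:
        return {
            "chains": self.chains,
            "iterations": self.iterations,
            "warmup": self.warmup,
            "target_accept": self.target_accept,
            "max_treedepth": self.max_treedepth,
            "seed": self.seed,
            "metric": self.metric,
        }


@dataclass
class PosteriorDraws:
    """Retained posterior draws of every model parameter plus sampler stats.

    ``params`` maps block names (``lambda``, ``nu``, ``gamma``, ``beta``,
    ``U``, ``U_std``, ``S``) to arrays indexed ``(chain, draw, ...)``;
    ``stats`` holds per-iteration sampler statistics (``divergent``,
    ``treedepth``, ``energy``, ``accept_stat``), each ``(chain, draw)``.
    """

    spec: ModelSpec
    params: dict
    stats: dict
    players: tuple
    subjects: Optional[tuple] = None
    covariate_names: Optional[tuple] = None
    player_covariate_matrix: Optional[np.ndarray] = None
    subject_covariate_matrix: Optional[np.ndarray] = None
    data_fingerprint: Optional[str] = None
    config: Optional[SamplerConfig] = None

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_retained(self) -> int:
        return next(iter(self.params.values())).shape[1]

    # -- access helpers ----------------------------------------------------

    def stacked(self, block: str) -> np.ndarray:
        """Draws of one block with chains merged: (chain*draw, ...)."""
        arr = self.params[block]
        return arr.reshape((-1,) + arr.shape[2:])

    def scalar_draws(self) -> dict:
        """Every scalar parameter as name -> (chain, draw) array."""
        out = {}
        for block, arr in self.params.items():
            labels = self._labels(block)
            if arr.ndim == 2:
                out[labels[0]] = arr
            elif arr.ndim == 3:
                for k, lab in enumerate(labels):
                    out[lab] = arr[:, :, k]
            else:  # (chain, draw, N, S-or-K)
                for a in range(arr.shape[2]):
                    for b in range(arr.shape[3]):
                        out[labels[a * arr.shape[3] + b]] = arr[:, :, a, b]
        return out

    def _labels(self, block: str) -> list:
        if block == "lambda":
            return [f"lambda[{p}]" for p in self.players]
        if block == "beta":
            names = self.covariate_names or range(self.params["beta"].shape[2])
            return [f"beta[{c}]" for c in names]
        if block == "U":
            return [f"U[{p},{s}]" for p in self.players for s in self.subjects]
        if block == "S":
            names = self.covariate_names or range(self.params["S"].shape[3])
            return [f"S[{p},{c}]" for p in self.players for c in names]
        return [block]

    def parameter_set(self, chain: int, draw: int) -> ParameterSet:
        p = self.params
        return ParameterSet(
            lam=p["lambda"][chain, draw] if "lambda" in p else None,
            nu=float(p["nu"][chain, draw]) if "nu" in p else None,
            gamma=float(p["gamma"][chain, draw]) if "gamma" in p else None,
            beta=p["beta"][chain, draw] if "beta" in p else None,
            U=p["U"][chain, draw] if "U" in p else None,
            U_std=float(p["U_std"][chain, draw]) if "U_std" in p else None,
            S_coef=p["S"][chain, draw] if "S" in p else None,
        )

    def ability_draws(self, subject=None, average_subjects: bool = False
                      ) -> np.ndarray:
        """Effective log-ability draws per player: (chain*draw, N).

        For subject-varying models either name a subject (label or index)
        or request the average subject (random effects and subject-covariate
        contributions set to zero).
        """
        if "lambda" in self.params:
            base = self.stacked("lambda")
        else:
            beta = self.stacked("beta")
            base = beta @ self.player_covariate_matrix.T
        if not self.spec.subject_varying:
            return base
        if average_subjects:
            return base
        if subject is None:
            raise UsageError(
                "abilities vary by subject for this model; pass subject=... "
                "or average_subjects=True for the population-level lambda"
            )
        if not isinstance(subject, (int, np.integer)):
            subject = self.subjects.index(subject)
        out = base.copy()
        if "U" in self.params:
            out = out + self.stacked("U")[:, :, subject]
        if "S" in self.params:
            x_s = self.subject_covariate_matrix[subject]
            out = out + self.stacked("S") @ x_s
        return out

    # -- serialization -----------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: chain, iteration, parameter, value."""
        frames = []
        for name, arr in self.scalar_draws().items():
            c, d = arr.shape
            frames.append(pd.DataFrame({
                "chain": np.repeat(np.arange(c), d),
                "iteration": np.tile(np.arange(d), c),
                "parameter": name,
                "value": arr.reshape(-1),
            }))
        return pd.concat(frames, ignore_index=True)

    def stats_dataframe(self) -> pd.DataFrame:
        c, d = self.stats["energy"].shape
        return pd.DataFrame({
            "chain": np.repeat(np.arange(c), d),
            "iteration": np.tile(np.arange(d), c),
            "divergent": self.stats["divergent"].reshape(-1).astype(int),
            "treedepth": self.stats["treedepth"].reshape(-1),
            "energy": self.stats["energy"].reshape(-1),
            "accept_stat": self.stats["accept_stat"].reshape(-1),
        })


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def sample_posterior(
    spec: ModelSpec,
    data: ContestTable,
    config: SamplerConfig,
    player_covariates: Optional[CovariateTable] = None,
    subject_covariates: Optional[CovariateTable] = None,
) -> PosteriorDraws:
    """Draw from the posterior of ``spec`` given ``data`` with NUTS.

    An identical (seed, config, data) triple reproduces the draw arrays
    bit for bit for a fixed backend version.  Chains are initialized
    uniformly in [-2, 2] on the unconstrained scale.
    """
    import warnings as _warnings

    spec = spec.bind(data, player_covariates, subject_covariates)
    X = None
    x_sub = None
    cov_names = None
    if spec.is_generalized:
        if not player_covariates.is_standardized():
            _warnings.warn(
                "player covariates are not standardized; the shared prior "
                "scale then weighs columns unevenly", stacklevel=2)
        X = player_covariates.matrix(data.players)
        cov_names = player_covariates.columns
    if spec.has_subject_predictors:
        if not subject_covariates.is_standardized():
            _warnings.warn(
                "subject covariates are not standardized; the shared prior "
                "scale then weighs columns unevenly", stacklevel=2)
        x_sub = subject_covariates.matrix(data.subjects)
        cov_names = subject_covariates.columns

    density = ModelLogDensity(spec, data, player_covariates=X,
                              subject_covariates=x_sub)
    n_keep = config.iterations - config.warmup
    chain_results = []
    seed_seq = np.random.SeedSequence(config.seed)
    for child in seed_seq.spawn(config.chains):
        rng = np.random.default_rng(child)
        x0 = None
        for _ in range(100):
            candidate = rng.uniform(-2.0, 2.0, size=density.dim)
            lp, _ = density.logp_grad(candidate)
            if np.isfinite(lp):
                x0 = candidate
                break
        if x0 is None:
            raise InitializationError(
                "could not find a finite log density in 100 tries; consider "
                "smaller prior standard deviations"
            )
        chain_results.append(sample_chain(
            density.logp_grad, x0, rng,
            n_iterations=config.iterations, warmup=config.warmup,
            target_accept=config.target_accept,
            max_treedepth=config.max_treedepth,
            metric_kind=config.metric,
        ))

    # constrain draws into named blocks
    blocks: dict = {}
    for c, res in enumerate(chain_results):
        for d in range(n_keep):
            named = density.constrain(res.draws[d])
            for name, value in named.items():
                arr = np.asarray(value, dtype=float)
                if name not in blocks:
                    blocks[name] = np.empty(
                        (config.chains, n_keep) + arr.shape)
                blocks[name][c, d] = arr

    stats = {
        "divergent": np.stack([r.divergent for r in chain_results]),
        "treedepth": np.stack([r.treedepth for r in chain_results]),
        "energy": np.stack([r.energy for r in chain_results]),
        "accept_stat": np.stack([r.accept_stat for r in chain_results]),
    }
    return PosteriorDraws(
        spec=spec,
        params=blocks,
        stats=stats,
        players=data.players,
        subjects=data.subjects,
        covariate_names=cov_names,
        player_covariate_matrix=X,
        subject_covariate_matrix=x_sub,
        data_fingerprint=data.fingerprint(),
        config=config,
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def split_rhat(chain_draws: np.ndarray, rank_normalized: bool = True) -> float:
    """Split Gelman-Rubin R-hat for one parameter.

    ``chain_draws`` has shape (chains, iterations).  Each chain is split in
    half; by default the pooled draws are rank-normalized (normal scores)
    before the between/within variance ratio is formed, which makes the
    statistic robust to heavy tails.  Degenerate inputs return flagged
    values rather than raising: ``inf`` when chains are constant at
    different values, ``nan`` when every draw is identical.
    """
    arr = np.asarray(chain_draws, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 4:
        raise UsageError("split_rhat needs >= 2 chains with >= 4 iterations")
    half = arr.shape[1] // 2
    split = np.concatenate([arr[:, :half], arr[:, half:2 * half]], axis=0)
    if rank_normalized:
        flat = split.reshape(-1)
        ranks = sps.rankdata(flat, method="average")
        z = sps.norm.ppf((ranks - 3.0 / 8.0) / (flat.size + 0.25))
        split = z.reshape(split.shape)
    m, n = split.shape
    chain_means = split.mean(axis=1)
    chain_vars = split.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w == 0.0:
        return float("nan") if b == 0.0 else float("inf")
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def effective_sample_size(chain_draws: np.ndarray) -> float:
    """Bulk (rank-normalized) effective sample size for one parameter."""
    import arviz as az

    arr = np.asarray(chain_draws, dtype=float)
    with np.errstate(invalid="ignore"):
        return float(az.ess(np.expand_dims(arr, -1) if arr.ndim == 1 else arr,
                            method="bulk"))


def e_bfmi(energy: np.ndarray) -> np.ndarray:
    """Estimated Bayesian fraction of missing information, per chain."""
    e = np.atleast_2d(np.asarray(energy, dtype=float))
    num = np.mean(np.diff(e, axis=1) ** 2, axis=1)
    den = e.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den


@dataclass
class ConvergenceDiagnostics:
    rhat: dict
    ess: dict
    n_divergent: int
    treedepth_hits: int
    ebfmi: np.ndarray
    passed: bool
    reasons: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "reasons": list(self.reasons),
            "warnings": list(self.warnings),
            "n_divergent": self.n_divergent,
            "treedepth_hits": self.treedepth_hits,
            "ebfmi": [float(v) for v in np.atleast_1d(self.ebfmi)],
            "rhat": {k: float(v) for k, v in self.rhat.items()},
            "ess": {k: float(v) for k, v in self.ess.items()},
        }

    def to_text(self) -> str:
        lines = ["Convergence diagnostics",
                 "=======================",
                 f"verdict: {'PASS' if self.passed else 'FAIL'}"]
        for r in self.reasons:
            lines.append(f"  reason: {r}")
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        lines.append(f"divergent iterations: {self.n_divergent}")
        lines.append(f"max-treedepth hits:   {self.treedepth_hits}")
        lines.append("E-BFMI per chain:     "
                     + ", ".join(f"{v:.3f}" for v in np.atleast_1d(self.ebfmi)))
        lines.append("")
        lines.append(f"{'parameter':<24}{'rhat':>10}{'ess':>10}")
        for name in self.rhat:
            lines.append(f"{name:<24}{self.rhat[name]:>10.4f}"
                         f"{self.ess[name]:>10.0f}")
        return "\n".join(lines)


def apply_diagnostic_rules(
    rhat: dict,
    ess: dict,
    n_divergent: int,
    treedepth_hits: int,
    ebfmi: np.ndarray,
) -> tuple:
    """Evaluate the documented pass/fail rules on already-computed values.

    Failure rules: any R-hat >= 1.01, any ESS < 200, any divergent
    iteration, any chain E-BFMI < 0.2.  Treedepth hits are an efficiency
    warning only.  Returns (passed, reasons, warnings).
    """
    reasons = []
    warnings = []
    bad_rhat = {k: v for k, v in rhat.items()
                if not np.isfinite(v) or v >= RHAT_THRESHOLD}
    if bad_rhat:
        worst = max(bad_rhat, key=lambda k: np.nan_to_num(bad_rhat[k], nan=np.inf))
        reasons.append(
            f"{len(bad_rhat)} parameter(s) with split R-hat >= "
            f"{RHAT_THRESHOLD} (worst: {worst} = {bad_rhat[worst]:.4f})")
    bad_ess = {k: v for k, v in ess.items()
               if not np.isfinite(v) or v < ESS_THRESHOLD}
    if bad_ess:
        worst = min(bad_ess, key=lambda k: np.nan_to_num(bad_ess[k], nan=-1))
        reasons.append(
            f"{len(bad_ess)} parameter(s) with effective sample size < "
            f"{ESS_THRESHOLD:.0f} (worst: {worst} = {bad_ess[worst]:.0f})")
    if n_divergent > 0:
        reasons.append(f"{n_divergent} divergent iteration(s); the sampler "
                       "has not fully explored the posterior")
    low_bfmi = np.atleast_1d(ebfmi) < EBFMI_THRESHOLD
    if low_bfmi.any():
        reasons.append(
            f"{int(low_bfmi.sum())} chain(s) with E-BFMI < {EBFMI_THRESHOLD}")
    if treedepth_hits > 0:
        warnings.append(
            f"{treedepth_hits} iteration(s) hit max treedepth (efficiency "
            "concern, not a validity failure)")
    return len(reasons) == 0, reasons, warnings


def check_convergence_diagnostics(draws: PosteriorDraws) -> ConvergenceDiagnostics:
    """Full diagnostic report with an overall pass/fail verdict."""
    scalars = draws.scalar_draws()
    rhat = {}
    ess = {}
    for name, arr in scalars.items():
        rhat[name] = split_rhat(arr)
        ess[name] = effective_sample_size(arr)
    n_div = int(draws.stats["divergent"].sum())
    td_hits = int(np.sum(
        draws.stats["treedepth"] >= (draws.config.max_treedepth
                                     if draws.config else 10)))
    bfmi = e_bfmi(draws.stats["energy"])
    passed, reasons, warnings = apply_diagnostic_rules(
        rhat, ess, n_div, td_hits, bfmi)
    return ConvergenceDiagnostics(
        rhat=rhat, ess=ess, n_divergent=n_div, treedepth_hits=td_hits,
        ebfmi=bfmi, passed=passed, reasons=reasons, warnings=warnings)
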