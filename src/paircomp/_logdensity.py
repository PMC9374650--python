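"""Unconstrained log posterior density with analytic gradients.

The sampler works on a flat unconstrained vector.  Layout (only active
blocks are present):

    lambda (N)  or  beta (K)     free abilities / covariate coefficients
    nu (1)                       tie balance (davidson)
    gamma (1)                    order effect
    u_raw (N*S), log_u_std (1)   non-centered random effects:
                                 U = exp(log_u_std) * u_raw
    s_coef (N*K)                 subject-predictor coefficients

The random effects use the non-centered parameterization (u_raw ~ N(0,1),
U = U_std * u_raw) with U_std sampled on the log scale; the log-density
includes the log-Jacobian of that transform, so the target is mathematically
identical to the centered hierarchical prior.

Every contest contributes a categorical log-probability whose category
scores are (theta0, theta1 + gamma*z[, nu + (theta0 + theta1 + gamma*z)/2]).
Contests sharing (players, subject, order, outcome) are collapsed to one
weighted row, which makes the per-evaluation cost depend on the number of
distinct matchups rather than the number of contests.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy import special

from .contest_data import ContestTable
from .errors import DataError, UsageError
from .model import ModelSpec

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class ModelLogDensity:
    """logp(x) and grad logp(x) for one (spec, data) pair."""

    def __init__(
        self,
        spec: ModelSpec,
        data: ContestTable,
        player_covariates: Optional[np.ndarray] = None,
        subject_covariates: Optional[np.ndarray] = None,
    ):
        if data.has_ties and not spec.handles_ties:
            raise DataError(
                "data contain ties but the model has no tie component; use a "
                "davidson base or drop ties explicitly"
            )
        if spec.requires_subjects and not data.has_subjects:
            raise DataError(f"model {spec.name!r} needs subject identifiers")
        self.spec = spec
        self.N = data.n_players
        self.S = data.n_subjects or 0
        if spec.is_generalized or spec.has_subject_predictors:
            if spec.is_generalized and player_covariates is None:
                raise UsageError("generalized spec needs player covariates")
            if spec.has_subject_predictors and subject_covariates is None:
                raise UsageError("subjectpredictors spec needs subject covariates")
        self.X = None if player_covariates is None else np.asarray(
            player_covariates, dtype=float)
        self.x_sub = None if subject_covariates is None else np.asarray(
            subject_covariates, dtype=float)
        if spec.is_generalized:
            self.K = self.X.shape[1]
        elif spec.has_subject_predictors:
            self.K = self.x_sub.shape[1]
        else:
            self.K = 0

        # -- block layout ---------------------------------------------------
        self.slices = {}
        pos = 0

        def block(name, size):
            nonlocal pos
            self.slices[name] = slice(pos, pos + size)
            pos += size

        if spec.is_generalized:
            block("beta", self.K)
        else:
            block("lambda", self.N)
        if spec.handles_ties:
            block("nu", 1)
        if spec.has_order_effect:
            block("gamma", 1)
        if spec.has_random_effects:
            block("u_raw", self.N * self.S)
            block("log_u_std", 1)
        if spec.has_subject_predictors:
            block("s_coef", self.N * self.K)
        self.dim = pos

        # -- aggregated data ------------------------------------------------
        n = data.n_contests
        if n:
            i = data.player0_idx()
            j = data.player1_idx()
            s = data.subject_idx()
            if s is None:
                s = np.zeros(n, dtype=np.int64)
            if spec.has_order_effect:
                z = data.order.astype(np.int64) if data.has_order \
                    else np.ones(n, dtype=np.int64)
            else:
                z = np.zeros(n, dtype=np.int64)
            key = np.stack([i, j, s, z, data.result], axis=1)
            uniq, counts = np.unique(key, axis=0, return_counts=True)
            self.i = uniq[:, 0]
            self.j = uniq[:, 1]
            self.s = uniq[:, 2]
            self.z = uniq[:, 3].astype(float)
            self.res = uniq[:, 4]
            self.w = counts.astype(float)
        else:
            self.i = np.zeros(0, dtype=np.int64)
            self.j = np.zeros(0, dtype=np.int64)
            self.s = np.zeros(0, dtype=np.int64)
            self.z = np.zeros(0)
            self.res = np.zeros(0, dtype=np.int64)
            self.w = np.zeros(0)
        self.n_rows = len(self.w)

    # ------------------------------------------------------------------

    def logp_grad(self, x: np.ndarray) -> tuple:
        """Log posterior density (up to a constant) and its gradient."""
        spec = self.spec
        pri = spec.priors
        g = np.zeros_like(x)
        logp = 0.0

        # unpack
        if spec.is_generalized:
            beta = x[self.slices["beta"]]
            base = self.X @ beta
        else:
            lam = x[self.slices["lambda"]]
            base = lam
        nu = x[self.slices["nu"]][0] if spec.handles_ties else 0.0
        gamma = x[self.slices["gamma"]][0] if spec.has_order_effect else 0.0
        if spec.has_random_effects:
            u_raw = x[self.slices["u_raw"]].reshape(self.N, self.S)
            log_u_std = x[self.slices["log_u_std"]][0]
            u_std = math.exp(log_u_std)
            U = u_std * u_raw
        if spec.has_subject_predictors:
            s_coef = x[self.slices["s_coef"]].reshape(self.N, self.K)
            M = self.x_sub @ s_coef.T  # (S, N)

        # likelihood
        if self.n_rows:
            theta0 = base[self.i].astype(float)
            theta1 = base[self.j].astype(float)
            if spec.has_random_effects:
                theta0 = theta0 + U[self.i, self.s]
                theta1 = theta1 + U[self.j, self.s]
            if spec.has_subject_predictors:
                theta0 = theta0 + M[self.s, self.i]
                theta1 = theta1 + M[self.s, self.j]
            sj = theta1 + gamma * self.z

            if spec.handles_ties:
                st = nu + 0.5 * (theta0 + sj)
                scores = np.stack([theta0, sj, st])
                lse = special.logsumexp(scores, axis=0)
                logp += float(
                    self.w @ (scores[self.res, np.arange(self.n_rows)] - lse))
                p = np.exp(scores - lse)
                resid = -p
                resid[self.res, np.arange(self.n_rows)] += 1.0
                resid *= self.w
                g0 = resid[0] + 0.5 * resid[2]
                gsj = resid[1] + 0.5 * resid[2]
                g[self.slices["nu"]] += resid[2].sum()
            else:
                d = theta0 - sj
                sgn = np.where(self.res == 0, 1.0, -1.0)
                logp += float(self.w @ (-np.logaddexp(0.0, -sgn * d)))
                # d/dd log sigma(sgn*d) = sgn * sigma(-sgn*d)
                g_d = self.w * sgn * special.expit(-sgn * d)
                g0 = g_d
                gsj = -g_d

            if spec.has_order_effect:
                g[self.slices["gamma"]] += gsj @ self.z
            g1 = gsj

            # scatter into ability parameters
            if spec.is_generalized:
                gb = self.X[self.i].T @ g0 + self.X[self.j].T @ g1
                g[self.slices["beta"]] += gb
            else:
                glam = np.zeros(self.N)
                np.add.at(glam, self.i, g0)
                np.add.at(glam, self.j, g1)
                g[self.slices["lambda"]] += glam
            if spec.has_random_effects:
                gU = np.zeros((self.N, self.S))
                np.add.at(gU, (self.i, self.s), g0)
                np.add.at(gU, (self.j, self.s), g1)
                g[self.slices["u_raw"]] += (u_std * gU).ravel()
                g[self.slices["log_u_std"]] += u_std * float(
                    np.sum(gU * u_raw))
            if spec.has_subject_predictors:
                gM = np.zeros((self.S, self.N))
                np.add.at(gM, (self.s, self.i), g0)
                np.add.at(gM, (self.s, self.j), g1)
                g[self.slices["s_coef"]] += (gM.T @ self.x_sub).ravel()

        # priors
        def normal_block(name, sd):
            nonlocal logp
            v = x[self.slices[name]]
            logp += float(-0.5 * np.sum((v / sd) ** 2)
                          - v.size * (_LOG_SQRT_2PI + math.log(sd)))
            g[self.slices[name]] += -v / sd**2

        if spec.is_generalized:
            normal_block("beta", pri.beta_sd)
        else:
            normal_block("lambda", pri.lambda_sd)
        if spec.handles_ties:
            normal_block("nu", pri.nu_sd)
        if spec.has_order_effect:
            normal_block("gamma", pri.gamma_sd)
        if spec.has_random_effects:
            normal_block("u_raw", 1.0)
            # half-normal on u_std plus log-Jacobian of u_std = exp(log_u_std)
            logp += (0.5 * math.log(2.0 / math.pi) - math.log(pri.U_sd)
                     - 0.5 * (u_std / pri.U_sd) ** 2 + log_u_std)
            g[self.slices["log_u_std"]] += 1.0 - (u_std / pri.U_sd) ** 2
        if spec.has_subject_predictors:
            normal_block("s_coef", pri.S_sd)

        return logp, g

    def logp(self, x: np.ndarray) -> float:
        return self.logp_grad(x)[0]

    # ------------------------------------------------------------------

    def constrain(self, x: np.ndarray) -> dict:
        """Map one unconstrained vector to named natural parameters."""
        spec = self.spec
        out = {}
        if spec.is_generalized:
            out["beta"] = x[self.slices["beta"]].copy()
        else:
            out["lambda"] = x[self.slices["lambda"]].copy()
        if spec.handles_ties:
            out["nu"] = float(x[self.slices["nu"]][0])
        if spec.has_order_effect:
            out["gamma"] = float(x[self.slices["gamma"]][0])
        if spec.has_random_effects:
            u_std = math.exp(float(x[self.slices["log_u_std"]][0]))
            out["U_std"] = u_std
            out["U"] = u_std * x[self.slices["u_raw"]].reshape(self.N, self.S)
        if spec.has_subject_predictors:
            out["S"] = x[self.slices["s_coef"]].reshape(self.N, self.K)
        return out
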