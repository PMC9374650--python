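"""Posterior summary products: parameter tables, ranks, probabilities,
predictions.

Rank 1 is the highest effective ability in a draw (the most preferred
item); ties within a draw are broken by player index, a probability-zero
event for continuous posteriors.  Probability tables report the posterior
mean of the model's win/tie probabilities across draws; for models with
subject-varying abilities the default "average subject" mode evaluates the
case in which random effects and subject-covariate contributions are zero.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import UsageError
from .inference import PosteriorDraws, effective_sample_size
from .model import bt_win_probability, davidson_probabilities

INTERVAL_KINDS = ("HPD", "equal-tailed")


def hpd_interval(samples, mass: float = 0.95) -> tuple:
    """Highest posterior density interval from draws.

    Among all windows of ``ceil(mass * n)`` consecutive order statistics
    the narrowest one is returned (first such window on ties, i.e. the
    lowest lower bound).  For a unimodal posterior this is the narrowest
    interval containing the requested mass.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if not 0 < mass < 1:
        raise UsageError("mass must lie in (0, 1)")
    m = math.ceil(mass * n)
    if n < m + 1:
        raise UsageError(
            f"need at least ceil(mass*n)+1 = {m + 1} samples, got {n}")
    widths = x[m - 1:] - x[: n - m + 1]
    k = int(np.argmin(widths))
    return float(x[k]), float(x[k + m - 1])


def equal_tailed_interval(samples, mass: float = 0.95) -> tuple:
    tail = (1.0 - mass) / 2.0
    lo, hi = np.quantile(np.asarray(samples, dtype=float), [tail, 1.0 - tail])
    return float(lo), float(hi)


def summarize_parameters(
    draws: PosteriorDraws,
    mass: float = 0.95,
    kind: str = "HPD",
) -> pd.DataFrame:
    """One row per scalar parameter: mean, median, interval bounds, ESS.

    ``kind`` selects HPD or equal-tailed intervals; for a symmetric
    unimodal posterior the two coincide, for skewed posteriors the HPD
    interval is the shorter one.
    """
    if kind not in INTERVAL_KINDS:
        raise UsageError(f"kind must be one of {INTERVAL_KINDS}")
    rows = []
    for name, arr in draws.scalar_draws().items():
        flat = arr.reshape(-1)
        if flat.size == 1:
            lo = hi = float(flat[0])
            ess = float("nan")
        else:
            if kind == "HPD":
                lo, hi = hpd_interval(flat, mass)
            else:
                lo, hi = equal_tailed_interval(flat, mass)
            ess = effective_sample_size(arr) if arr.shape[0] >= 1 else float("nan")
        rows.append({
            "parameter": name,
            "mean": float(flat.mean()),
            "median": float(np.median(flat)),
            f"{kind} lower": lo,
            f"{kind} upper": hi,
            "n_eff": ess,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ranks
# ---------------------------------------------------------------------------


def rank_draws_matrix(ability: np.ndarray) -> np.ndarray:
    """Per-draw ranks (1 = highest ability) from a (draws, N) ability array."""
    order = np.argsort(-ability, axis=1, kind="stable")
    ranks = np.empty_like(order)
    d, n = ability.shape
    rows = np.arange(d)[:, None]
    ranks[rows, order] = np.arange(1, n + 1)
    return ranks


def rank_distribution(
    draws: PosteriorDraws,
    who: Optional[Sequence] = None,
    subject=None,
    average_subjects: bool = False,
    include_frequencies: bool = False,
):
    """Posterior rank table per player: median, mean, sd of rank.

    Ranks are computed within each retained draw over *all* players (so a
    ``who`` subset selects rows without changing the rank scale).  With
    ``include_frequencies`` the player x rank-position frequency matrix is
    returned alongside.
    """
    ability = draws.ability_draws(subject=subject,
                                  average_subjects=average_subjects)
    ranks = rank_draws_matrix(ability)
    players = list(draws.players)
    table = pd.DataFrame({
        "player": players,
        "median_rank": np.median(ranks, axis=0),
        "mean_rank": ranks.mean(axis=0),
        "sd_rank": ranks.std(axis=0, ddof=0),
    })
    if who is not None:
        table = table[table["player"].isin(list(who))].reset_index(drop=True)
    if not include_frequencies:
        return table
    n = len(players)
    freq = np.zeros((n, n))
    for pos in range(1, n + 1):
        freq[:, pos - 1] = (ranks == pos).mean(axis=0)
    freq_df = pd.DataFrame(freq, index=players,
                           columns=[f"rank_{k}" for k in range(1, n + 1)])
    return table, freq_df


# ---------------------------------------------------------------------------
# Probability tables
# ---------------------------------------------------------------------------


def _pair_indices(draws: PosteriorDraws, pairs):
    players = list(draws.players)
    if pairs is None:
        pairs = [(a, b) for a in players for b in players if a != b]
    idx = []
    for a, b in pairs:
        if a not in players or b not in players:
            raise UsageError(f"unknown player in pair ({a!r}, {b!r})")
        idx.append((players.index(a), players.index(b)))
    return pairs, idx


def probability_table(
    draws: PosteriorDraws,
    pairs: Optional[Sequence] = None,
    subject=None,
    conditions: Optional[dict] = None,
    include_intervals: bool = False,
    mass: float = 0.95,
) -> pd.DataFrame:
    """Posterior mean win (and tie) probability for ordered player pairs.

    For subject-varying models the default is the average subject (random
    effects zero); ``conditions`` may set subject-covariate values (on the
    scale the model was fitted with, keyed by covariate name) to probe
    subject-predictor effects, and ``subject`` evaluates one observed
    subject instead.  The odds ratio is P/(1-P) for Bradley-Terry models
    and P(i wins)/P(j wins) for Davidson models.
    """
    spec = draws.spec
    if conditions is not None and not spec.has_subject_predictors:
        raise UsageError("conditions require a subjectpredictors model")
    ability = draws.ability_draws(
        subject=subject,
        average_subjects=spec.subject_varying and subject is None,
    )
    if conditions is not None:
        names = list(draws.covariate_names)
        unknown = set(conditions) - set(names)
        if unknown:
            raise UsageError(f"conditions reference unmodeled covariates: "
                             f"{sorted(unknown)}")
        x = np.array([conditions.get(c, 0.0) for c in names], dtype=float)
        ability = ability + draws.stacked("S") @ x
    pairs, idx = _pair_indices(draws, pairs)
    nu = draws.stacked("nu") if spec.handles_ties else None
    rows = []
    for (a, b), (ia, ib) in zip(pairs, idx):
        ti = ability[:, ia]
        tj = ability[:, ib]
        if spec.handles_ties:
            p_i, p_j, p_tie = davidson_probabilities(ti, tj, nu)
            row = {
                "i": a, "j": b,
                "probability": float(p_i.mean()),
                "tie_probability": float(p_tie.mean()),
                "odds_ratio": float(p_i.mean() / p_j.mean()),
            }
            if include_intervals:
                row["lower"], row["upper"] = hpd_interval(p_i, mass) \
                    if p_i.size > 1 else (row["probability"],) * 2
        else:
            p_i = bt_win_probability(ti, tj)
            pm = float(p_i.mean())
            row = {
                "i": a, "j": b,
                "probability": pm,
                "odds_ratio": pm / (1.0 - pm),
            }
            if include_intervals:
                row["lower"], row["upper"] = hpd_interval(p_i, mass) \
                    if p_i.size > 1 else (pm, pm)
        rows.append(row)
    return pd.DataFrame(rows)


def predict_contests(
    draws: PosteriorDraws,
    newdata,
    n_samples: int = 1000,
    seed: int = 0,
    subject=None,
) -> pd.DataFrame:
    """Sample predicted outcomes for new contests.

    ``newdata`` is a sequence of (player0, player1) pairs or a DataFrame
    with ``player0``/``player1`` columns (and optionally ``subject``).  For
    each requested contest, posterior draws are resampled and an outcome is
    drawn from that draw's win/tie probabilities.  Returns a long DataFrame
    (contest, sample, result) with the usual 0/1/2 coding.
    """
    if isinstance(newdata, pd.DataFrame):
        pairs = list(zip(newdata["player0"], newdata["player1"]))
        subj_col = list(newdata["subject"]) if "subject" in newdata else None
    else:
        pairs = list(newdata)
        subj_col = None
    rng = np.random.default_rng(seed)
    spec = draws.spec
    frames = []
    for c, (a, b) in enumerate(pairs):
        subj = subj_col[c] if subj_col is not None else subject
        ability = draws.ability_draws(
            subject=subj,
            average_subjects=spec.subject_varying and subj is None,
        )
        players = list(draws.players)
        if a not in players or b not in players:
            raise UsageError(f"unknown player in contest ({a!r}, {b!r})")
        ia, ib = players.index(a), players.index(b)
        pick = rng.integers(0, ability.shape[0], size=n_samples)
        ti = ability[pick, ia]
        tj = ability[pick, ib]
        if spec.handles_ties:
            nu = draws.stacked("nu")[pick]
            p_i, p_j, p_tie = davidson_probabilities(ti, tj, nu)
            u = rng.uniform(size=n_samples)
            result = np.where(u < p_i, 0, np.where(u < p_i + p_j, 1, 2))
        else:
            p_i = bt_win_probability(ti, tj)
            result = (rng.uniform(size=n_samples) >= p_i).astype(int)
        frames.append(pd.DataFrame({
            "contest": c, "player0": a, "player1": b,
            "sample": np.arange(n_samples), "result": result,
        }))
    return pd.concat(frames, ignore_index=True)


def plot_abilities(draws: PosteriorDraws, mass: float = 0.95, ax=None):
    """Minimal caterpillar plot of per-player abilities (untested surface)."""
    import matplotlib.pyplot as plt

    ability = draws.ability_draws(
        average_subjects=draws.spec.subject_varying)
    if ax is None:
        _, ax = plt.subplots()
    for k, player in enumerate(draws.players):
        lo, hi = hpd_interval(ability[:, k], mass)
        ax.plot([lo, hi], [k, k], color="C0")
        ax.plot(np.median(ability[:, k]), k, "o", color="C0")
    ax.set_yticks(range(len(draws.players)))
    ax.set_yticklabels(draws.players)
    ax.set_xlabel("log ability")
    return ax
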