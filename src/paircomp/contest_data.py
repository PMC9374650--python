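"""Long-format paired-comparison data: reading, validation, indexing.

A *contest* is one pairwise comparison between two players, optionally made
by an identified subject (judge) and optionally carrying an order indicator
(e.g. whether the second-listed player enjoyed a presentation-position or
home-field condition).  Results are coded ``0`` (player0 wins), ``1``
(player1 wins), ``2`` (tie).  Internally player0 plays the role of "i" in
the win-probability formulas, so result 0 corresponds to "i beats j".
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

RESULT_WIN0 = 0
RESULT_WIN1 = 1
RESULT_TIE = 2
_VALID_RESULTS = (RESULT_WIN0, RESULT_WIN1, RESULT_TIE)


def _first_appearance_index(*label_columns: Sequence) -> tuple:
    """Distinct labels in order of first appearance, scanning rows left to right."""
    seen: dict = {}
    for row in zip(*label_columns):
        for label in row:
            if label not in seen:
                seen[label] = len(seen)
    return tuple(seen)


@dataclass(frozen=True)
class ContestTable:
    """Validated long-format contest records plus player/subject indices.

    Attributes
    ----------
    player0, player1 : tuple of labels, one per contest
    result : int array with codes in {0, 1, 2}
    subject : optional tuple of subject labels (all-or-none across contests)
    order : optional int array in {0, 1}; 1 means the order effect applies
        to that contest (advantage/disadvantage attached to player1)
    players : tuple of distinct player labels in first-appearance order;
        position in the tuple is the 0-based player index
    subjects : optional tuple of distinct subject labels
    """

    player0: tuple
    player1: tuple
    result: np.ndarray
    subject: Optional[tuple] = None
    order: Optional[np.ndarray] = None
    players: tuple = field(default=())
    subjects: Optional[tuple] = None

    @classmethod
    def from_records(
        cls,
        player0: Sequence,
        player1: Sequence,
        result: Sequence[int],
        subject: Optional[Sequence] = None,
        order: Optional[Sequence[int]] = None,
    ) -> "ContestTable":
        player0 = tuple(player0)
        player1 = tuple(player1)
        n = len(player0)
        if len(player1) != n or len(result) != n:
            raise DataError("player0, player1 and result must have equal length")
        result = np.asarray(result, dtype=np.int64)
        for row, code in enumerate(result):
            if code not in _VALID_RESULTS:
                raise DataError(
                    f"row {row + 1}: result {code} is not a valid code (0, 1 or 2)"
                )
        for row, (a, b) in enumerate(zip(player0, player1)):
            if a == b:
                raise DataError(f"row {row + 1}: self-contest ({a!r} vs itself)")

        if subject is not None:
            subject = tuple(subject)
            if len(subject) != n:
                raise DataError("subject column must cover every contest")
            if any(pd.isna(s) for s in subject):
                raise DataError("subject column has missing entries; it must be "
                                "present on all rows or absent entirely")
            subjects = tuple(dict.fromkeys(subject))
        else:
            subjects = None

        if order is not None:
            order_arr = np.asarray(order)
            if len(order_arr) != n:
                raise DataError("order column must cover every contest")
            if pd.isna(order_arr.astype(object)).any():
                raise DataError("order column has missing entries; it must be "
                                "present on all rows or absent entirely")
            order_arr = order_arr.astype(np.int64)
            bad = np.flatnonzero(~np.isin(order_arr, (0, 1)))
            if bad.size:
                raise DataError(f"row {bad[0] + 1}: order indicator must be 0 or 1")
        else:
            order_arr = None

        players = _first_appearance_index(player0, player1)
        return cls(
            player0=player0,
            player1=player1,
            result=result,
            subject=subject,
            order=order_arr,
            players=players,
            subjects=subjects,
        )

    # -- derived views ----------------------------------------------------

    @property
    def n_contests(self) -> int:
        return len(self.player0)

    @property
    def n_players(self) -> int:
        return len(self.players)

    @property
    def n_subjects(self) -> Optional[int]:
        return None if self.subjects is None else len(self.subjects)

    @property
    def has_subjects(self) -> bool:
        return self.subject is not None

    @property
    def has_order(self) -> bool:
        return self.order is not None

    @property
    def has_ties(self) -> bool:
        return bool(np.any(self.result == RESULT_TIE))

    @property
    def n_ties(self) -> int:
        return int(np.sum(self.result == RESULT_TIE))

    def player_index(self, label) -> int:
        try:
            return self.players.index(label)
        except ValueError:
            raise DataError(f"unknown player {label!r}") from None

    def subject_index(self, label) -> int:
        if self.subjects is None:
            raise DataError("table has no subject column")
        try:
            return self.subjects.index(label)
        except ValueError:
            raise DataError(f"unknown subject {label!r}") from None

    def player0_idx(self) -> np.ndarray:
        lut = {p: k for k, p in enumerate(self.players)}
        return np.fromiter((lut[p] for p in self.player0), dtype=np.int64,
                           count=self.n_contests)

    def player1_idx(self) -> np.ndarray:
        lut = {p: k for k, p in enumerate(self.players)}
        return np.fromiter((lut[p] for p in self.player1), dtype=np.int64,
                           count=self.n_contests)

    def subject_idx(self) -> Optional[np.ndarray]:
        if self.subject is None:
            return None
        lut = {s: k for k, s in enumerate(self.subjects)}
        return np.fromiter((lut[s] for s in self.subject), dtype=np.int64,
                           count=self.n_contests)

    # -- transformations ---------------------------------------------------

    def drop_ties(self) -> tuple["ContestTable", int]:
        """Remove tie rows; returns (new table, number of rows removed).

        The player index of the original table is preserved so players that
        only ever tied remain in the model.
        """
        keep = self.result != RESULT_TIE
        dropped = int((~keep).sum())
        if dropped == 0:
            return self, 0
        sel = np.flatnonzero(keep)
        new = ContestTable(
            player0=tuple(self.player0[k] for k in sel),
            player1=tuple(self.player1[k] for k in sel),
            result=self.result[sel],
            subject=None if self.subject is None
            else tuple(self.subject[k] for k in sel),
            order=None if self.order is None else self.order[sel],
            players=self.players,
            subjects=self.subjects,
        )
        return new, dropped

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        data = {
            "player0": list(self.player0),
            "player1": list(self.player1),
            "result": self.result,
        }
        if self.subject is not None:
            data["subject"] = list(self.subject)
        if self.order is not None:
            data["order"] = self.order
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def fingerprint(self) -> str:
        """SHA-256 of the canonical CSV serialization (data identity)."""
        payload = self.to_frame().to_csv(index=False).encode()
        return hashlib.sha256(payload).hexdigest()

    def __eq__(self, other) -> bool:
        if not isinstance(other, ContestTable):
            return NotImplemented
        return (
            self.player0 == other.player0
            and self.player1 == other.player1
            and np.array_equal(self.result, other.result)
            and self.subject == other.subject
            and (
                (self.order is None) == (other.order is None)
                and (self.order is None or np.array_equal(self.order, other.order))
            )
            and self.players == other.players
            and self.subjects == other.subjects
        )


def read_contest_table(
    path,
    player0_col: str = "player0",
    player1_col: str = "player1",
    result_col: str = "result",
    subject_col: Optional[str] = None,
    order_col: Optional[str] = None,
) -> ContestTable:
    """Read a delimited text file (CSV/TSV, sniffed) into a ContestTable.

    Raises
    ------
    ConfigurationError
        if a named column is missing from the header.
    DataError
        if a result code is outside {0, 1, 2}, a row is a self-contest, or
        an optional column is present on only some rows.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    wanted = [player0_col, player1_col, result_col]
    if subject_col is not None:
        wanted.append(subject_col)
    if order_col is not None:
        wanted.append(order_col)
    for col in wanted:
        if col not in df.columns:
            raise ConfigurationError(
                f"column {col!r} not found in {path} (header: {list(df.columns)})"
            )
    res_raw = df[result_col]
    if res_raw.isna().any():
        row = int(res_raw.isna().idxmax()) + 1
        raise DataError(f"row {row}: missing result")
    try:
        result = res_raw.astype(np.int64)
    except (TypeError, ValueError) as exc:
        raise DataError(f"result column is not integer-coded: {exc}") from exc
    if (result != res_raw.astype(float)).any():
        raise DataError("result column contains non-integer values")
    return ContestTable.from_records(
        player0=df[player0_col],
        player1=df[player1_col],
        result=result,
        subject=None if subject_col is None else df[subject_col].where(
            df[subject_col].notna(), None),
        order=None if order_col is None else df[order_col],
    )


def results_from_scores(score0, score1, allow_ties: bool = False) -> np.ndarray:
    """Convert per-contest numeric scores to result codes.

    The higher score wins (0 if score0 is larger, 1 if score1 is larger);
    equal scores become a tie (code 2) when ``allow_ties`` is set and a
    DataError naming the first offending row otherwise.
    """
    s0 = np.asarray(score0, dtype=float)
    s1 = np.asarray(score1, dtype=float)
    if s0.shape != s1.shape:
        raise DataError("score vectors must have equal length")
    if not (np.all(np.isfinite(s0)) and np.all(np.isfinite(s1))):
        raise DataError("scores must be finite")
    result = np.where(s0 > s1, RESULT_WIN0, RESULT_WIN1).astype(np.int64)
    equal = s0 == s1
    if equal.any():
        if not allow_ties:
            row = int(np.flatnonzero(equal)[0]) + 1
            raise DataError(f"row {row}: equal scores but allow_ties is false")
        result[equal] = RESULT_TIE
    return result


# ---------------------------------------------------------------------------
# Covariate tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateTable:
    """A numeric covariate matrix keyed by player or subject label.

    ``transform`` records any standardization already applied (per-column
    mean and sd) so reported coefficients can be mapped back to the raw
    covariate scale.
    """

    frame: pd.DataFrame
    transform: Optional[pd.DataFrame] = None

    def __post_init__(self):
        values = self.frame.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise DataError("covariate columns must be numeric")
        if values.size and not np.all(np.isfinite(values)):
            raise DataError("covariate table has missing or non-finite entries")

    @property
    def labels(self) -> tuple:
        return tuple(self.frame.index)

    @property
    def columns(self) -> tuple:
        return tuple(self.frame.columns)

    @property
    def n_covariates(self) -> int:
        return self.frame.shape[1]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.frame.mean(axis=0), "sd": self.frame.std(axis=0, ddof=0)}
        )

    def matrix(self, labels: Sequence) -> np.ndarray:
        """Rows aligned to ``labels`` (a player/subject index order)."""
        missing = [lab for lab in labels if lab not in self.frame.index]
        if missing:
            raise DataError(f"covariate table missing rows for {missing}")
        return self.frame.loc[list(labels)].to_numpy(dtype=float)

    def is_standardized(self, tol: float = 1e-8) -> bool:
        s = self.summary()
        return bool(
            np.all(np.abs(s["mean"].to_numpy()) < tol)
            and np.all(np.abs(s["sd"].to_numpy() - 1.0) < tol)
        )


class PlayerCovariates(CovariateTable):
    """Covariates X with one row per player (generalized models)."""


class SubjectCovariates(CovariateTable):
    """Covariates x with one row per subject (subject-predictor models)."""


def read_covariates(path, index_col, kind: type = CovariateTable) -> CovariateTable:
    df = pd.read_csv(path, sep=None, engine="python")
    if index_col not in df.columns:
        raise ConfigurationError(f"column {index_col!r} not found in {path}")
    df = df.set_index(index_col)
    return kind(frame=df)


def standardize_covariates(table: CovariateTable) -> CovariateTable:
    """Scale every column to mean 0, sd 1 (population sd).

    The applied per-column (mean, sd) is recorded in ``transform`` so users
    can back-transform fitted coefficients.  Constant columns are rejected.
    """
    frame = table.frame
    means = frame.mean(axis=0)
    sds = frame.std(axis=0, ddof=0)
    for col, sd in sds.items():
        if sd == 0:
            raise DataError(f"covariate column {col!r} is constant (zero variance)")
    standardized = (frame - means) / sds
    transform = pd.DataFrame({"mean": means, "sd": sds})
    return type(table)(frame=standardized, transform=transform)
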