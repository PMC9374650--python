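"""On-disk fit bundles: a versioned directory with everything needed to
reproduce and post-process one model fit.

Layout::

    <outdir>/
      manifest.json            run configuration, seed, labels, version
      data/contests.csv        canonical contest table
      data/player_covariates.csv, subject_covariates.csv   (when used)
      draws/draws.csv          chain, iteration, parameter, value
      draws/sampler_stats.csv  chain, iteration, divergent, treedepth, ...
      diagnostics/report.txt, diagnostics.json
      tables/                  summary products written by the table commands
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .contest_data import (
    ContestTable,
    CovariateTable,
    PlayerCovariates,
    SubjectCovariates,
    read_contest_table,
)
from .errors import UsageError
from .inference import (
    ConvergenceDiagnostics,
    PosteriorDraws,
    SamplerConfig,
    check_convergence_diagnostics,
)
from .model import ModelSpec, PriorConfig


def save_bundle(
    outdir,
    draws: PosteriorDraws,
    data: ContestTable,
    diagnostics: Optional[ConvergenceDiagnostics] = None,
    player_covariates: Optional[CovariateTable] = None,
    subject_covariates: Optional[CovariateTable] = None,
) -> Path:
    out = Path(outdir)
    for sub in ("data", "draws", "diagnostics", "tables"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    data.to_csv(out / "data" / "contests.csv")
    if player_covariates is not None:
        player_covariates.frame.to_csv(out / "data" / "player_covariates.csv",
                                       index_label="player")
    if subject_covariates is not None:
        subject_covariates.frame.to_csv(out / "data" / "subject_covariates.csv",
                                        index_label="subject")

    draws.to_dataframe().to_csv(out / "draws" / "draws.csv", index=False)
    draws.stats_dataframe().to_csv(out / "draws" / "sampler_stats.csv",
                                   index=False)

    if diagnostics is None:
        diagnostics = check_convergence_diagnostics(draws)
    (out / "diagnostics" / "report.txt").write_text(diagnostics.to_text() + "\n")
    (out / "diagnostics" / "diagnostics.json").write_text(
        json.dumps(diagnostics.to_dict(), indent=2) + "\n")

    spec = draws.spec
    manifest = {
        "paircomp_version": __version__,
        "model": spec.name,
        "priors": spec.priors.to_dict(),
        "sampler": draws.config.to_dict() if draws.config else None,
        "players": list(draws.players),
        "subjects": None if draws.subjects is None else list(draws.subjects),
        "covariate_names": None if draws.covariate_names is None
        else list(draws.covariate_names),
        "has_subject_column": data.has_subjects,
        "has_order_column": data.has_order,
        "data_fingerprint": draws.data_fingerprint,
        "diagnostics_passed": diagnostics.passed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out


def _blocks_from_long(df: pd.DataFrame, spec: ModelSpec, players, subjects,
                      covariate_names) -> dict:
    chains = int(df["chain"].max()) + 1
    n_draw = int(df["iteration"].max()) + 1
    wide = df.pivot_table(index=["chain", "iteration"], columns="parameter",
                          values="value", sort=False)

    def grab(label):
        col = wide[label].to_numpy()
        return col.reshape(chains, n_draw)

    blocks = {}
    if spec.is_generalized:
        blocks["beta"] = np.stack(
            [grab(f"beta[{c}]") for c in covariate_names], axis=-1)
    else:
        blocks["lambda"] = np.stack(
            [grab(f"lambda[{p}]") for p in players], axis=-1)
    if spec.handles_ties:
        blocks["nu"] = grab("nu")
    if spec.has_order_effect:
        blocks["gamma"] = grab("gamma")
    if spec.has_random_effects:
        blocks["U_std"] = grab("U_std")
        u = np.stack(
            [np.stack([grab(f"U[{p},{s}]") for s in subjects], axis=-1)
             for p in players], axis=-2)
        blocks["U"] = u
    if spec.has_subject_predictors:
        blocks["S"] = np.stack(
            [np.stack([grab(f"S[{p},{c}]") for c in covariate_names], axis=-1)
             for p in players], axis=-2)
    return blocks


def load_bundle(bundle_dir) -> tuple:
    """Load (draws, data, player_covariates, subject_covariates)."""
    path = Path(bundle_dir)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise UsageError(f"{bundle_dir} is not a fit bundle (no manifest.json)")
    manifest = json.loads(manifest_path.read_text())

    spec = ModelSpec.from_string(
        manifest["model"], priors=PriorConfig(**manifest["priors"]))
    data = read_contest_table(
        path / "data" / "contests.csv",
        subject_col="subject" if manifest["has_subject_column"] else None,
        order_col="order" if manifest["has_order_column"] else None,
    )
    player_cov = None
    subject_cov = None
    X = None
    x_sub = None
    pc_path = path / "data" / "player_covariates.csv"
    if pc_path.exists():
        player_cov = PlayerCovariates(
            pd.read_csv(pc_path).set_index("player"))
        X = player_cov.matrix(data.players)
    sc_path = path / "data" / "subject_covariates.csv"
    if sc_path.exists():
        subject_cov = SubjectCovariates(
            pd.read_csv(sc_path).set_index("subject"))
        x_sub = subject_cov.matrix(data.subjects)

    spec = spec.bind(data, player_cov, subject_cov)
    long_df = pd.read_csv(path / "draws" / "draws.csv")
    players = tuple(manifest["players"])
    subjects = None if manifest["subjects"] is None \
        else tuple(manifest["subjects"])
    cov_names = None if manifest["covariate_names"] is None \
        else tuple(manifest["covariate_names"])
    blocks = _blocks_from_long(long_df, spec, players, subjects, cov_names)

    stats_df = pd.read_csv(path / "draws" / "sampler_stats.csv")
    chains = int(stats_df["chain"].max()) + 1
    n_draw = int(stats_df["iteration"].max()) + 1

    def stat(col, dtype=float):
        return stats_df[col].to_numpy().reshape(chains, n_draw).astype(dtype)

    stats = {
        "divergent": stat("divergent", bool),
        "treedepth": stat("treedepth", np.int64),
        "energy": stat("energy"),
        "accept_stat": stat("accept_stat"),
    }
    config = None
    if manifest.get("sampler"):
        config = SamplerConfig(**manifest["sampler"])
    draws = PosteriorDraws(
        spec=spec, params=blocks, stats=stats, players=players,
        subjects=subjects, covariate_names=cov_names,
        player_covariate_matrix=X, subject_covariate_matrix=x_sub,
        data_fingerprint=manifest.get("data_fingerprint"), config=config)
    return draws, data, player_cov, subject_cov
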