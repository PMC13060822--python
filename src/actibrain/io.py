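"""Shared plumbing: table IO, configuration, manifests, orchestration.

Participant alignment is always by explicit identifier join (the first
column of every table), never by row order: the analytic samples of
different blocks can differ, and complete-case analysis is the
intersection of identifiers present in every block of a given stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from actibrain import __version__ as _version

__all__ = [
    "AnalysisConfig",
    "RunManifest",
    "align_blocks",
    "read_table",
    "run_pipeline",
    "write_table",
]


def read_table(path, required_columns=None) -> pd.DataFrame:
    """Read a TSV/CSV table indexed by participant identifier.

    The first column is the identifier; duplicates raise, as does any
    required column missing from the header.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate participant ids in {path.name}: {dupes}")
    if required_columns is not None:
        missing = set(required_columns) - set(df.columns)
        if missing:
            raise ValueError(
                f"{path.name} is missing required column(s): {sorted(missing)}"
            )
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep)
    return path


def align_blocks(*frames: pd.DataFrame) -> list[pd.DataFrame]:
    """Complete-case join: restrict every frame to the common ids, drop NaNs.

    Participants with a missing value in any variable of any supplied
    block are removed (complete-case analysis), then all frames are
    reindexed to the shared sorted identifier set.
    """
    ids = None
    for f in frames:
        ok = f.dropna().index
        ids = ok if ids is None else ids.intersection(ok)
    ids = ids.sort_values()
    if len(ids) == 0:
        raise ValueError("no participants with complete data in all blocks")
    return [f.loc[ids] for f in frames]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record emitted for every pipeline invocation."""

    config: dict
    version: str = _version
    seeds: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)  # stage -> {files, sha256, seconds}

    def record(self, stage: str, out_files: list, seconds: float) -> None:
        self.stages[stage] = {
            "files": [str(f) for f in out_files],
            "sha256": {Path(f).name: _sha256(Path(f)) for f in out_files},
            "seconds": round(seconds, 3),
        }

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
        return path


@dataclass
class AnalysisConfig:
    """Pipeline configuration (YAML- or flag-driven).

    Paths may point at an existing cohort directory or be absent when the
    simulate stage generates one.  Defaults mirror the study design:
    correlation-scale CCA with 999 permutations, BH at 0.05, 10-fold CV
    repeated 100 times, 90% IDP variance retained for risk models.
    """

    cohort_dir: str | None = None
    out_dir: str = "actibrain_out"
    idp_block: str = "fc"
    n_participants: int = 2000
    n_fc_nodes: int = 55
    n_gmv: int = 139
    standardize_cca: bool = True
    n_permutations: int = 999
    alpha: float = 0.05
    importance_reps: int = 20
    n_trees: int = 100
    risk_folds: int = 10
    risk_reps: int = 20
    idp_variance: float = 0.9
    diseases: list = field(
        default_factory=lambda: ["diabetes", "stroke", "chd", "cancer"]
    )
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def run_pipeline(config: AnalysisConfig) -> RunManifest:
    """Execute simulate -> cca -> importance -> predict-risk in order.

    Each stage writes its outputs under ``config.out_dir`` and is recorded
    (files, checksums, wall-clock) in the returned manifest; stages are
    independently re-runnable from the written intermediates.
    """
    from actibrain.cca import BipartialCCA
    from actibrain.mass_univariate import MassUnivariateScreen, consensus_ranking
    from actibrain.risk import run_disease_panel
    from actibrain.synthetic import CohortConfig, generate_cohort, read_cohort, write_cohort

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), seeds={"master": config.seed})

    # stage: cohort
    t0 = time.perf_counter()
    if config.cohort_dir is None:
        cohort = generate_cohort(
            CohortConfig(
                n_participants=config.n_participants,
                n_fc_nodes=config.n_fc_nodes,
                n_gmv=config.n_gmv,
                seed=config.seed,
            )
        )
        cohort_dir = write_cohort(cohort, out / "cohort")
        data = read_cohort(cohort_dir)
    else:
        cohort_dir = Path(config.cohort_dir)
        if not cohort_dir.exists():
            raise FileNotFoundError(
                f"stage 'cohort': directory {cohort_dir} does not exist"
            )
        data = read_cohort(cohort_dir)
    manifest.record(
        "cohort",
        sorted(p for p in Path(cohort_dir).glob("*.tsv")),
        time.perf_counter() - t0,
    )

    idp = data[config.idp_block]
    conf_idp = data["confounders"][config.idp_block]
    conf_pa = data["confounders"]["pa"]
    pa, idp, conf_pa, conf_idp, disease = align_blocks(
        data["pa"], idp, conf_pa, conf_idp, data["disease"]
    )

    # stage: cca
    t0 = time.perf_counter()
    cca = BipartialCCA(scale=config.standardize_cca).fit(
        pa.to_numpy(),
        idp.to_numpy(),
        confounders_x=conf_pa.to_numpy(),
        confounders_y=conf_idp.to_numpy(),
    )
    approx = cca.approximation_test()
    perm = cca.permutation_test(config.n_permutations, seed=config.seed)
    cca_dir = out / "cca"
    cca_dir.mkdir(exist_ok=True)
    write_table(
        pd.DataFrame({"rho": cca.rho_}, index=range(1, cca.rho_.size + 1)),
        cca_dir / "rho.tsv",
    )
    write_table(
        pd.DataFrame(cca.x_weights_, index=pa.columns), cca_dir / "pa_coefficients.tsv"
    )
    write_table(
        pd.DataFrame(cca.y_weights_, index=idp.columns), cca_dir / "idp_coefficients.tsv"
    )
    write_table(
        pd.DataFrame(
            np.column_stack([cca.x_scores_[:, 0], cca.y_scores_[:, 0]]),
            index=pa.index,
            columns=["U1", "V1"],
        ),
        cca_dir / "variates.tsv",
    )
    write_table(
        pd.DataFrame(
            {
                "varexp_pa": cca.variance_explained("x"),
                "varexp_idp": cca.variance_explained("y"),
            },
            index=range(1, cca.rho_.size + 1),
        ),
        cca_dir / "varexp.tsv",
    )
    write_table(
        pd.DataFrame(
            {"cross_loading_primary": cca.cross_loadings("x", 0)}, index=pa.columns
        ),
        cca_dir / "loadings.tsv",
    )
    tests = {
        "approximation_p": approx.p_values.tolist(),
        "permutation_p": perm.p_values.tolist(),
        "n_permutations": config.n_permutations,
        "seed": config.seed,
        "caveat": "permutation inference beyond the primary mode may violate "
        "exchangeability after residualization",
    }
    with open(cca_dir / "tests.json", "w") as fh:
        json.dump(tests, fh, indent=2)
    manifest.record(
        "cca", sorted(cca_dir.glob("*.tsv")) + [cca_dir / "tests.json"],
        time.perf_counter() - t0,
    )

    # stage: importance
    t0 = time.perf_counter()
    screen = MassUnivariateScreen(
        alpha=config.alpha, n_reps=config.importance_reps, seed=config.seed
    ).fit(idp.to_numpy(), confounders=conf_idp.to_numpy(), pa=pa.to_numpy())
    imp_dir = out / "importance"
    imp_dir.mkdir(exist_ok=True)
    write_table(
        pd.DataFrame(
            {
                "p_value": screen.result_.p_values,
                "p_adjusted": screen.result_.p_adjusted,
            },
            index=idp.columns,
        ),
        imp_dir / "pvalues.tsv",
    )
    (imp_dir / "jset.txt").write_text(
        "\n".join(idp.columns[screen.selected_]) + "\n"
    )
    cv = screen.cv_correlations()
    write_table(
        pd.DataFrame(
            {"mean_cv_correlation": cv}, index=idp.columns[screen.selected_]
        ),
        imp_dir / "cvcorr.tsv",
    )
    pa_names = list(pa.columns)
    tables = []
    for method, fname in (
        ("ttest", "importance_ttest.tsv"),
        ("stepwise_bic", "importance_bic.tsv"),
        ("random_forest", "importance_rf.tsv"),
    ):
        tab = screen.importance(method, pa_names=pa_names, n_trees=config.n_trees)
        tab.scores.index = idp.columns[
            np.asarray(tab.scores.index, dtype=int)
        ]
        write_table(tab.scores, imp_dir / fname)
        tables.append(tab)
    write_table(consensus_ranking(tables), imp_dir / "consensus_ranking.tsv")
    manifest.record(
        "importance", sorted(imp_dir.glob("*.tsv")), time.perf_counter() - t0
    )

    # stage: predict-risk
    t0 = time.perf_counter()
    panel = run_disease_panel(
        disease[config.diseases],
        conf_pa.to_numpy(),
        pa.to_numpy(),
        idp.to_numpy(),
        n_folds=config.risk_folds,
        n_reps=config.risk_reps,
        idp_variance=config.idp_variance,
        seed=config.seed,
    )
    risk_dir = out / "risk"
    risk_dir.mkdir(exist_ok=True)
    auc_rows, mcf_rows = [], []
    for name, res in panel.items():
        for m in res.auc:
            write_table(
                pd.DataFrame(
                    {"fpr": res.fpr_grid, "mean_tpr": res.mean_tpr[m]}
                ).set_index("fpr"),
                risk_dir / f"roc_{m}_{name}.tsv",
            )
        auc_rows.append(pd.Series(res.auc, name=name))
        mcf_rows.append(pd.Series(res.mcfadden, name=name))
    write_table(pd.DataFrame(auc_rows), risk_dir / "auc.tsv")
    write_table(pd.DataFrame(mcf_rows), risk_dir / "mcfadden.tsv")
    with open(risk_dir / "panel.json", "w") as fh:
        json.dump({k: v.to_dict() for k, v in panel.items()}, fh, indent=2)
    manifest.record(
        "risk",
        [risk_dir / "auc.tsv", risk_dir / "mcfadden.tsv", risk_dir / "panel.json"],
        time.perf_counter() - t0,
    )

    manifest.write(out / "manifest.json")
    return manifest
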