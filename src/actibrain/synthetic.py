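"""Synthetic cohorts with planted canonical structure and disease risk.

Real accelerometer + imaging cohorts of this kind are access-restricted, so
every analysis stage here is validated against synthetic cohorts whose
ground truth is known by construction:

* A linear Gaussian factor model links the physical-activity (PA) block to
  each image-derived-phenotype (IDP) block.  Each latent factor loads one
  unit-norm direction per block, with loading scales solved so that the
  population canonical correlation of that mode equals a requested target
  (the estimand of CCA depends on second moments only, so a Gaussian
  factor model gives the population canonical correlations in closed
  form).
* Confounders (a binary sex-like column plus continuous age-like and
  motion-like columns) affect every block linearly but are generated
  independently of the latents, so residualization leaves planted
  correlations intact.
* Functional-connectivity netmats are built by embedding Gaussian edge
  signals ``z`` into a symmetric matrix as ``tanh(c z)`` with unit
  diagonal: entries always lie in (-1, 1), and the Fisher-z vectorized
  edge table equals ``c z`` exactly — linear in the planted signal.
* Gray-matter volumes are positive by construction (exponential of a
  small-variance Gaussian field).
* Binary disease outcomes follow a logistic model over standardized
  confounder/PA/IDP columns, with the intercept solved numerically to hit
  a target prevalence (the study diseases are rare: diabetes 4.5%, stroke
  2.3%, CHD 3.3%, cancer 12.5%).

No attempt is made to match the marginal distributions of real PA or IDP
variables; the generator reproduces the second-order and outcome structure
the analysis methods assume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from actibrain.cca import _inv_sqrt
from actibrain.features import PA_COLUMNS
from actibrain.preprocess import unvectorize_netmat

__all__ = [
    "CohortConfig",
    "DiseaseSpec",
    "LatentFactor",
    "SyntheticCohort",
    "generate_cohort",
    "generate_disease",
    "population_canonical_correlations",
    "read_cohort",
    "write_cohort",
]

CONFOUNDER_NAMES = ["sex", "age", "motion"]

# presentation scales for the 11 PA columns (mean, sd); the map from the
# Gaussian core is affine per column, so canonical structure is unchanged
_PA_SCALE = {
    "TLAC": (2400.0, 600.0),
    "LIPA": (300.0, 90.0),
    "MVPA": (35.0, 25.0),
    "SBout": (20.0, 8.0),
    "ABout": (10.0, 4.0),
    "SATP": (0.25, 0.07),
    "ASTP": (0.35, 0.10),
    "DARE": (0.70, 0.08),
    "M10": (2.8, 0.6),
    "L5": (0.6, 0.3),
    "RA": (0.65, 0.12),
}
_FC_EDGE_SCALE = 0.15  # netmat entry = tanh(scale * edge signal)
_GMV_LOG_SD = 0.08  # lognormal field sd; small so correlations carry over


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


@dataclass
class LatentFactor:
    """One shared latent factor between the PA block and an IDP block.

    Parameters
    ----------
    rho : float in [0, 1)
        Target population canonical correlation of this mode.
    pa_weights, idp_weights : array-like or None
        Loading directions (normalized internally; orthogonalized in order
        against earlier factors).  ``None`` draws a random direction.
    """

    rho: float
    pa_weights: np.ndarray | None = None
    idp_weights: np.ndarray | None = None

    def validate(self, n_pa: int, n_idp: int, where: str) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ConfigurationError(
                f"{where}: rho must lie in [0, 1), got {self.rho}"
            )
        for name, w, dim in (
            ("pa_weights", self.pa_weights, n_pa),
            ("idp_weights", self.idp_weights, n_idp),
        ):
            if w is not None and np.asarray(w).shape != (dim,):
                raise ConfigurationError(
                    f"{where}.{name}: expected length {dim}, "
                    f"got shape {np.asarray(w).shape}"
                )


@dataclass
class DiseaseSpec:
    """Logistic disease-generating model for one outcome.

    The linear predictor runs over standardized confounder, PA and
    (optionally) IDP columns; the intercept is solved numerically so the
    analytic prevalence matches ``prevalence``.
    """

    name: str
    prevalence: float
    coef_confounders: np.ndarray | None = None
    coef_pa: np.ndarray | None = None
    coef_idp: np.ndarray | None = None
    idp_block: str = "fc"

    def validate(self, n_conf: int, n_pa: int, n_idp: dict) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError(
                f"disease {self.name}: prevalence must lie in (0, 1)"
            )
        if self.idp_block not in ("fc", "gmv"):
            raise ConfigurationError(
                f"disease {self.name}: idp_block must be 'fc' or 'gmv'"
            )
        for name, w, dim in (
            ("coef_confounders", self.coef_confounders, n_conf),
            ("coef_pa", self.coef_pa, n_pa),
            ("coef_idp", self.coef_idp, n_idp[self.idp_block]),
        ):
            if w is not None and np.asarray(w).shape != (dim,):
                raise ConfigurationError(
                    f"disease {self.name}.{name}: expected length {dim}"
                )


def _default_diseases() -> list[DiseaseSpec]:
    """Study-condition defaults: rare outcomes driven by confounders + PA.

    Higher activity lowers risk (negative loadings on volume/intensity
    columns TLAC/MVPA/M10, positive on sedentary ones); cancer is only
    weakly related to PA.
    """
    base_conf = np.array([0.2, 0.5, 0.0])

    def pa(**kw):
        v = np.zeros(len(PA_COLUMNS))
        for k, val in kw.items():
            v[PA_COLUMNS.index(k)] = val
        return v

    return [
        DiseaseSpec("diabetes", 0.045, base_conf,
                    pa(TLAC=-0.45, MVPA=-0.25, SBout=0.20)),
        DiseaseSpec("stroke", 0.023, base_conf,
                    pa(TLAC=-0.25, M10=-0.15, SBout=0.10)),
        DiseaseSpec("chd", 0.033, base_conf,
                    pa(TLAC=-0.50, MVPA=-0.30, SBout=0.20)),
        DiseaseSpec("cancer", 0.125, base_conf, pa(TLAC=-0.08)),
    ]


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    Parameters
    ----------
    n_participants : int
    n_pa : int
        PA block width (default 11, the canonical feature set).
    n_fc_nodes : int
        Netmat dimension (default 55, giving 1485 edges).
    n_gmv : int
        Number of regional volumes (default 139).
    n_confounders_per_block : int
        Up to 3: sex-like binary, age-like and motion-like continuous.
    latent_fc, latent_gmv : list of LatentFactor
        Shared factors between PA and each IDP block.  Defaults plant one
        factor per block with population canonical correlations 0.50 (FC)
        and 0.19 (GMV).
    noise_scales : dict
        Strictly positive per-block noise standard deviations.
    confounder_strength : float
        Scale of the random confounder effect matrices.
    diseases : list of DiseaseSpec
    seed : int
    """

    n_participants: int
    n_pa: int = 11
    n_fc_nodes: int = 55
    n_gmv: int = 139
    n_confounders_per_block: int = 3
    latent_fc: list[LatentFactor] = field(
        default_factory=lambda: [LatentFactor(0.50)]
    )
    latent_gmv: list[LatentFactor] = field(
        default_factory=lambda: [LatentFactor(0.19)]
    )
    noise_scales: dict = field(
        default_factory=lambda: {"pa": 1.0, "fc": 1.0, "gmv": 1.0}
    )
    confounder_strength: float = 0.5
    diseases: list[DiseaseSpec] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.diseases is None:
            self.diseases = _default_diseases()
            if self.n_pa != len(PA_COLUMNS):
                for d in self.diseases:
                    d.coef_pa = None  # default PA loadings target 11 columns

    @property
    def n_fc_edges(self) -> int:
        return self.n_fc_nodes * (self.n_fc_nodes - 1) // 2

    def validate(self) -> None:
        for name, val, lo in (
            ("n_participants", self.n_participants, 1),
            ("n_pa", self.n_pa, 1),
            ("n_fc_nodes", self.n_fc_nodes, 2),
            ("n_gmv", self.n_gmv, 1),
            ("n_confounders_per_block", self.n_confounders_per_block, 0),
        ):
            if not isinstance(val, (int, np.integer)) or val < lo:
                raise ConfigurationError(f"{name} must be an integer >= {lo}")
        if self.n_confounders_per_block > len(CONFOUNDER_NAMES):
            raise ConfigurationError(
                f"n_confounders_per_block must be <= {len(CONFOUNDER_NAMES)}"
            )
        for key in ("pa", "fc", "gmv"):
            if key not in self.noise_scales or self.noise_scales[key] <= 0:
                raise ConfigurationError(
                    f"noise_scales['{key}'] must be strictly positive"
                )
        for i, f in enumerate(self.latent_fc):
            f.validate(self.n_pa, self.n_fc_edges, f"latent_fc[{i}]")
        for i, f in enumerate(self.latent_gmv):
            f.validate(self.n_pa, self.n_gmv, f"latent_gmv[{i}]")
        n_idp = {"fc": self.n_fc_edges, "gmv": self.n_gmv}
        for d in self.diseases:
            d.validate(self.n_confounders_per_block, self.n_pa, n_idp)


@dataclass
class SyntheticCohort:
    """A generated cohort plus its generating ground truth."""

    config: CohortConfig
    confounders: dict  # block -> DataFrame (pa / fc / gmv)
    pa: pd.DataFrame
    fc_edges: pd.DataFrame
    gmv: pd.DataFrame
    disease: pd.DataFrame
    ground_truth: dict

    @property
    def participant_ids(self) -> pd.Index:
        return self.pa.index

    def netmat(self, i: int) -> np.ndarray:
        """Symmetric unit-diagonal netmat of participant ``i``.

        Built from the stored Fisher-z edge values; vectorizing it
        recovers the stored edges exactly.
        """
        return unvectorize_netmat(self.fc_edges.to_numpy()[i])


# ----------------------------------------------------------------------
# structure resolution (deterministic given config)
# ----------------------------------------------------------------------


def _orthonormal_directions(dim, factors, attr, rng):
    """In-order orthonormalized loading directions (dim x m).

    User-supplied directions keep their leading components (Gram-Schmidt
    in list order); missing ones are drawn isotropically.
    """
    cols = []
    for f in factors:
        w = getattr(f, attr)
        w = rng.standard_normal(dim) if w is None else np.asarray(w, float).copy()
        for prev in cols:
            w = w - (w @ prev) * prev
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            raise ConfigurationError(
                "latent loading directions are collinear after orthogonalization"
            )
        cols.append(w / norm)
    return np.column_stack(cols) if cols else np.zeros((dim, 0))


@dataclass
class _Structure:
    U_pa: np.ndarray  # n_pa x (m_fc + m_gmv), PA-side directions
    W_fc: np.ndarray  # n_fc_edges x m_fc
    W_gmv: np.ndarray  # n_gmv x m_gmv
    h_pa: np.ndarray  # PA-side loading scales (all factors, fc then gmv)
    h_fc: np.ndarray
    h_gmv: np.ndarray
    B_conf: dict  # block -> (n_conf, q) confounder effect matrix
    gmv_ref: np.ndarray


def _loading_scale(rho: float, sigma: float) -> float:
    # per-side communality rho => mode canonical correlation rho
    return sigma * np.sqrt(rho / (1.0 - rho))


def _resolve_structure(config: CohortConfig) -> _Structure:
    config.validate()
    ss = np.random.SeedSequence([config.seed, 2026])
    rng = np.random.default_rng(ss)
    s_pa = config.noise_scales["pa"]
    s_fc = config.noise_scales["fc"]
    s_gmv = config.noise_scales["gmv"]

    all_factors = list(config.latent_fc) + list(config.latent_gmv)
    U_pa = _orthonormal_directions(config.n_pa, all_factors, "pa_weights", rng)
    W_fc = _orthonormal_directions(
        config.n_fc_edges, config.latent_fc, "idp_weights", rng
    )
    W_gmv = _orthonormal_directions(
        config.n_gmv, config.latent_gmv, "idp_weights", rng
    )
    h_pa = np.array([_loading_scale(f.rho, s_pa) for f in all_factors])
    h_fc = np.array([_loading_scale(f.rho, s_fc) for f in config.latent_fc])
    h_gmv = np.array([_loading_scale(f.rho, s_gmv) for f in config.latent_gmv])

    p_conf = config.n_confounders_per_block
    B_conf = {
        block: config.confounder_strength
        * rng.standard_normal((p_conf, q))
        for block, q in (
            ("pa", config.n_pa),
            ("fc", config.n_fc_edges),
            ("gmv", config.n_gmv),
        )
    }
    gmv_ref = rng.uniform(2000.0, 20000.0, size=config.n_gmv)
    return _Structure(U_pa, W_fc, W_gmv, h_pa, h_fc, h_gmv, B_conf, gmv_ref)


# ----------------------------------------------------------------------
# closed-form oracle
# ----------------------------------------------------------------------


def population_canonical_correlations(
    config: CohortConfig, block: str = "fc"
) -> np.ndarray:
    """Population canonical correlations of the residualized PA/IDP blocks.

    Computed from the implied within- and cross-block covariances of the
    factor model (confounders are independent of the latents, so
    residualization leaves these second moments unchanged) as the singular
    values of the whitened cross-covariance.

    Returns
    -------
    (min(n_pa, q),) ndarray, descending; all zeros when no factor links
    the two blocks.
    """
    st = _resolve_structure(config)
    m_fc = len(config.latent_fc)
    if block == "fc":
        W, h_idp = st.W_fc, st.h_fc
        idx = np.arange(m_fc)
        sigma = config.noise_scales["fc"]
        q = config.n_fc_edges
    elif block == "gmv":
        W, h_idp = st.W_gmv, st.h_gmv
        idx = np.arange(m_fc, m_fc + len(config.latent_gmv))
        sigma = config.noise_scales["gmv"]
        q = config.n_gmv
    else:
        raise ValueError("block must be 'fc' or 'gmv'")

    p = config.n_pa
    s_pa = config.noise_scales["pa"]
    k = min(p, q)
    Sxx = st.U_pa @ np.diag(st.h_pa**2) @ st.U_pa.T + s_pa**2 * np.eye(p)
    Syy = W @ np.diag(h_idp**2) @ W.T + sigma**2 * np.eye(q)
    Sxy = st.U_pa[:, idx] @ np.diag(st.h_pa[idx] * h_idp) @ W.T
    if np.linalg.matrix_rank(Sxx) < p:
        raise np.linalg.LinAlgError("implied PA covariance is singular")
    K = _inv_sqrt(Sxx) @ Sxy @ _inv_sqrt(Syy)
    s = np.linalg.svd(K, compute_uv=False)
    out = np.zeros(k)
    out[: min(k, s.size)] = np.clip(s[:k], 0.0, 1.0)
    return out


# ----------------------------------------------------------------------
# generation
# ----------------------------------------------------------------------


def generate_disease(
    linpred_design,
    coef,
    rng,
    *,
    intercept: float | None = None,
    prevalence: float | None = None,
) -> tuple[np.ndarray, float]:
    """Draw binary labels from a logistic model.

    Parameters
    ----------
    linpred_design : (n, d) array-like
    coef : (d,) array-like
    rng : numpy Generator
    intercept : float, optional
        Used as-is when given.
    prevalence : float, optional
        Otherwise the intercept is solved (Brent's method) so the analytic
        prevalence ``mean(expit(eta + b))`` equals this target.

    Returns
    -------
    (labels, intercept)
    """
    X = np.asarray(linpred_design, dtype=float)
    beta = np.asarray(coef, dtype=float)
    if X.shape[1] != beta.shape[0]:
        raise ValueError(
            f"coefficient length {beta.shape[0]} does not match design "
            f"width {X.shape[1]}"
        )
    eta = X @ beta
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    if intercept is None:
        if prevalence is None:
            intercept = 0.0
        else:
            intercept = brentq(
                lambda b: expit(eta + b).mean() - prevalence, -40.0, 40.0
            )
    p = expit(eta + intercept)
    labels = (rng.random(X.shape[0]) < p).astype(np.int8)
    return labels, float(intercept)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a complete synthetic cohort.

    Deterministic given ``config.seed``.  PA and IDP blocks share latent
    factors per the config's latent lists, plus linear confounder effects
    and independent Gaussian noise; the returned ground truth holds the
    population canonical correlations of each PA/IDP pairing and the
    disease-generating coefficients.
    """
    st = _resolve_structure(config)
    ss = np.random.SeedSequence([config.seed, 777])
    rng = np.random.default_rng(ss)
    n = config.n_participants
    p_conf = config.n_confounders_per_block

    ids = pd.Index(
        [f"P{i:06d}" for i in range(n)], name="participant_id"
    )

    # confounders: independent across blocks and of the latents
    def draw_conf():
        cols = {}
        if p_conf >= 1:
            cols["sex"] = rng.integers(0, 2, size=n).astype(float)
        if p_conf >= 2:
            cols["age"] = rng.standard_normal(n)
        if p_conf >= 3:
            cols["motion"] = rng.standard_normal(n)
        return pd.DataFrame(cols, index=ids)

    confounders = {b: draw_conf() for b in ("pa", "fc", "gmv")}

    m_fc, m_gmv = len(config.latent_fc), len(config.latent_gmv)
    Z = rng.standard_normal((n, m_fc + m_gmv))
    s = config.noise_scales

    core_pa = (
        Z * st.h_pa @ st.U_pa.T
        + s["pa"] * rng.standard_normal((n, config.n_pa))
    )
    core_fc = (
        Z[:, :m_fc] * st.h_fc @ st.W_fc.T
        + s["fc"] * rng.standard_normal((n, config.n_fc_edges))
    )
    core_gmv = (
        Z[:, m_fc:] * st.h_gmv @ st.W_gmv.T
        + s["gmv"] * rng.standard_normal((n, config.n_gmv))
    )
    for block, core in (("pa", core_pa), ("fc", core_fc), ("gmv", core_gmv)):
        G = confounders[block].to_numpy()
        if G.size:
            core += G @ st.B_conf[block]

    # presentation scales (affine / monotone maps; see module docstring)
    pa_names = (
        PA_COLUMNS if config.n_pa == len(PA_COLUMNS)
        else [f"PA{j + 1}" for j in range(config.n_pa)]
    )
    core_sd_pa = core_pa.std(axis=0, ddof=1)
    core_sd_pa[core_sd_pa == 0] = 1.0
    pa_vals = np.empty_like(core_pa)
    for j, name in enumerate(pa_names):
        mean, sd = _PA_SCALE.get(name, (0.0, 1.0))
        pa_vals[:, j] = mean + sd * (core_pa[:, j] - core_pa[:, j].mean()) / core_sd_pa[j]
    pa = pd.DataFrame(pa_vals, index=ids, columns=pa_names)

    fc_edge_vals = _FC_EDGE_SCALE * core_fc  # Fisher-z scale (= atanh of netmat)
    nodes = config.n_fc_nodes
    edge_names = [
        f"edge_{i}_{j}" for i in range(1, nodes) for j in range(i)
    ]
    fc_edges = pd.DataFrame(fc_edge_vals, index=ids, columns=edge_names)

    core_sd_gmv = core_gmv.std(axis=0, ddof=1)
    core_sd_gmv[core_sd_gmv == 0] = 1.0
    gmv_vals = st.gmv_ref * np.exp(
        _GMV_LOG_SD * (core_gmv - core_gmv.mean(axis=0)) / core_sd_gmv
    )
    gmv = pd.DataFrame(
        gmv_vals, index=ids, columns=[f"roi_{j + 1}" for j in range(config.n_gmv)]
    )

    # disease outcomes over standardized columns
    def zscore(M):
        sd = M.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        return (M - M.mean(axis=0)) / sd

    z_conf = {b: zscore(confounders[b].to_numpy()) for b in confounders}
    z_pa = zscore(pa_vals)
    z_idp = {"fc": None, "gmv": None}  # standardized lazily

    labels = {}
    truth_disease = {}
    for d in config.diseases:
        parts, coefs = [], []
        if d.coef_confounders is not None and p_conf:
            parts.append(z_conf["pa"])
            coefs.append(np.asarray(d.coef_confounders, float)[:p_conf])
        if d.coef_pa is not None:
            parts.append(z_pa)
            coefs.append(np.asarray(d.coef_pa, float))
        if d.coef_idp is not None:
            if z_idp[d.idp_block] is None:
                src = fc_edge_vals if d.idp_block == "fc" else np.log(gmv_vals)
                z_idp[d.idp_block] = zscore(src)
            parts.append(z_idp[d.idp_block])
            coefs.append(np.asarray(d.coef_idp, float))
        if parts:
            design = np.hstack(parts)
            coef = np.concatenate(coefs)
        else:
            design = np.zeros((n, 1))
            coef = np.zeros(1)
        y, intercept = generate_disease(
            design, coef, rng, prevalence=d.prevalence
        )
        labels[d.name] = y
        truth_disease[d.name] = {
            "intercept": intercept,
            "prevalence_target": d.prevalence,
            "coef_confounders": None
            if d.coef_confounders is None
            else np.asarray(d.coef_confounders, float).tolist(),
            "coef_pa": None
            if d.coef_pa is None
            else np.asarray(d.coef_pa, float).tolist(),
            "idp_block": d.idp_block,
            "uses_idp": d.coef_idp is not None,
        }
    disease = pd.DataFrame(labels, index=ids)

    ground_truth = {
        "rho_fc": population_canonical_correlations(config, "fc").tolist(),
        "rho_gmv": population_canonical_correlations(config, "gmv").tolist(),
        "diseases": truth_disease,
        "seed": config.seed,
    }
    return SyntheticCohort(
        config=config,
        confounders=confounders,
        pa=pa,
        fc_edges=fc_edges,
        gmv=gmv,
        disease=disease,
        ground_truth=ground_truth,
    )


# ----------------------------------------------------------------------
# persistence
# ----------------------------------------------------------------------


def write_cohort(
    cohort: SyntheticCohort, out_dir, *, write_netmats: bool = False
) -> Path:
    """Write a cohort as a directory of TSV files plus ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    conf = pd.concat(
        {b: df for b, df in cohort.confounders.items()}, axis=1
    )
    conf.columns = [f"{b}_{c}" for b, c in conf.columns]
    conf.to_csv(out / "confounders.tsv", sep="\t")
    cohort.pa.to_csv(out / "pa.tsv", sep="\t")
    cohort.fc_edges.to_csv(out / "fc.tsv", sep="\t")
    cohort.gmv.to_csv(out / "gmv.tsv", sep="\t")
    cohort.disease.to_csv(out / "disease.tsv", sep="\t")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(cohort.ground_truth, fh, indent=2)
    if write_netmats:
        nm_dir = out / "netmats"
        nm_dir.mkdir(exist_ok=True)
        for i, pid in enumerate(cohort.participant_ids):
            np.savetxt(nm_dir / f"{pid}.txt", cohort.netmat(i), fmt="%.10g")
    return out


def read_cohort(in_dir) -> dict:
    """Read a written cohort directory back into DataFrames.

    Returns a dict with keys ``confounders`` (per-block frames), ``pa``,
    ``fc``, ``gmv``, ``disease`` and ``ground_truth``.
    """
    p = Path(in_dir)
    conf_all = pd.read_csv(p / "confounders.tsv", sep="\t", index_col=0)
    confounders = {}
    for block in ("pa", "fc", "gmv"):
        cols = [c for c in conf_all.columns if c.startswith(block + "_")]
        confounders[block] = conf_all[cols].rename(
            columns=lambda c: c[len(block) + 1 :]
        )
    out = {
        "confounders": confounders,
        "pa": pd.read_csv(p / "pa.tsv", sep="\t", index_col=0),
        "fc": pd.read_csv(p / "fc.tsv", sep="\t", index_col=0),
        "gmv": pd.read_csv(p / "gmv.tsv", sep="\t", index_col=0),
        "disease": pd.read_csv(p / "disease.tsv", sep="\t", index_col=0),
    }
    gt = p / "ground_truth.json"
    out["ground_truth"] = json.loads(gt.read_text()) if gt.exists() else None
    return out
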