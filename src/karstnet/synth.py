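"""Synthetic data emulating a 2x2x2 water x nitrogen x phosphorus field study.

Generates the three tables every downstream stage consumes, with known ground
truth so the whole pipeline is testable without sequencing data:

* a balanced factorial sample design (8 treatments x B blocks),
* a per-sample soil-property table drawn around published treatment baselines,
* an OTU count table from a Gaussian-copula log-normal compositional model
  with planted inter-taxon correlations and multinomial count sampling.

The copula construction makes the correlation matrix of the latent log
abundances exactly the planted basis correlation, which is what the SparCC
estimator downstream tries to recover from the closed (compositional) counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import as_rng, derive_seed
from .otu import FACTORS, TREATMENTS, OtuTable, treatment_label
from .reference import load_soil_reference

__all__ = [
    "TruthCorrelation",
    "EnvProfile",
    "LognormalParams",
    "DepthParams",
    "SyntheticDataset",
    "generate_design",
    "default_env_profile",
    "generate_env_table",
    "generate_basis_correlation",
    "random_planted_pairs",
    "generate_otu_table",
    "make_taxon_labels",
    "generate_dataset",
]

#: replicates (blocks) per treatment in the emulated field study
DEFAULT_BLOCKS = 5
#: default taxa: 150 "bacteria" + 60 "fungi" (domain labels are metadata only)
DEFAULT_N_BACTERIA = 150
DEFAULT_N_FUNGI = 60


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def generate_design(blocks: int = DEFAULT_BLOCKS, seed: int | None = None) -> pd.DataFrame:
    """Balanced full-factorial design: 8 W/N/P treatments x ``blocks`` blocks.

    Returns a DataFrame indexed by sample id with columns ``W``, ``N``, ``P``
    (binary levels), ``block`` and ``treatment`` (C/W/N/P/WN/WP/NP/WNP).
    ``seed`` is accepted for interface symmetry; the design is deterministic.
    """
    if blocks < 1:
        raise ValueError(f"blocks must be >= 1, got {blocks}")
    levels = {t: tuple(int(f in t) for f in FACTORS) for t in TREATMENTS}
    rows = []
    for block in range(1, blocks + 1):
        for trt in TREATMENTS:
            w, n, p = levels[trt]
            rows.append(
                {
                    "sample_id": f"{trt}_B{block}",
                    "W": w,
                    "N": n,
                    "P": p,
                    "block": block,
                    "treatment": treatment_label(w, n, p),
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# environmental table
# ---------------------------------------------------------------------------

@dataclass
class EnvProfile:
    """Baselines and factor effects for the soil-property simulator.

    ``baseline`` maps variable -> (mean, SD) under the control treatment;
    ``effects`` maps factor (W/N/P) -> {variable: multiplicative effect on the
    mean when the factor is active}. Variables absent from ``effects`` have
    multiplier 1. All variables are truncated at zero after the normal draw.
    """

    baseline: dict[str, tuple[float, float]]
    effects: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for var, (mean, sd) in self.baseline.items():
            if mean <= 0:
                raise ValueError(f"baseline mean for {var} must be > 0")
            if sd < 0:
                raise ValueError(f"baseline SD for {var} must be >= 0")
        for factor, mult in self.effects.items():
            if factor not in FACTORS:
                raise ValueError(f"unknown factor {factor!r}")
            for var, m in mult.items():
                if m <= 0:
                    raise ValueError(f"effect multiplier for {factor}->{var} must be > 0")

    @property
    def variables(self) -> list[str]:
        return list(self.baseline)

    def multiplier(self, var: str, active_factors) -> float:
        m = 1.0
        for f in active_factors:
            m *= self.effects.get(f, {}).get(var, 1.0)
        return m


def default_env_profile() -> EnvProfile:
    """Profile anchored to the bundled karst-shrubland control means.

    SDs are the published standard errors scaled by sqrt(5) (n = 5 blocks).
    The three documented single-factor responses are planted as multiplicative
    effects: W raises soil water content by 7.58%, N raises nitrate by 57.66%,
    P raises the C:N ratio by 16.09%.
    """
    means, ses = load_soil_reference()
    baseline = {
        var: (float(means.loc[var, "C"]), float(ses.loc[var, "C"]) * np.sqrt(5.0))
        for var in means.index
    }
    effects = {
        "W": {"SWC": 1.0758},
        "N": {"NO3": 1.5766},
        "P": {"C:N": 1.1609},
    }
    return EnvProfile(baseline=baseline, effects=effects)


def generate_env_table(
    design: pd.DataFrame,
    profile: EnvProfile | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a per-sample soil-property table under the factorial design.

    Each variable is Normal(baseline mean x product of active-factor
    multipliers, SD), truncated at zero. Deterministic given ``seed``.
    """
    profile = profile if profile is not None else default_env_profile()
    rng = as_rng(seed)
    variables = profile.variables
    if not variables:
        raise ValueError("profile defines no variables")
    out = np.empty((len(design), len(variables)))
    active = [
        [f for f in FACTORS if design.iloc[i][f]] for i in range(len(design))
    ]
    for j, var in enumerate(variables):
        mean, sd = profile.baseline[var]
        mus = np.array([mean * profile.multiplier(var, a) for a in active])
        out[:, j] = np.maximum(mus + sd * rng.standard_normal(len(design)), 0.0)
    return pd.DataFrame(out, index=design.index, columns=variables)


# ---------------------------------------------------------------------------
# ground-truth correlation structure
# ---------------------------------------------------------------------------

@dataclass
class TruthCorrelation:
    """Basis correlation matrix over taxa with a record of planted pairs."""

    matrix: np.ndarray
    planted: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    def planted_lookup(self) -> dict[tuple[int, int], float]:
        return {(min(i, j), max(i, j)): r for i, j, r in self.planted}


def _nearest_psd_correlation(mat: np.ndarray) -> np.ndarray:
    """Project onto the PSD cone (eigenvalue clipping) and re-unitize the diagonal."""
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() >= 0:
        return mat
    vals = np.clip(vals, 0.0, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.clip(np.diag(repaired), 1e-12, None))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2.0


def generate_basis_correlation(
    n_taxa: int,
    planted_pairs=(),
    seed: int | None = None,
) -> TruthCorrelation:
    """Sparse ground-truth correlation matrix with planted off-diagonal pairs.

    Starts from the identity, sets each planted (i, j, rho) entry, and projects
    to the nearest positive semi-definite correlation matrix (a no-op for
    disjoint pairs, which form PSD 2x2 blocks). ``seed`` is unused but accepted
    so all generators share a signature.
    """
    if n_taxa < 4:
        raise ValueError(f"need at least 4 taxa, got {n_taxa}")
    mat = np.eye(n_taxa)
    seen: set[int] = set()
    planted = []
    for i, j, rho in planted_pairs:
        i, j = int(i), int(j)
        if i == j:
            raise ValueError(f"planted pair ({i},{j}) is a self-pair")
        if not (0 <= i < n_taxa and 0 <= j < n_taxa):
            raise ValueError(f"planted pair ({i},{j}) out of range for D={n_taxa}")
        if i in seen or j in seen:
            raise ValueError(f"planted pairs must be disjoint; taxon {i if i in seen else j} reused")
        if not abs(rho) < 1:
            raise ValueError(f"planted |rho| must be < 1, got {rho}")
        seen.update((i, j))
        mat[i, j] = mat[j, i] = float(rho)
        planted.append((min(i, j), max(i, j), float(rho)))
    mat = _nearest_psd_correlation(mat)
    return TruthCorrelation(matrix=mat, planted=planted)


def random_planted_pairs(
    n_taxa: int,
    n_pairs: int,
    rho_range: tuple[float, float] = (0.7, 0.9),
    frac_positive: float = 0.8,
    seed: int | None = None,
) -> list[tuple[int, int, float]]:
    """Draw disjoint taxon pairs with correlation magnitudes in ``rho_range``.

    A fraction ``frac_positive`` of pairs receive positive sign (co-occurrence
    networks in nutrient-addition studies are dominated by positive edges).
    """
    if 2 * n_pairs > n_taxa:
        raise ValueError(f"{n_pairs} disjoint pairs need >= {2 * n_pairs} taxa, have {n_taxa}")
    rng = as_rng(seed)
    idx = rng.permutation(n_taxa)[: 2 * n_pairs]
    mags = rng.uniform(*rho_range, size=n_pairs)
    signs = np.where(rng.uniform(size=n_pairs) < frac_positive, 1.0, -1.0)
    return [
        (int(idx[2 * k]), int(idx[2 * k + 1]), float(signs[k] * mags[k]))
        for k in range(n_pairs)
    ]


# ---------------------------------------------------------------------------
# OTU counts
# ---------------------------------------------------------------------------

@dataclass
class LognormalParams:
    """Marginals of the latent log-abundance model.

    ``taxon_mean_log_sd`` spreads mean log abundances across taxa (a heavy
    right tail of relative abundances, as in amplicon data); ``sigma_log`` is
    the across-sample SD of each taxon's log abundance.
    """

    taxon_mean_log_sd: float = 1.5
    sigma_log: float = 1.0


@dataclass
class DepthParams:
    """Library-size model: log-normal with given mean and coefficient of variation."""

    mean: float = 2.0e4
    cv: float = 0.3

    def __post_init__(self) -> None:
        if self.mean < 1000:
            raise ValueError("mean library size must be >= 1000")
        if self.cv < 0:
            raise ValueError("depth CV must be >= 0")


def make_taxon_labels(
    n_bacteria: int = DEFAULT_N_BACTERIA, n_fungi: int = DEFAULT_N_FUNGI
) -> tuple[list[str], dict[str, str]]:
    """Taxon ids ('B0001'.., 'F0001'..) and their domain-label mapping."""
    labels = [f"B{k:04d}" for k in range(1, n_bacteria + 1)]
    labels += [f"F{k:04d}" for k in range(1, n_fungi + 1)]
    domains = {t: ("bacteria" if t.startswith("B") else "fungi") for t in labels}
    return labels, domains


def generate_otu_table(
    design: pd.DataFrame,
    truth: TruthCorrelation,
    lognormal_params: LognormalParams | None = None,
    depth_params: DepthParams | None = None,
    effects: dict[str, dict[int, float]] | None = None,
    seed: int | None = None,
    taxon_labels: list[str] | None = None,
    taxon_domains: dict[str, str] | None = None,
    return_latents: bool = False,
):
    """Simulate compositional OTU counts with known correlation structure.

    Per sample: latent log abundances are a Gaussian copula draw with
    correlation ``truth.matrix`` and log-normal marginals; optional
    factor-specific fold changes (``effects[factor][taxon_index]``) shift the
    latent means of responsive taxa in samples where the factor is active;
    abundances are closed to fractions and counts drawn multinomially at a
    log-normally distributed library size. Row sums therefore equal the drawn
    depths exactly.
    """
    lognormal_params = lognormal_params or LognormalParams()
    depth_params = depth_params or DepthParams()
    rng = as_rng(seed)
    n = len(design)
    D = truth.n_taxa
    if taxon_labels is None:
        taxon_labels = [f"OTU{k:04d}" for k in range(1, D + 1)]
    if len(taxon_labels) != D:
        raise ValueError(f"{len(taxon_labels)} taxon labels for D={D} taxa")

    # correlated standard-normal latents via Cholesky (jitter guards fp PSD edge)
    chol = np.linalg.cholesky(truth.matrix + 1e-10 * np.eye(D))
    z = rng.standard_normal((n, D)) @ chol.T

    mu_taxa = rng.normal(0.0, lognormal_params.taxon_mean_log_sd, size=D)
    log_abund = mu_taxa + lognormal_params.sigma_log * z
    if effects:
        for factor, taxon_folds in effects.items():
            if factor not in FACTORS:
                raise ValueError(f"unknown factor {factor!r} in effects")
            active = design[factor].to_numpy(dtype=bool)
            for taxon_idx, fold in taxon_folds.items():
                if not 0 <= int(taxon_idx) < D:
                    raise ValueError(f"effect taxon index {taxon_idx} out of range")
                log_abund[active, int(taxon_idx)] += np.log(fold)

    abund = np.exp(log_abund)
    fractions = abund / abund.sum(axis=1, keepdims=True)

    sigma2 = np.log1p(depth_params.cv**2)
    mu_depth = np.log(depth_params.mean) - sigma2 / 2.0
    depths = np.maximum(
        np.round(rng.lognormal(mu_depth, np.sqrt(sigma2), size=n)).astype(np.int64), 1
    )
    counts = np.vstack(
        [rng.multinomial(depths[i], fractions[i]) for i in range(n)]
    )
    table = OtuTable(
        pd.DataFrame(counts, index=design.index, columns=taxon_labels),
        metadata=design,
        taxon_domains=taxon_domains or {},
    )
    if return_latents:
        return table, pd.DataFrame(log_abund, index=design.index, columns=taxon_labels)
    return table


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """A complete simulated study: counts, soil table, ground truth, seed record."""

    otu: OtuTable
    env: pd.DataFrame
    truth: TruthCorrelation
    seed: int
    params: dict = field(default_factory=dict)

    def write(self, outdir) -> dict[str, Path]:
        """Write all tables plus a JSON run manifest; returns written paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "otu": outdir / "otu_counts.tsv",
            "metadata": outdir / "sample_metadata.csv",
            "env": outdir / "soil_properties.csv",
            "truth": outdir / "truth_correlation.tsv",
            "manifest": outdir / "synth_manifest.json",
        }
        self.otu.to_tsv(paths["otu"])
        self.otu.metadata_to_csv(paths["metadata"])
        env = self.env.copy()
        env.index.name = "sample_id"
        env.to_csv(paths["env"], float_format="%.10g")
        taxa = self.otu.taxa
        pd.DataFrame(self.truth.matrix, index=taxa, columns=taxa).to_csv(
            paths["truth"], sep="\t", float_format="%.10g"
        )
        manifest = {
            "seed": self.seed,
            "params": self.params,
            "planted_pairs": [[i, j, r] for i, j, r in self.truth.planted],
        }
        paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return paths


def generate_dataset(
    blocks: int = DEFAULT_BLOCKS,
    n_bacteria: int = DEFAULT_N_BACTERIA,
    n_fungi: int = DEFAULT_N_FUNGI,
    n_planted_pairs: int = 40,
    rho_range: tuple[float, float] = (0.7, 0.9),
    frac_positive: float = 0.8,
    lognormal_params: LognormalParams | None = None,
    depth_params: DepthParams | None = None,
    n_responsive_per_factor: int = 10,
    responsive_fold: float = 2.0,
    env_profile: EnvProfile | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """One-call simulator for the default emulated study.

    Defaults mirror the emulated field design: 8 treatments x 5 blocks = 40
    samples, 210 taxa (150 bacteria + 60 fungi), 40 planted correlation pairs
    with |rho| in [0.7, 0.9] (80% positive), mean depth 2e4 reads (CV 0.3),
    and 10 taxa per factor responding 2-fold to W/N/P additions. Sub-seeds for
    each component are derived deterministically from ``seed``.
    """
    design = generate_design(blocks)
    D = n_bacteria + n_fungi
    pairs = random_planted_pairs(
        D, n_planted_pairs, rho_range, frac_positive, seed=derive_seed(seed, "pairs")
    )
    truth = generate_basis_correlation(D, pairs)
    env = generate_env_table(design, env_profile, seed=derive_seed(seed, "env"))
    labels, domains = make_taxon_labels(n_bacteria, n_fungi)

    # responsive taxa are drawn outside the planted pairs so treatment effects
    # do not confound correlation recovery
    rng = as_rng(derive_seed(seed, "effects"))
    in_pairs = {i for i, j, _ in truth.planted} | {j for i, j, _ in truth.planted}
    free = np.array(sorted(set(range(D)) - in_pairs))
    effects: dict[str, dict[int, float]] = {}
    if n_responsive_per_factor > 0 and len(free):
        for factor in FACTORS:
            chosen = rng.choice(free, size=min(n_responsive_per_factor, len(free)), replace=False)
            effects[factor] = {int(t): responsive_fold for t in chosen}

    otu = generate_otu_table(
        design,
        truth,
        lognormal_params,
        depth_params,
        effects,
        seed=derive_seed(seed, "otu"),
        taxon_labels=labels,
        taxon_domains=domains,
    )
    params = {
        "blocks": blocks,
        "n_bacteria": n_bacteria,
        "n_fungi": n_fungi,
        "n_planted_pairs": n_planted_pairs,
        "rho_range": list(rho_range),
        "frac_positive": frac_positive,
        "n_responsive_per_factor": n_responsive_per_factor,
        "responsive_fold": responsive_fold,
        "depth_mean": (depth_params or DepthParams()).mean,
        "depth_cv": (depth_params or DepthParams()).cv,
    }
    return SyntheticDataset(otu=otu, env=env, truth=truth, seed=seed, params=params)
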