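"""End-to-end orchestration: simulate -> filter/SparCC -> network -> topology
and stability -> treatment statistics, as one reproducible, seeded run.

Every stage derives its own seed from the master seed by stable hashing, all
outputs are plain TSV/CSV/JSON with fixed float formatting, and the run
manifest records a checksum for each file — two runs from the same config and
master seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import derive_seed
from .netbuild import build_network, extract_sample_subnetworks, write_network
from .otu import FACTORS, OtuTable
from .sparcc import SparCC, SparccParams
from .stability import StabilityParams, robustness_curve, stability_summary, vulnerability_curve
from .stats import (
    bray_curtis,
    env_distance,
    factorial_anova,
    mantel,
    oneway_lsd,
    percent_change,
    shannon_table,
)
from .synth import DepthParams, LognormalParams, generate_dataset
from .topology import ModularityParams, summarize_topology

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "write_report"]

FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SynthConfig:
    blocks: int = 5
    n_bacteria: int = 150
    n_fungi: int = 60
    n_planted_pairs: int = 40
    rho_min: float = 0.7
    rho_max: float = 0.9
    frac_positive: float = 0.8
    depth_mean: float = 2.0e4
    depth_cv: float = 0.3
    taxon_mean_log_sd: float = 1.5
    sigma_log: float = 1.0
    n_responsive_per_factor: int = 10
    responsive_fold: float = 2.0


@dataclass
class SparccConfig:
    min_total: int = 400
    dirichlet_resamples: int = 20
    exclusion_iterations: int = 10
    exclusion_threshold: float = 0.1
    bootstrap_count: int = 100
    bootstrap_resamples: int = 5


@dataclass
class NetworkConfig:
    r_threshold: float = 0.6
    p_threshold: float = 0.01
    min_count: int = 1


@dataclass
class TopologyConfig:
    null_replicates: int = 100


@dataclass
class StabilityConfig:
    fraction_step: float = 0.05
    robustness_replicates: int = 50
    vulnerability_replicates: int = 10
    mode: str = "random"
    secondary_extinction: bool = True
    per_sample: bool = True


@dataclass
class StatsConfig:
    alpha: float = 0.05
    mantel_permutations: int = 999
    include_block: bool = False
    transform: str = "auto"


@dataclass
class PipelineConfig:
    """Validated full-run configuration with spec'd defaults.

    Defaults reproduce the emulated study conditions: 40 samples, 210 taxa,
    abundance filter > 400, |rho| >= 0.6, p < 0.01, 100 bootstraps.
    """

    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)
    sparcc: SparccConfig = field(default_factory=SparccConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    topology: TopologyConfig = field(default_factory=TopologyConfig)
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    _SECTIONS = {
        "synth": SynthConfig,
        "sparcc": SparccConfig,
        "network": NetworkConfig,
        "topology": TopologyConfig,
        "stability": StabilityConfig,
        "stats": StatsConfig,
    }

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        kwargs: dict = {}
        if "seed" in raw:
            kwargs["seed"] = int(raw.pop("seed"))
        for name, section_cls in cls._SECTIONS.items():
            sub = raw.pop(name, {}) or {}
            known = {f.name for f in dataclasses.fields(section_cls)}
            unknown = set(sub) - known
            if unknown:
                raise ValueError(
                    f"unknown key(s) in config section '{name}': {sorted(unknown)}"
                )
            kwargs[name] = section_cls(**sub)
        if raw:
            raise ValueError(f"unknown top-level config key(s): {sorted(raw)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = {"seed": self.seed}
        for name in self._SECTIONS:
            d[name] = dataclasses.asdict(getattr(self, name))
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig.from_dict(raw or {})


def dump_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, float_format=FLOAT_FMT, index=index)


@dataclass
class RunManifest:
    """Record of one pipeline run: config, per-stage seeds, file checksums."""

    config: dict
    config_hash: str
    version: str
    seed: int
    stage_seeds: dict[str, int]
    files: dict[str, str]
    notes: dict[str, str] = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def run_pipeline(config: PipelineConfig, outdir) -> RunManifest:
    """Execute all stages, writing outputs and a manifest under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {
        stage: derive_seed(config.seed, "stage", stage)
        for stage in ("synth", "sparcc", "topology", "stability", "stats")
    }
    files: dict[str, Path] = {}
    notes: dict[str, str] = {}

    # -- stage 1: simulate -------------------------------------------------
    syn = config.synth
    dataset = generate_dataset(
        blocks=syn.blocks,
        n_bacteria=syn.n_bacteria,
        n_fungi=syn.n_fungi,
        n_planted_pairs=syn.n_planted_pairs,
        rho_range=(syn.rho_min, syn.rho_max),
        frac_positive=syn.frac_positive,
        lognormal_params=LognormalParams(syn.taxon_mean_log_sd, syn.sigma_log),
        depth_params=DepthParams(syn.depth_mean, syn.depth_cv),
        n_responsive_per_factor=syn.n_responsive_per_factor,
        responsive_fold=syn.responsive_fold,
        seed=seeds["synth"],
    )
    files.update(dataset.write(outdir))
    table, env, design = dataset.otu, dataset.env, dataset.otu.metadata

    # -- stage 2: filter + SparCC + bootstrap ------------------------------
    sp = config.sparcc
    params = SparccParams(
        dirichlet_resamples=sp.dirichlet_resamples,
        exclusion_iterations=sp.exclusion_iterations,
        exclusion_threshold=sp.exclusion_threshold,
        bootstrap_count=sp.bootstrap_count,
        bootstrap_resamples=sp.bootstrap_resamples,
        min_total_abundance=sp.min_total,
        seed=seeds["sparcc"],
    )
    model = SparCC(table, params=params)
    results = model.fit()
    pvals = results.pvalues()
    files["rho"] = outdir / "sparcc_rho.tsv"
    files["pvals"] = outdir / "sparcc_pvals.tsv"
    results.write(files["rho"], files["pvals"])
    notes["sparcc"] = (
        f"{model.table.n_taxa} of {table.n_taxa} taxa passed the "
        f"total-abundance > {sp.min_total} filter"
    )

    # -- stage 3: network --------------------------------------------------
    net = build_network(
        results.rho,
        pvals,
        r_threshold=config.network.r_threshold,
        p_threshold=config.network.p_threshold,
        taxon_domains=model.table.taxon_domains,
    )
    files["network_tsv"] = outdir / "network_edges.tsv"
    files["network_graphml"] = outdir / "network.graphml"
    write_network(net, files["network_tsv"], fmt="tsv")
    write_network(net, files["network_graphml"], fmt="graphml")
    notes["network"] = (
        f"{net.number_of_nodes()} nodes, {net.number_of_edges()} edges at "
        f"|rho| >= {config.network.r_threshold}, p < {config.network.p_threshold}"
    )

    # -- stage 4: per-sample topology --------------------------------------
    subnets = extract_sample_subnetworks(net, model.table, config.network.min_count)
    topo = summarize_topology(
        subnets,
        metadata=design,
        modularity_params=ModularityParams(
            null_model_replicates=config.topology.null_replicates, seed=seeds["topology"]
        ),
    )
    files["topology"] = outdir / "topology.csv"
    _write_csv(topo, files["topology"])

    # -- stage 5: stability -------------------------------------------------
    stab = config.stability
    grid = np.round(np.arange(0.0, 0.951, stab.fraction_step), 10)
    grid = grid[grid < 1.0]
    networks = {"GLOBAL": net}
    if stab.per_sample:
        networks.update(subnets)
    rob_curves, vuln_curves, summaries = [], [], []
    for net_id, graph in networks.items():
        if graph.number_of_nodes() < 2:
            continue
        rparams = StabilityParams(
            fractions=grid,
            replicates=stab.robustness_replicates,
            mode=stab.mode,
            secondary_extinction=stab.secondary_extinction,
            seed=derive_seed(seeds["stability"], "robustness", net_id),
        )
        vparams = StabilityParams(
            fractions=grid,
            replicates=stab.vulnerability_replicates,
            mode=stab.mode,
            seed=derive_seed(seeds["stability"], "vulnerability", net_id),
        )
        rob = robustness_curve(graph, rparams)
        vuln = vulnerability_curve(graph, vparams)
        rob.insert(0, "network_id", net_id)
        vuln.insert(0, "network_id", net_id)
        rob_curves.append(rob)
        vuln_curves.append(vuln)
        summaries.append({"network_id": net_id, **stability_summary(rob, vuln)})
    files["robustness"] = outdir / "robustness_curves.csv"
    files["vulnerability"] = outdir / "vulnerability_curves.csv"
    files["stability_summary"] = outdir / "stability_summary.csv"
    _write_csv(pd.concat(rob_curves, ignore_index=True), files["robustness"], index=False)
    _write_csv(pd.concat(vuln_curves, ignore_index=True), files["vulnerability"], index=False)
    _write_csv(pd.DataFrame(summaries).set_index("network_id"), files["stability_summary"])

    # -- stage 6: statistics -------------------------------------------------
    st = config.stats
    diversity = shannon_table(table)
    files["diversity"] = outdir / "diversity.csv"
    _write_csv(diversity, files["diversity"])

    per_sample_stab = (
        pd.DataFrame(summaries).set_index("network_id").drop(index="GLOBAL", errors="ignore")
        if stab.per_sample
        else pd.DataFrame()
    )
    response = design.join(env).join(diversity[["shannon"]])
    topo_metrics = [
        "n_edges",
        "n_nodes_connected",
        "negative_ratio",
        "positive_ratio",
        "density",
        "average_degree",
        "relative_modularity",
    ]
    response = response.join(topo[topo_metrics])
    if len(per_sample_stab):
        response = response.join(per_sample_stab)

    anova_rows, lsd_rows = [], []
    analysis_vars = [
        c
        for c in response.columns
        if c not in (*FACTORS, "block", "treatment")
        and pd.api.types.is_numeric_dtype(response[c])
    ]
    for var in analysis_vars:
        y = response[var]
        if y.isna().any() or np.ptp(y.to_numpy()) == 0:
            anova_rows.append(
                {
                    "variable": var,
                    "term": "(skipped)",
                    "note": "missing values or constant response",
                }
            )
            continue
        tab = factorial_anova(
            y.to_numpy(), design, include_block=st.include_block, transform=st.transform
        )
        for term, row in tab.iterrows():
            if term == "Residual":
                continue
            anova_rows.append(
                {
                    "variable": var,
                    "term": term,
                    "sum_sq": row["sum_sq"],
                    "df": row["df"],
                    "F": row["F"],
                    "p": row["p"],
                    "transform_applied": tab.attrs["transform_applied"],
                }
            )
        lsd = oneway_lsd(y.to_numpy(), design["treatment"].to_numpy(), alpha=st.alpha)
        for group, row in lsd.iterrows():
            lsd_rows.append({"variable": var, "treatment": group, **row.to_dict()})
    files["anova"] = outdir / "anova.csv"
    files["lsd"] = outdir / "lsd_letters.csv"
    _write_csv(pd.DataFrame(anova_rows), files["anova"], index=False)
    _write_csv(pd.DataFrame(lsd_rows), files["lsd"], index=False)

    pct = pd.concat(
        [percent_change(response, factor, analysis_vars) for factor in FACTORS],
        ignore_index=True,
    )
    files["percent_change"] = outdir / "percent_change.csv"
    _write_csv(pct, files["percent_change"], index=False)

    bc = bray_curtis(table)
    mantel_rows = []
    targets = {"ALL": None, **{v: [v] for v in env.columns}}
    for label, variables in targets.items():
        res = mantel(
            bc,
            env_distance(env, variables),
            permutations=st.mantel_permutations,
            seed=derive_seed(seeds["stats"], "mantel", label),
        )
        mantel_rows.append(
            {
                "env_variables": label,
                "r": res.r,
                "p": res.p,
                "permutations": res.permutations,
                "method": res.method,
            }
        )
    files["mantel"] = outdir / "mantel.csv"
    _write_csv(pd.DataFrame(mantel_rows), files["mantel"], index=False)

    manifest = RunManifest(
        config=config.to_dict(),
        config_hash=config.config_hash(),
        version=__version__,
        seed=config.seed,
        stage_seeds=seeds,
        files={name: _sha256(Path(p)) for name, p in sorted(files.items())},
        notes=notes,
    )
    manifest.write(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def write_report(outdir, path=None) -> Path:
    """Human-readable Markdown summary regenerated from a completed run."""
    outdir = Path(outdir)
    manifest = RunManifest.read(outdir / "manifest.json")
    path = Path(path) if path is not None else outdir / "report.md"
    lines = [
        "# Co-occurrence network pipeline report",
        "",
        f"- package version: {manifest.version}",
        f"- master seed: {manifest.seed}",
        f"- config hash: {manifest.config_hash}",
        "",
    ]
    for stage, note in sorted(manifest.notes.items()):
        lines.append(f"- {stage}: {note}")
    lines.append("")

    def section(title, fname, render):
        lines.append(f"## {title}")
        lines.append("")
        fpath = outdir / fname
        if not fpath.exists():
            lines.append("_not run_")
        else:
            lines.extend(render(fpath))
        lines.append("")

    def render_pct(fpath):
        df = pd.read_csv(fpath)
        key = df[df["variable"].isin(["SWC", "NO3", "C:N"])]
        out = ["factor | variable | percent change", "--- | --- | ---"]
        for _, r in key.iterrows():
            out.append(f"{r['factor']} | {r['variable']} | {r['percent_change']:+.2f}%")
        return out

    def render_anova(fpath):
        df = pd.read_csv(fpath)
        df = df[df.get("term", "") != "(skipped)"]
        sig = df[df["p"] < 0.05] if "p" in df else df.iloc[:0]
        out = [f"{len(sig)} significant (p < 0.05) variable x term effects:", ""]
        out += ["variable | term | F | p", "--- | --- | --- | ---"]
        for _, r in sig.iterrows():
            out.append(f"{r['variable']} | {r['term']} | {r['F']:.2f} | {r['p']:.4g}")
        return out

    def render_stability(fpath):
        df = pd.read_csv(fpath, index_col=0)
        out = ["network | robustness AUC | initial natural connectivity",
               "--- | --- | ---"]
        show = df.loc[[i for i in df.index if i == "GLOBAL"]]
        rest = df.drop(index="GLOBAL", errors="ignore")
        for i, r in show.iterrows():
            out.append(
                f"{i} | {r['robustness_auc']:.4f} | {r['initial_natural_connectivity']:.4f}"
            )
        if len(rest):
            out.append(
                f"per-sample mean | {rest['robustness_auc'].mean():.4f} | "
                f"{rest['initial_natural_connectivity'].mean():.4f}"
            )
        out += ["", f"curves: `robustness_curves.csv`, `vulnerability_curves.csv`"]
        return out

    section("Marginal factor effects (soil variables)", "percent_change.csv", render_pct)
    section("Factorial ANOVA (W x N x P)", "anova.csv", render_anova)
    section("Network stability", "stability_summary.csv", render_stability)
    path.write_text("\n".join(lines) + "\n")
    return path
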