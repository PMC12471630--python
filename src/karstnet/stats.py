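"""Treatment-level statistics for the factorial W x N x P experiment.

Shannon diversity, the three-way factorial ANOVA (with the ln(x+1) normality
gate), one-way ANOVA with Fisher's LSD and compact letter displays, marginal
percent-change effects of each factor, Bray-Curtis community distances and
Mantel tests against environmental distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.spatial.distance import pdist, squareform

from ._utils import as_rng, check_square_symmetric
from .otu import FACTORS, OtuTable

__all__ = [
    "shannon",
    "shannon_table",
    "check_and_transform",
    "factorial_anova",
    "oneway_lsd",
    "percent_change",
    "percent_change_from_means",
    "bray_curtis",
    "env_distance",
    "mantel",
    "MantelResult",
]


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def shannon(counts) -> float:
    """Shannon index H = -sum p_i ln(p_i) in nats over taxa with count > 0."""
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    total = arr.sum()
    if total == 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_table(table: OtuTable) -> pd.DataFrame:
    """Per-sample Shannon diversity with the observed taxon count."""
    rows = [
        {
            "sample_id": s,
            "shannon": shannon(table.counts.loc[s]),
            "observed_taxa": int((table.counts.loc[s] > 0).sum()),
        }
        for s in table.samples
    ]
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# factorial ANOVA
# ---------------------------------------------------------------------------

def _design_frame(y, design: pd.DataFrame, include_block: bool) -> pd.DataFrame:
    df = pd.DataFrame({"y": np.asarray(y, dtype=float)}, index=design.index)
    for f in FACTORS:
        df[f] = design[f].astype(int).to_numpy()
    if include_block:
        df["block"] = design["block"].to_numpy()
    return df


def check_and_transform(y, design: pd.DataFrame, alpha: float = 0.05):
    """Apply ln(x+1) iff full-model residuals fail Shapiro-Wilk normality.

    Returns ``(y_transformed, applied_flag)``. The gate fits y ~ W*N*P and
    tests the residuals at ``alpha``; when the transform fires, negative
    values are rejected (ln(x+1) requires x >= 0).
    """
    y = np.asarray(y, dtype=float)
    df = _design_frame(y, design, include_block=False)
    resid = smf.ols("y ~ C(W) * C(N) * C(P)", data=df).fit().resid
    if np.allclose(resid, 0.0):
        return y, False
    p_norm = scipy.stats.shapiro(resid).pvalue
    if p_norm >= alpha:
        return y, False
    if (y < 0).any():
        raise ValueError("ln(x+1) transform required but values are negative")
    return np.log1p(y), True


def factorial_anova(
    y,
    design: pd.DataFrame,
    include_block: bool = False,
    transform: str = "auto",
) -> pd.DataFrame:
    """Three-way factorial ANOVA of ``y`` on the W/N/P design.

    Ordinary-least-squares fit of y ~ W*N*P (plus an additive block term on
    request) with per-term sums of squares, df, F and p. On a balanced 2x2x2
    design sequential and partial sums of squares coincide; type-II is used.
    ``transform``: 'auto' applies the ln(x+1) normality gate, 'log1p' forces
    it, 'none' skips it; the flag is recorded in ``result.attrs``.

    Raises on unbalanced designs (unequal cell counts).
    """
    if transform not in ("auto", "log1p", "none"):
        raise ValueError(f"unknown transform {transform!r}")
    cells = design.groupby(["W", "N", "P"]).size()
    if len(cells) != 8 or cells.nunique() != 1:
        raise ValueError("factorial_anova requires a balanced 2x2x2 design with replicates")
    y = np.asarray(y, dtype=float)
    applied = False
    if transform == "auto":
        y, applied = check_and_transform(y, design)
    elif transform == "log1p":
        if (y < 0).any():
            raise ValueError("ln(x+1) transform requires non-negative values")
        y, applied = np.log1p(y), True

    df = _design_frame(y, design, include_block)
    formula = "y ~ C(W) * C(N) * C(P)"
    if include_block:
        formula += " + C(block)"
    fit = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    table = table.rename(
        index=lambda s: s.replace("C(", "").replace(")", "").replace(":", ":")
    )
    # zero-variance response: define F = 0, p = 1 rather than 0/0
    if np.ptp(y) == 0:
        terms = table.index != "Residual"
        table.loc[terms, "F"] = 0.0
        table.loc[terms, "PR(>F)"] = 1.0
    else:
        zero_terms = np.isclose(table["sum_sq"], 0.0, atol=1e-12)
        table.loc[zero_terms & table["F"].isna(), "PR(>F)"] = 1.0
        table.loc[zero_terms & table["F"].isna(), "F"] = 0.0
    table = table.rename(columns={"PR(>F)": "p"})
    table.attrs["transform_applied"] = applied
    return table


# ---------------------------------------------------------------------------
# one-way ANOVA + LSD compact letters
# ---------------------------------------------------------------------------

def oneway_lsd(y, groups, alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA followed by Fisher's LSD with compact letter display.

    Pairwise comparisons use pooled-MSE two-sided t tests on the residual df.
    Letters are built from the maximal cliques of the "not significantly
    different" graph, so two treatments share a letter iff their pairwise LSD
    p >= alpha; groups are ordered by descending mean and the highest-mean
    clique gets 'a'. Returns a DataFrame (group, n, mean, se, letters) in
    descending-mean order.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if len(y) != len(groups):
        raise ValueError("y and groups must have equal length")
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    data = {g: y[groups == g] for g in labels}
    ns = {g: len(v) for g, v in data.items()}
    if min(ns.values()) < 2:
        raise ValueError("need at least 2 replicates per group")
    n_total = len(y)
    df_resid = n_total - len(labels)
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    means = {g: float(v.mean()) for g, v in data.items()}
    sse = sum(float(((v - means[g]) ** 2).sum()) for g, v in data.items())
    mse = sse / df_resid

    order = sorted(labels, key=lambda g: -means[g])
    nsd = nx.Graph()
    nsd.add_nodes_from(order)
    for a_i, ga in enumerate(order):
        for gb in order[a_i + 1 :]:
            if mse == 0.0:
                p = 1.0 if means[ga] == means[gb] else 0.0
            else:
                se_diff = np.sqrt(mse * (1.0 / ns[ga] + 1.0 / ns[gb]))
                tstat = (means[ga] - means[gb]) / se_diff
                p = 2.0 * scipy.stats.t.sf(abs(tstat), df_resid)
            if p >= alpha:
                nsd.add_edge(ga, gb)

    rank = {g: i for i, g in enumerate(order)}
    cliques = sorted(
        (sorted(c, key=lambda g: rank[g]) for c in nx.find_cliques(nsd)),
        key=lambda c: [rank[g] for g in c],
    )
    letters: dict[str, list[str]] = {g: [] for g in order}
    for k, clique in enumerate(cliques):
        letter = chr(ord("a") + k) if k < 26 else f"z{k}"
        for g in clique:
            letters[g].append(letter)
    rows = [
        {
            "group": g,
            "n": ns[g],
            "mean": means[g],
            "se": float(data[g].std(ddof=1) / np.sqrt(ns[g])),
            "letters": "".join(sorted(letters[g])),
        }
        for g in order
    ]
    out = pd.DataFrame(rows).set_index("group")
    out.attrs["alpha"] = alpha
    out.attrs["mse"] = mse
    out.attrs["df_resid"] = df_resid
    return out


# ---------------------------------------------------------------------------
# marginal percent change
# ---------------------------------------------------------------------------

def percent_change(data: pd.DataFrame, factor: str, variables=None) -> pd.DataFrame:
    """Marginal percent change of each variable for one factor.

    ``data`` holds per-sample values with binary W/N/P columns. The estimate
    is 100 x (mean over +factor samples - mean over -factor samples) / the
    -factor mean; NaN with a note when the -factor mean is zero.
    """
    if factor not in FACTORS:
        raise ValueError(f"factor must be one of {FACTORS}, got {factor!r}")
    if factor not in data.columns:
        raise ValueError(f"data lacks a {factor!r} column")
    if variables is None:
        variables = [
            c
            for c in data.columns
            if c not in (*FACTORS, "block", "treatment")
            and pd.api.types.is_numeric_dtype(data[c])
        ]
    plus = data[data[factor] == 1]
    minus = data[data[factor] == 0]
    rows = []
    for var in variables:
        m_plus = float(plus[var].mean())
        m_minus = float(minus[var].mean())
        pct = 100.0 * (m_plus - m_minus) / m_minus if m_minus != 0 else np.nan
        rows.append(
            {
                "factor": factor,
                "variable": var,
                "mean_plus": m_plus,
                "mean_minus": m_minus,
                "percent_change": pct,
            }
        )
    return pd.DataFrame(rows)


def percent_change_from_means(
    means: pd.DataFrame, factor: str, variables=None
) -> pd.DataFrame:
    """Marginal percent change computed from per-treatment means.

    ``means`` is indexed by variable with one column per treatment label
    (C, W, N, P, WN, WP, NP, WNP). With a balanced design this equals the
    per-sample marginal estimate: the four treatments containing ``factor``
    are averaged against the four that do not.
    """
    if factor not in FACTORS:
        raise ValueError(f"factor must be one of {FACTORS}, got {factor!r}")
    plus_cols = [c for c in means.columns if factor in c]
    minus_cols = [c for c in means.columns if factor not in c]
    if len(plus_cols) != 4 or len(minus_cols) != 4:
        raise ValueError("means must have the 8 factorial treatment columns")
    variables = list(variables) if variables is not None else list(means.index)
    rows = []
    for var in variables:
        m_plus = float(means.loc[var, plus_cols].mean())
        m_minus = float(means.loc[var, minus_cols].mean())
        pct = 100.0 * (m_plus - m_minus) / m_minus if m_minus != 0 else np.nan
        rows.append(
            {
                "factor": factor,
                "variable": var,
                "mean_plus": m_plus,
                "mean_minus": m_minus,
                "percent_change": pct,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distances and Mantel
# ---------------------------------------------------------------------------

def bray_curtis(table) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix between samples.

    d(u, v) = sum|u_i - v_i| / sum(u_i + v_i); symmetric with zero diagonal,
    values in [0, 1]. Accepts an OtuTable or a samples x taxa DataFrame.
    """
    counts = table.counts if isinstance(table, OtuTable) else pd.DataFrame(table)
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=1) == 0).any():
        raise ValueError("Bray-Curtis undefined for all-zero samples")
    dist = squareform(pdist(arr, metric="braycurtis"))
    return pd.DataFrame(dist, index=counts.index, columns=counts.index)


def env_distance(env: pd.DataFrame, variables=None) -> pd.DataFrame:
    """Euclidean distance between samples on z-scored environmental variables."""
    sub = env[list(variables)] if variables is not None else env
    z = (sub - sub.mean()) / sub.std(ddof=1).replace(0.0, 1.0)
    dist = squareform(pdist(z.to_numpy(), metric="euclidean"))
    return pd.DataFrame(dist, index=env.index, columns=env.index)


@dataclass(frozen=True)
class MantelResult:
    """Mantel correlation between two distance matrices."""

    r: float
    p: float
    permutations: int
    method: str
    seed: int | None = None


def mantel(
    dist_a,
    dist_b,
    method: str = "spearman",
    permutations: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Mantel test between two square symmetric distance matrices.

    r correlates the upper-triangle entries (Spearman by default, Pearson
    optional). The one-sided pseudo p-value permutes the rows and columns of
    the second matrix jointly: p = (1 + #{r_perm >= r_obs}) / (1 + B).
    """
    a = dist_a.to_numpy() if isinstance(dist_a, pd.DataFrame) else np.asarray(dist_a, float)
    b = dist_b.to_numpy() if isinstance(dist_b, pd.DataFrame) else np.asarray(dist_b, float)
    check_square_symmetric(a, "dist_a")
    check_square_symmetric(b, "dist_b")
    if a.shape != b.shape:
        raise ValueError(f"distance matrices differ in size: {a.shape} vs {b.shape}")
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    n = a.shape[0]
    iu = np.triu_indices(n, 1)
    if np.ptp(a[iu]) == 0 or np.ptp(b[iu]) == 0:
        # a constant distance vector carries no rank information
        return MantelResult(
            r=float("nan"), p=float("nan"), permutations=permutations,
            method=method, seed=seed,
        )

    def corr(x, y):
        if method == "spearman":
            return float(scipy.stats.spearmanr(x, y).statistic)
        return float(scipy.stats.pearsonr(x, y).statistic)

    r_obs = corr(a[iu], b[iu])
    rng = as_rng(seed)
    count = 0
    for _ in range(permutations):
        idx = rng.permutation(n)
        bp = b[np.ix_(idx, idx)]
        if corr(a[iu], bp[iu]) >= r_obs:
            count += 1
    p = (1.0 + count) / (1.0 + permutations)
    return MantelResult(r=r_obs, p=p, permutations=permutations, method=method, seed=seed)
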