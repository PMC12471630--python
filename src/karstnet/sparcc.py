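"""SparCC: compositionality-robust correlation inference for OTU counts.

Sequencing counts carry only relative-abundance information, so naive
correlations between taxa are confounded by the unit-sum constraint. SparCC
works on log-ratio variances t_ij = Var[log(x_i/x_j)], which are invariant to
the closure, and inverts the decomposition

    t_ij = w_i + w_j - 2 rho_ij sqrt(w_i w_j)

under a sparsity assumption (most rho_ij ~ 0) to recover basis variances w
of the latent absolute abundances and basis correlations rho. Counts are
converted to strictly positive fractions by Dirichlet resampling (counts + 1),
repeated R times, and the estimate is the element-wise median. Strongly
correlated pairs are iteratively excluded from the linear system so they do
not bias the basis variances. Significance is assessed with bootstrap pseudo
p-values from per-taxon permutations.

The estimator is exposed both as plain functions and as a model object:
``SparCC(table).fit()`` returns a :class:`SparccResults` carrying the
correlation matrix, basis variances, exclusion log and bootstrap machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import as_rng, check_square_symmetric, derive_seed
from .otu import OtuTable

__all__ = [
    "SparccParams",
    "EmptyFilterError",
    "filter_otus",
    "to_fractions",
    "logratio_variance",
    "estimate_basis",
    "sparcc",
    "bootstrap_pvalues",
    "SparCC",
    "SparccResults",
]

#: floor applied to negative basis-variance solutions
OMEGA_FLOOR = 1e-6


class EmptyFilterError(ValueError):
    """Raised when abundance filtering removes every taxon."""


@dataclass(frozen=True)
class SparccParams:
    """Tuning parameters of the SparCC procedure.

    dirichlet_resamples
        R, number of Dirichlet posterior draws aggregated by median.
    exclusion_iterations / exclusion_threshold
        E and x of the iterative strong-pair exclusion: per iteration the
        not-yet-excluded pair with the largest |rho| is removed from the basis
        solve if |rho| > x; at most E iterations.
    bootstrap_count
        B, permutation bootstraps for pseudo p-values (minimum p = 1/(B+1)).
    bootstrap_resamples
        reduced R used inside each bootstrap replicate.
    min_total_abundance
        abundance filter: keep taxa with total count strictly greater.
    """

    dirichlet_resamples: int = 20
    exclusion_iterations: int = 10
    exclusion_threshold: float = 0.1
    bootstrap_count: int = 100
    bootstrap_resamples: int = 5
    min_total_abundance: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dirichlet_resamples < 1:
            raise ValueError("dirichlet_resamples must be >= 1")
        if self.exclusion_iterations < 0:
            raise ValueError("exclusion_iterations must be >= 0")
        if not 0 < self.exclusion_threshold < 1:
            raise ValueError("exclusion_threshold must be in (0, 1)")
        if self.bootstrap_count < 1:
            raise ValueError("bootstrap_count must be >= 1")
        if self.min_total_abundance < 0:
            raise ValueError("min_total_abundance must be >= 0")


# ---------------------------------------------------------------------------
# filtering and fractions
# ---------------------------------------------------------------------------

def filter_otus(table: OtuTable, min_total: int = 400) -> OtuTable:
    """Keep taxa whose total count over all samples is strictly > ``min_total``.

    The low-abundance filter applied before correlation inference; the sample
    set is unchanged. Raises :class:`EmptyFilterError` if nothing survives.
    """
    if table.n_samples < 1:
        raise ValueError("table has no samples")
    totals = table.taxon_totals()
    keep = totals.index[totals > min_total]
    if len(keep) == 0:
        raise EmptyFilterError(
            f"no taxa with total abundance > {min_total} (max total {totals.max()})"
        )
    return table.select_taxa(keep)


def to_fractions(counts, seed=None, row_keys=None) -> np.ndarray:
    """Dirichlet-resample counts into strictly positive fractions.

    Each sample's fraction vector is one draw from Dirichlet(counts + 1), the
    posterior under a uniform prior. When ``row_keys`` is given, each row uses
    its own generator seeded from (seed, key), which makes the draw for a
    sample independent of the ordering of samples in the table.
    """
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    alpha = arr + 1.0
    if row_keys is not None:
        if len(row_keys) != arr.shape[0]:
            raise ValueError("row_keys length must match number of rows")
        gammas = np.vstack(
            [
                as_rng(derive_seed(seed if seed is not None else 0, str(k))).standard_gamma(alpha[i])
                for i, k in enumerate(row_keys)
            ]
        )
    else:
        gammas = as_rng(seed).standard_gamma(alpha)
    return gammas / gammas.sum(axis=1, keepdims=True)


def logratio_variance(fractions) -> np.ndarray:
    """Variation matrix t_ij = sample variance (ddof=1) of log(x_i/x_j)."""
    frac = np.asarray(fractions, dtype=float)
    if frac.shape[0] < 2:
        raise ValueError("need at least 2 samples for log-ratio variances")
    if (frac <= 0).any():
        raise ValueError("fractions must be strictly positive")
    logf = np.log(frac)
    cov = np.cov(logf, rowvar=False, ddof=1)
    var = np.diag(cov)
    t = var[:, None] + var[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    return np.clip((t + t.T) / 2.0, 0.0, None)


# ---------------------------------------------------------------------------
# basis decomposition
# ---------------------------------------------------------------------------

def _solve_omega(t: np.ndarray, exclusions: set[tuple[int, int]]) -> np.ndarray:
    """Solve the SparCC linear system M w = t_row for the basis variances.

    Without exclusions M = (D-2) I + 1 1^T and t_row_i = sum_j t_ij. Each
    excluded pair (i, j) drops t_ij from rows i and j, which removes one w_i
    and one w_j term: M_ii, M_jj, M_ij and M_ji all decrement by 1.
    """
    D = t.shape[0]
    M = np.ones((D, D)) + (D - 2.0) * np.eye(D)
    t_row = t.sum(axis=1)
    for i, j in exclusions:
        t_row[i] -= t[i, j]
        t_row[j] -= t[i, j]
        M[i, i] -= 1.0
        M[j, j] -= 1.0
        M[i, j] -= 1.0
        M[j, i] -= 1.0
    try:
        omega = np.linalg.solve(M, t_row)
    except np.linalg.LinAlgError as err:  # pragma: no cover - guarded upstream
        raise np.linalg.LinAlgError(
            f"singular SparCC system (D={D}, {len(exclusions)} exclusions): {err}"
        ) from err
    return np.maximum(omega, OMEGA_FLOOR)


def _rho_from_omega(t: np.ndarray, omega: np.ndarray) -> np.ndarray:
    denom = 2.0 * np.sqrt(np.outer(omega, omega))
    rho = (omega[:, None] + omega[None, :] - t) / denom
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def estimate_basis(
    t: np.ndarray, exclusions: set[tuple[int, int]] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Basis variances w and correlations rho from a variation matrix.

    ``exclusions`` is a set of (i, j) pairs left out of the basis solve;
    rho is still reported for every pair from the solved variances. Negative
    variance solutions are floored at 1e-6; rho is clipped to [-1, 1].
    """
    t = np.asarray(t, dtype=float)
    check_square_symmetric(t, "variation matrix")
    if t.shape[0] < 4:
        raise ValueError(f"SparCC basis solve needs >= 4 taxa, got {t.shape[0]}")
    exclusions = {(min(i, j), max(i, j)) for i, j in (exclusions or set())}
    omega = _solve_omega(t, exclusions)
    return omega, _rho_from_omega(t, omega)


def _basis_with_exclusion_iterations(
    t: np.ndarray, max_iterations: int, threshold: float
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """One resample's estimate: solve, then iteratively exclude strong pairs.

    Per iteration the not-yet-excluded off-diagonal pair with the largest
    |rho| is excluded (if above ``threshold``) and the system re-solved.
    Taxa appearing in >= D-3 excluded pairs are dropped from the solve (their
    estimates become NaN for this resample) to keep the system well posed.
    """
    D = t.shape[0]
    active = np.ones(D, dtype=bool)
    excluded: list[tuple[int, int]] = []
    excl_count = np.zeros(D, dtype=int)

    def solve_active():
        idx = np.flatnonzero(active)
        sub_t = t[np.ix_(idx, idx)]
        pos = {g: k for k, g in enumerate(idx)}
        sub_excl = {
            (pos[i], pos[j]) for i, j in excluded if active[i] and active[j]
        }
        omega_sub = _solve_omega(sub_t, sub_excl)
        omega = np.full(D, np.nan)
        omega[idx] = omega_sub
        rho = np.full((D, D), np.nan)
        rho[np.ix_(idx, idx)] = _rho_from_omega(sub_t, omega_sub)
        return omega, rho

    omega, rho = solve_active()
    for _ in range(max_iterations):
        if active.sum() < 4:
            break
        mask = np.abs(rho.copy())
        np.fill_diagonal(mask, np.nan)
        for i, j in excluded:
            mask[i, j] = mask[j, i] = np.nan
        if np.all(np.isnan(mask)):
            break
        i, j = np.unravel_index(np.nanargmax(mask), mask.shape)
        if mask[i, j] <= threshold:
            break
        pair = (min(i, j), max(i, j))
        excluded.append(pair)
        excl_count[list(pair)] += 1
        drop = np.flatnonzero(active & (excl_count >= max(D - 3, 1)))
        if len(drop):
            warnings.warn(
                f"dropping taxa {drop.tolist()} from basis solve "
                "(involved in too many excluded pairs)",
                RuntimeWarning,
                stacklevel=2,
            )
            active[drop] = False
            if active.sum() < 4:
                break
        omega, rho = solve_active()
    return omega, rho, excluded


def _sparcc_core(
    counts: np.ndarray,
    resamples: int,
    exclusion_iterations: int,
    exclusion_threshold: float,
    seed: int,
    row_keys=None,
) -> tuple[np.ndarray, np.ndarray, list[list[tuple[int, int]]]]:
    """Median-aggregated SparCC estimate on a raw count matrix."""
    D = counts.shape[1]
    rhos = np.empty((resamples, D, D))
    omegas = np.empty((resamples, D))
    log: list[list[tuple[int, int]]] = []
    for r in range(resamples):
        frac = to_fractions(counts, seed=derive_seed(seed, "dirichlet", r), row_keys=row_keys)
        t = logratio_variance(frac)
        omega, rho, excluded = _basis_with_exclusion_iterations(
            t, exclusion_iterations, exclusion_threshold
        )
        rhos[r] = rho
        omegas[r] = omega
        log.append(excluded)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        rho_med = np.nanmedian(rhos, axis=0)
        omega_med = np.nanmedian(omegas, axis=0)
    rho_med = np.nan_to_num(rho_med, nan=0.0)
    rho_med = np.clip((rho_med + rho_med.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho_med, 1.0)
    omega_med = np.nan_to_num(omega_med, nan=OMEGA_FLOOR)
    return rho_med, omega_med, log


def _counts_and_labels(table) -> tuple[np.ndarray, list[str], list[str] | None]:
    if isinstance(table, OtuTable):
        return table.counts.to_numpy(), table.taxa, table.samples
    arr = np.asarray(table)
    return arr, [f"T{k}" for k in range(arr.shape[1])], None


def sparcc(table, params: SparccParams | None = None) -> "SparccResults":
    """Estimate SparCC correlations on an (already filtered) OTU table."""
    params = params or SparccParams()
    counts, taxa, samples = _counts_and_labels(table)
    if counts.shape[1] < 4:
        raise ValueError(f"SparCC needs >= 4 taxa, got {counts.shape[1]}")
    rho, omega, log = _sparcc_core(
        counts,
        params.dirichlet_resamples,
        params.exclusion_iterations,
        params.exclusion_threshold,
        params.seed,
        row_keys=samples,
    )
    return SparccResults(
        rho=pd.DataFrame(rho, index=taxa, columns=taxa),
        omega=pd.Series(omega, index=taxa, name="basis_variance"),
        exclusion_log=log,
        params=params,
        table=table if isinstance(table, OtuTable) else None,
        _counts=counts,
    )


def bootstrap_pvalues(table, rho_obs, params: SparccParams | None = None) -> pd.DataFrame:
    """Permutation-bootstrap pseudo p-values for observed SparCC correlations.

    Each bootstrap replicate permutes every taxon's counts independently
    across samples — destroying inter-taxon association while preserving each
    taxon's marginal distribution — and re-estimates the correlation matrix
    with a reduced number of Dirichlet resamples. The pseudo p-value uses the
    add-one rule p = (1 + #{|rho_b| >= |rho_obs|}) / (1 + B), so the smallest
    attainable value is 1/(B+1); the diagonal is reported as 1.
    """
    params = params or SparccParams()
    counts, taxa, _ = _counts_and_labels(table)
    rho_arr = rho_obs.to_numpy() if isinstance(rho_obs, pd.DataFrame) else np.asarray(rho_obs)
    if rho_arr.shape != (counts.shape[1], counts.shape[1]):
        raise ValueError("rho_obs shape does not match the table's taxa")
    B = params.bootstrap_count
    exceed = np.zeros_like(rho_arr)
    abs_obs = np.abs(rho_arr)
    for b in range(B):
        child = derive_seed(params.seed, "bootstrap", b)
        perm = as_rng(child).permuted(counts, axis=0)
        rho_b, _, _ = _sparcc_core(
            perm,
            params.bootstrap_resamples,
            params.exclusion_iterations,
            params.exclusion_threshold,
            derive_seed(child, "estimate"),
        )
        exceed += np.abs(rho_b) >= abs_obs
    pvals = (1.0 + exceed) / (1.0 + B)
    pvals = np.minimum(pvals, 1.0)
    pvals = (pvals + pvals.T) / 2.0
    np.fill_diagonal(pvals, 1.0)
    return pd.DataFrame(pvals, index=taxa, columns=taxa)


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

@dataclass
class SparccResults:
    """Fitted SparCC estimate: correlations, basis variances, diagnostics."""

    rho: pd.DataFrame
    omega: pd.Series
    exclusion_log: list[list[tuple[int, int]]]
    params: SparccParams
    table: OtuTable | None = None
    _counts: np.ndarray | None = None
    _pvalues: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_taxa(self) -> int:
        return self.rho.shape[0]

    def pvalues(self, bootstrap_count: int | None = None) -> pd.DataFrame:
        """Bootstrap pseudo p-values (computed on first access, then cached)."""
        if self._pvalues is None:
            params = self.params
            if bootstrap_count is not None:
                params = replace(params, bootstrap_count=bootstrap_count)
            source = self.table if self.table is not None else self._counts
            self._pvalues = bootstrap_pvalues(source, self.rho, params)
        return self._pvalues

    def summary(self, r_threshold: float = 0.6) -> str:
        off = self.rho.to_numpy()[np.triu_indices(self.n_taxa, 1)]
        lines = [
            "SparCC correlation estimate",
            "=" * 40,
            f"taxa:                  {self.n_taxa}",
            f"dirichlet resamples:   {self.params.dirichlet_resamples}",
            f"exclusion iterations:  {self.params.exclusion_iterations}"
            f" (threshold {self.params.exclusion_threshold})",
            f"median basis variance: {float(np.median(self.omega)):.4f}",
            f"|rho| >= {r_threshold:.2f} pairs:   {int((np.abs(off) >= r_threshold).sum())}"
            f" of {off.size}",
            f"max |rho|:             {float(np.abs(off).max()):.4f}",
        ]
        return "\n".join(lines)

    def write(self, rho_path, pvals_path=None) -> None:
        self.rho.to_csv(rho_path, sep="\t", float_format="%.10g")
        if pvals_path is not None:
            self.pvalues().to_csv(pvals_path, sep="\t", float_format="%.10g")


class SparCC:
    """SparCC correlation model over an OTU count table.

    Statsmodels-style entry point: construct from data (optionally filtering
    low-abundance taxa), then :meth:`fit` to obtain :class:`SparccResults`.

    >>> model = SparCC(table, min_total=400, seed=1)
    >>> res = model.fit()
    >>> res.rho          # doctest: +SKIP
    """

    def __init__(
        self,
        table: OtuTable,
        params: SparccParams | None = None,
        min_total: int | None = None,
        **overrides,
    ) -> None:
        params = params or SparccParams()
        if overrides:
            params = replace(params, **overrides)
        if min_total is not None:
            params = replace(params, min_total_abundance=min_total)
        self.params = params
        self.raw_table = table
        self.table = filter_otus(table, params.min_total_abundance)

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, **kwargs) -> "SparCC":
        return cls(OtuTable(counts), **kwargs)

    def fit(self) -> SparccResults:
        return sparcc(self.table, self.params)
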