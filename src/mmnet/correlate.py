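"""The three correlation layers of the co-occurrence analysis.

* **MM** (microbe-microbe): SparCC, which estimates correlations of the
  latent *basis* abundances from log-ratio variances and so avoids the
  negative bias that closure to relative abundances induces in naive
  correlations on sparse compositions.
* **TT** (metabolite-metabolite): Spearman rank correlation.
* **MT** (microbe-metabolite): Spearman computed from ranks taken within
  each modality's own table.

Spearman p-values are exact (full permutation enumeration) for n <= 7
— which covers six-animal groups — and use the t approximation beyond
that. SparCC p-values come from permutation of sample labels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tables import FeatureTable

EXACT_PERMUTATION_MAX_N = 7

LAYER_MM = "MM"
LAYER_TT = "TT"
LAYER_MT = "MT"
LAYERS = (LAYER_MM, LAYER_TT, LAYER_MT)


@dataclass
class CorrelationSet:
    """Typed pairwise correlation records for one layer (or several).

    ``records`` columns: feature_a, feature_b, layer, rho, p, method.
    Unordered pairs are stored once (feature_a < feature_b for
    within-layer pairs; microbe first for MT).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["feature_a", "feature_b", "layer", "rho", "p", "method"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise ValueError(f"CorrelationSet missing column(s): {missing}")
        rec = self.records
        if (rec["feature_a"] == rec["feature_b"]).any():
            raise ValueError("self-correlation record (feature_a == feature_b)")
        bad_layer = set(rec["layer"]) - set(LAYERS)
        if bad_layer:
            raise ValueError(f"unknown layer(s): {bad_layer}")
        keys = rec.apply(
            lambda r: (r["layer"], *sorted((r["feature_a"], r["feature_b"]))), axis=1
        )
        if keys.duplicated().any():
            raise ValueError("duplicate unordered pair within a layer")
        finite = rec["rho"].dropna()
        if (finite.abs() > 1 + 1e-9).any():
            raise ValueError("|rho| must be <= 1")

    def significant(self, p_threshold: float = 0.05, use_bh: bool = False) -> pd.DataFrame:
        """Records admitted at the threshold (optionally BH-adjusted per layer)."""
        rec = self.records.dropna(subset=["rho", "p"])
        if use_bh:
            from statsmodels.stats.multitest import multipletests

            parts = []
            for _, grp in rec.groupby("layer"):
                grp = grp.copy()
                grp["q"] = multipletests(grp["p"].to_numpy(), method="fdr_bh")[1]
                parts.append(grp)
            rec = pd.concat(parts) if parts else rec.assign(q=[])
            return rec[rec["q"] <= p_threshold]
        return rec[rec["p"] <= p_threshold]

    @staticmethod
    def concat(sets) -> "CorrelationSet":
        frames = [s.records for s in sets]
        return CorrelationSet(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(permutations(range(n))), dtype=np.intp)


@lru_cache(maxsize=None)
def _exact_null_abs_rho(rx_key: tuple, ry_key: tuple) -> np.ndarray:
    """Sorted |rho| null distribution over all pairings of two rank multisets."""
    rx = np.array(rx_key, dtype=float)
    ry = np.array(ry_key, dtype=float)
    n = rx.size
    perms = _perm_matrix(n)
    rxc = rx - rx.mean()
    ryp = ry[perms] - ry.mean()
    denom = math.sqrt((rxc**2).sum()) * math.sqrt(((ry - ry.mean()) ** 2).sum())
    rhos = (ryp @ rxc) / denom
    return np.sort(np.abs(rhos))


def _exact_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    key_x = tuple(np.round(np.sort(rx), 6))
    key_y = tuple(np.round(np.sort(ry), 6))
    null = _exact_null_abs_rho(key_x, key_y)
    count = null.size - np.searchsorted(null, abs(rho) - 1e-9, side="left")
    return float(count / null.size)


def _t_approx_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return float(np.finfo(float).tiny)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(max(2.0 * sps.t.sf(abs(t), n - 2), np.finfo(float).tiny))


def spearman(x, y, exact: bool | None = None) -> tuple[float, float]:
    """Spearman rho (average ranks under ties) with a two-sided p-value.

    ``exact=None`` picks full permutation enumeration for n <= 7 and the
    t approximation otherwise. Zero-variance input yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    if rx.std() == 0 or ry.std() == 0:
        return (float("nan"), float("nan"))
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if exact is None:
        exact = n <= EXACT_PERMUTATION_MAX_N
    if exact:
        if n > 10:
            raise ValueError("exact enumeration limited to n <= 10")
        return rho, _exact_p(rx, ry, rho)
    return rho, _t_approx_p(rho, n)


def _rank_rows(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 1, values)


def _spearman_matrices(
    ranks_a: np.ndarray, ranks_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rho and p matrices between two row-rank matrices (shared samples)."""
    n = ranks_a.shape[1]
    sa = ranks_a.std(axis=1)
    sb = ranks_b.std(axis=1)
    za = (ranks_a - ranks_a.mean(axis=1, keepdims=True))
    zb = (ranks_b - ranks_b.mean(axis=1, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (za @ zb.T) / (n * np.outer(sa, sb))
    rho = np.clip(rho, -1.0, 1.0)
    rho[sa == 0, :] = np.nan
    rho[:, sb == 0] = np.nan

    p = np.full_like(rho, np.nan)
    if n <= EXACT_PERMUTATION_MAX_N:
        for i in range(ranks_a.shape[0]):
            if sa[i] == 0:
                continue
            for j in range(ranks_b.shape[0]):
                if sb[j] == 0:
                    continue
                p[i, j] = _exact_p(ranks_a[i], ranks_b[j], rho[i, j])
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * sps.t.sf(np.abs(t), n - 2)
        p[np.abs(rho) >= 1.0] = np.finfo(float).tiny
        p = np.maximum(p, np.finfo(float).tiny)
        p[np.isnan(rho)] = np.nan
    return rho, p


def _pairs_frame(
    rho: np.ndarray,
    p: np.ndarray,
    ids_a,
    ids_b,
    layer: str,
    method: str,
    symmetric: bool,
) -> CorrelationSet:
    rows = []
    for i, fa in enumerate(ids_a):
        start = i + 1 if symmetric else 0
        for j in range(start, len(ids_b)):
            rows.append((fa, ids_b[j], layer, rho[i, j], p[i, j], method))
    return CorrelationSet(
        pd.DataFrame(rows, columns=["feature_a", "feature_b", "layer", "rho", "p", "method"])
    )


def metabolite_spearman(table: FeatureTable) -> CorrelationSet:
    """All-pairs Spearman correlations within a metabolite table (layer TT)."""
    ranks = _rank_rows(table.values.to_numpy(dtype=float))
    rho, p = _spearman_matrices(ranks, ranks)
    return _pairs_frame(
        rho, p, table.feature_ids, table.feature_ids, LAYER_TT, "spearman", symmetric=True
    )


def cross_modal_spearman(
    microbes: FeatureTable, metabolites: FeatureTable
) -> CorrelationSet:
    """Microbe x metabolite Spearman correlations (layer MT).

    Ranks are computed within each modality's own table and correlated
    pairwise; both tables must cover exactly the same samples.
    """
    sa, sb = set(microbes.sample_ids), set(metabolites.sample_ids)
    if sa != sb:
        raise ValueError(
            "sample sets differ between tables; "
            f"only in microbes: {sorted(sa - sb)}, only in metabolites: {sorted(sb - sa)}"
        )
    order = microbes.sample_ids
    ranks_m = _rank_rows(microbes.values.to_numpy(dtype=float))
    ranks_t = _rank_rows(metabolites.values.loc[:, order].to_numpy(dtype=float))
    rho, p = _spearman_matrices(ranks_m, ranks_t)
    return _pairs_frame(
        rho, p, microbes.feature_ids, metabolites.feature_ids, LAYER_MT,
        "spearman_cross_modal", symmetric=False,
    )


# ---------------------------------------------------------------------------
# SparCC
# ---------------------------------------------------------------------------

@dataclass
class SparCCState:
    """Internals of one SparCC fit, for inspection and debugging.

    ``t_matrix`` holds the log-ratio variances t_ij = var(log(x_i/x_j))
    of the observed fractions; ``basis_variances`` the solved basis
    variances omega_i^2; ``excluded_pairs`` the strongly correlated
    pairs removed from the sparsity approximation.
    """

    t_matrix: pd.DataFrame
    basis_variances: pd.Series
    excluded_pairs: list = field(default_factory=list)
    n_resamples: int = 20
    exclusion_threshold: float = 0.1
    exclusion_iterations: int = 0
    seed: int | None = None


def _log_ratio_variances(fractions: np.ndarray) -> np.ndarray:
    """t_ij = var(log(x_i / x_j)) across samples; fractions are (d, n)."""
    logf = np.log(fractions)
    cov = np.cov(logf)
    var = np.diag(cov)
    return var[:, None] + var[None, :] - 2.0 * cov


def _solve_basis(
    t: np.ndarray, threshold: float, max_exclusions: int
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]], int]:
    """Solve basis variances under the sparsity approximation.

    Row sums of t satisfy (d-2) * w_i^2 + sum_j w_j^2 = sum_j t_ij when
    basis correlations are sparse; strongly correlated pairs violate the
    approximation, so the strongest |rho| pair above ``threshold`` is
    iteratively dropped from the equations and the system re-solved.
    Returns (rho, omega_sq, excluded pairs, iterations).
    """
    d = t.shape[0]
    include = np.ones((d, d), dtype=bool)
    np.fill_diagonal(include, False)
    excluded: list[tuple[int, int]] = []
    rho = np.full((d, d), np.nan)
    iterations = 0
    while True:
        m = include.astype(float) + np.diag(include.sum(axis=1).astype(float))
        rowsum = (t * include).sum(axis=1)
        try:
            omega_sq = np.linalg.solve(m, rowsum)
        except np.linalg.LinAlgError:
            omega_sq = np.linalg.lstsq(m, rowsum, rcond=None)[0]
        valid = omega_sq > 0
        omega = np.sqrt(np.where(valid, omega_sq, np.nan))
        with np.errstate(invalid="ignore"):
            rho = (omega_sq[:, None] + omega_sq[None, :] - t) / (
                2.0 * np.outer(omega, omega)
            )
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        rho[~valid, :] = np.nan
        rho[:, ~valid] = np.nan
        np.fill_diagonal(rho, 1.0)

        if iterations >= max_exclusions:
            break
        cand = np.abs(np.where(include, rho, np.nan))
        # keep each feature in at least 3 equations so the system stays solvable
        deg = include.sum(axis=1)
        cand[deg <= 3, :] = np.nan
        cand[:, deg <= 3] = np.nan
        if np.all(np.isnan(cand)) or np.nanmax(cand) <= threshold:
            break
        i, j = np.unravel_index(np.nanargmax(cand), cand.shape)
        include[i, j] = include[j, i] = False
        excluded.append((min(i, j), max(i, j)))
        iterations += 1
    return rho, omega_sq, excluded, iterations


def _closure(values: np.ndarray) -> np.ndarray:
    sums = values.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("sample with zero total abundance")
    return values / sums


def _sparcc_rho_once(
    counts: np.ndarray,
    rng: np.random.Generator,
    n_resamples: int,
    threshold: float,
    x_iter: int,
) -> np.ndarray:
    """Median SparCC rho over Dirichlet resamplings of one count matrix."""
    d, n = counts.shape
    rhos = np.empty((n_resamples, d, d)) if n_resamples else None
    if n_resamples == 0:
        fractions = _closure(counts + 0.5)  # pseudo-count resolves zeros
        rho, _, _, _ = _solve_basis(
            _log_ratio_variances(fractions), threshold, x_iter
        )
        return rho
    for r in range(n_resamples):
        fractions = np.column_stack(
            [rng.dirichlet(counts[:, j] + 1.0) for j in range(n)]
        )
        rho, _, _, _ = _solve_basis(
            _log_ratio_variances(fractions), threshold, x_iter
        )
        rhos[r] = rho
    with warnings.catch_warnings():
        # features degenerate in every resample stay NaN by design
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(rhos, axis=0)


def sparcc(
    table: FeatureTable,
    n_resamples: int = 20,
    exclusion_threshold: float = 0.1,
    x_iter: int = 10,
    n_permutations: int = 100,
    pseudo_count_scale: float = 1e4,
    seed: int = 0,
) -> tuple[CorrelationSet, SparCCState]:
    """SparCC microbe-microbe correlations (layer MM).

    The input (fractions or counts) is closed to fractions and converted
    to pseudo-counts (``round(fraction * pseudo_count_scale)``), which
    makes the estimate exactly invariant to per-sample count scaling.
    Per resampling round, compositions are drawn from
    Dirichlet(counts + 1) to resolve zeros, log-ratio variances are
    computed, basis variances solved under the sparsity approximation
    with iterative exclusion of the strongest pair above the threshold,
    and the final rho is the element-wise median across rounds.
    p-values are two-sided permutation p's from shuffling each feature's
    samples independently (``n_permutations`` times; set 0 to skip,
    leaving p = NaN).
    """
    vals = table.values.to_numpy(dtype=float)
    d, n = vals.shape
    if d < 4:
        raise ValueError("SparCC needs at least 4 features (basis solve requires d > 3)")
    if n < 4:
        raise ValueError("SparCC needs at least 4 samples")
    rng = np.random.default_rng(seed)
    counts = np.round(_closure(vals) * pseudo_count_scale)

    rho = _sparcc_rho_once(counts, rng, n_resamples, exclusion_threshold, x_iter)

    p = np.full((d, d), np.nan)
    if n_permutations > 0:
        exceed = np.zeros((d, d))
        n_valid = np.zeros((d, d))
        for _ in range(n_permutations):
            perm = counts.copy()
            for i in range(d):
                perm[i] = perm[i, rng.permutation(n)]
            rho_perm = _sparcc_rho_once(
                perm, rng, n_resamples, exclusion_threshold, x_iter
            )
            with np.errstate(invalid="ignore"):
                hit = np.abs(rho_perm) >= np.abs(rho) - 1e-12
            ok = ~np.isnan(rho_perm) & ~np.isnan(rho)
            exceed += np.where(ok & hit, 1.0, 0.0)
            n_valid += ok
        with np.errstate(divide="ignore", invalid="ignore"):
            p = (1.0 + exceed) / (1.0 + n_valid)
        p[n_valid == 0] = np.nan
        p[np.isnan(rho)] = np.nan

    # state diagnostics computed on the observed (un-resampled) fractions
    fractions = _closure(counts + 0.5)
    t = _log_ratio_variances(fractions)
    _, omega_sq, excluded, iters = _solve_basis(t, exclusion_threshold, x_iter)
    ids = table.feature_ids
    state = SparCCState(
        t_matrix=pd.DataFrame(t, index=ids, columns=ids),
        basis_variances=pd.Series(omega_sq, index=ids, name="omega_sq"),
        excluded_pairs=[(ids[i], ids[j]) for i, j in excluded],
        n_resamples=n_resamples,
        exclusion_threshold=exclusion_threshold,
        exclusion_iterations=iters,
        seed=seed,
    )
    corr = _pairs_frame(rho, p, ids, ids, LAYER_MM, "sparcc", symmetric=True)
    return corr, state


def naive_pearson_fractions(table: FeatureTable) -> pd.DataFrame:
    """Pearson correlation on closed fractions (the biased baseline).

    Provided for comparison only: closure induces a negative bias that
    SparCC is designed to remove.
    """
    fractions = _closure(table.values.to_numpy(dtype=float) + np.finfo(float).tiny)
    rho = np.corrcoef(fractions)
    return pd.DataFrame(rho, index=table.feature_ids, columns=table.feature_ids)
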