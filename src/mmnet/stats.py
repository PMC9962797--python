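"""Group-wise differential abundance statistics.

All group comparisons use the Mann-Whitney U test with an exact p-value
by full enumeration of the C(nA+nB, nA) group labelings whenever
nA + nB <= 14 (which covers a six-versus-six animal design exactly) and
a tie- and continuity-corrected normal approximation beyond that. Fold
changes follow the metabolomics-vendor convention of median scaling:
each feature is divided by its across-sample median so the feature
median is 1, and the fold change is the ratio of group means on that
scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tables import FeatureTable, GroupDesign

logger = logging.getLogger(__name__)

EXACT_ENUMERATION_MAX_N = 14


def _rankdata(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Mann-Whitney U for ``x`` vs ``y`` with a two-sided p-value.

    U is computed from average ranks (ties allowed). For
    ``len(x) + len(y) <= 14`` the p-value is exact: every labeling of
    the pooled observations into groups of the observed sizes is
    enumerated and the two-sided p is
    ``min(1, 2 * min(P(U <= u), P(U >= u)))``. Larger designs use the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    nx_, ny_ = x.size, y.size
    n = nx_ + ny_
    pooled = np.concatenate([x, y])
    ranks = _rankdata(pooled)
    u = ranks[:nx_].sum() - nx_ * (nx_ + 1) / 2.0

    if n <= EXACT_ENUMERATION_MAX_N:
        offset = nx_ * (nx_ + 1) / 2.0
        us = np.array(
            [sum(ranks[list(c)]) - offset for c in combinations(range(n), nx_)]
        )
        eps = 1e-9
        p_le = np.mean(us <= u + eps)
        p_ge = np.mean(us >= u - eps)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return float(u), float(p)

    mu = nx_ * ny_ / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = nx_ * ny_ / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # all observations identical
        return float(u), 1.0
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return float(u), float(max(p, np.finfo(float).tiny))


def stars(p: float) -> int:
    """Significance stars: 1 for p < 0.05, 2 for p < 0.01."""
    if p < 0.01:
        return 2
    if p < 0.05:
        return 1
    return 0


# ---------------------------------------------------------------------------
# normalization helpers
# ---------------------------------------------------------------------------

def impute_pseudo_intensity(values: pd.DataFrame) -> pd.DataFrame:
    """Replace zeros by half the feature's smallest positive value.

    Standard minimum-imputation for mass-spectrometry intensities so log
    transforms and ratios stay defined. Features that are entirely zero
    are left unchanged (they are flagged downstream).
    """
    out = values.copy()
    arr = out.to_numpy(dtype=float)
    for i in range(arr.shape[0]):
        row = arr[i]
        pos = row[row > 0]
        if pos.size and (row == 0).any():
            arr[i] = np.where(row == 0, pos.min() / 2.0, row)
    out.iloc[:, :] = arr
    return out


def median_scale(values: pd.DataFrame) -> pd.DataFrame:
    """Divide each feature by its across-sample median (median -> 1)."""
    med = values.median(axis=1)
    med = med.replace(0, np.nan)
    return values.div(med, axis=0)


# ---------------------------------------------------------------------------
# fold change / volcano
# ---------------------------------------------------------------------------

def fold_change(
    table: FeatureTable,
    design: GroupDesign,
    contrast: tuple[str, str],
    median_scaling: bool = True,
    pseudo: bool = True,
) -> pd.DataFrame:
    """Per-feature fold change (group A over group B) on a normalized scale.

    Returns a frame with columns ``fc``, ``log2_fc`` and ``fc_defined``.
    Zero denominators leave the fold change undefined (NaN) and flagged.
    """
    group_a, group_b = contrast
    vals = table.values
    if pseudo:
        vals = impute_pseudo_intensity(vals)
    if median_scaling:
        vals = median_scale(vals)
    a = vals[design.samples(group_a)].mean(axis=1)
    b = vals[design.samples(group_b)].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = a / b
    defined = (b > 0) & np.isfinite(fc) & (fc > 0)
    log2_fc = pd.Series(np.where(defined, np.log2(fc.where(defined, 1.0)), np.nan),
                        index=vals.index)
    return pd.DataFrame(
        {"fc": fc.where(defined, np.nan), "log2_fc": log2_fc, "fc_defined": defined}
    )


def differential_abundance(
    table: FeatureTable,
    design: GroupDesign,
    contrast: tuple[str, str],
    median_scaling: bool | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Mann-Whitney differential test plus fold change for one contrast.

    ``median_scaling`` defaults to True for metabolite tables and False
    for microbe tables (already relative abundances). With
    ``bh_correct`` a Benjamini-Hochberg ``q`` column is added; the
    per-feature ``p`` and its stars are left uncorrected.
    """
    group_a, group_b = contrast
    if median_scaling is None:
        median_scaling = table.kind == "metabolite"
    sa, sb = design.samples(group_a), design.samples(group_b)
    vals = table.values
    us, ps = [], []
    for fid in vals.index:
        u, p = mann_whitney_exact(vals.loc[fid, sa].to_numpy(), vals.loc[fid, sb].to_numpy())
        us.append(u)
        ps.append(p)
    fc = fold_change(table, design, contrast, median_scaling=median_scaling)
    res = pd.DataFrame(
        {
            "feature_id": vals.index,
            "contrast": f"{group_a} vs {group_b}",
            "U": us,
            "p": ps,
            "fc": fc["fc"].to_numpy(),
            "log2_fc": fc["log2_fc"].to_numpy(),
            "fc_defined": fc["fc_defined"].to_numpy(),
        }
    ).set_index("feature_id")
    res["direction"] = np.select(
        [res["log2_fc"] > 0, res["log2_fc"] < 0], ["up", "down"], default="none"
    )
    res["stars"] = [stars(p) for p in res["p"]]
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        res["q"] = multipletests(res["p"].to_numpy(), method="fdr_bh")[1]
    return res


def volcano_stats(
    table: FeatureTable,
    design: GroupDesign,
    contrast: tuple[str, str],
    median_scaling: bool | None = None,
) -> pd.DataFrame:
    """Per-feature (log2 fold change, -log10 p) for volcano plotting.

    Features with an undefined fold change are excluded and logged.
    """
    res = differential_abundance(table, design, contrast, median_scaling=median_scaling)
    excluded = res.index[~res["fc_defined"]]
    if len(excluded):
        logger.warning(
            "volcano: excluded %d feature(s) with undefined fold change: %s",
            len(excluded),
            list(excluded[:5]),
        )
    keep = res[res["fc_defined"]]
    return pd.DataFrame(
        {
            "log2_fc": keep["log2_fc"],
            "neg_log10_p": -np.log10(keep["p"]),
            "p": keep["p"],
        }
    )


# ---------------------------------------------------------------------------
# box-plot summaries
# ---------------------------------------------------------------------------

@dataclass
class BoxSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list


def _tukey_summary(values: np.ndarray) -> BoxSummary:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = sorted(values[(values < lo_fence) | (values > hi_fence)].tolist())
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
    )


def boxplot_summaries(table: FeatureTable, design: GroupDesign, log: bool = True) -> pd.DataFrame:
    """Per-feature per-group five-number summaries with Tukey outliers.

    Intensities are log-transformed (natural log, zeros imputed with
    half the feature minimum positive) to match box plots drawn on
    log-transformed raw ion counts. All-zero features are flagged.
    """
    vals = impute_pseudo_intensity(table.values)
    rows = []
    for fid in vals.index:
        all_zero = bool((table.values.loc[fid] == 0).all())
        for group in design.groups:
            v = vals.loc[fid, design.samples(group)].to_numpy(dtype=float)
            if all_zero:
                rows.append(
                    {
                        "feature_id": fid,
                        "group": group,
                        "all_zero": True,
                        "median": np.nan,
                        "q1": np.nan,
                        "q3": np.nan,
                        "whisker_low": np.nan,
                        "whisker_high": np.nan,
                        "outliers": [],
                    }
                )
                continue
            s = _tukey_summary(np.log(v) if log else v)
            rows.append(
                {
                    "feature_id": fid,
                    "group": group,
                    "all_zero": False,
                    "median": s.median,
                    "q1": s.q1,
                    "q3": s.q3,
                    "whisker_low": s.whisker_low,
                    "whisker_high": s.whisker_high,
                    "outliers": s.outliers,
                }
            )
    return pd.DataFrame(rows)
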