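"""Alpha diversity, Bray-Curtis beta diversity and metabolite PCA."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _scipy_braycurtis
from sklearn.decomposition import PCA

from .stats import impute_pseudo_intensity
from .tables import FeatureTable, GroupDesign

logger = logging.getLogger(__name__)


def shannon_index(abundances, base: float = math.e) -> float:
    """Shannon diversity H = -sum p_i log p_i over the non-zero fractions.

    Input is renormalized first, so the index is invariant to the scale
    of the abundance vector. Natural log (nats) by default; pass
    ``base=2`` for bits.
    """
    p = np.asarray(abundances, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero sample has no diversity")
    p = p[p > 0] / total
    return float(-(p * np.log(p)).sum() / math.log(base))


def alpha_diversity(table: FeatureTable, base: float = math.e) -> pd.Series:
    """Shannon index per sample."""
    return pd.Series(
        {s: shannon_index(table.values[s].to_numpy(), base=base) for s in table.sample_ids},
        name="shannon",
    )


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples must share the same feature set")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero samples")
    return float(_scipy_braycurtis(x, y))


def bray_curtis_matrix(table: FeatureTable) -> pd.DataFrame:
    """Symmetric sample-by-sample Bray-Curtis dissimilarity matrix."""
    samples = table.sample_ids
    vals = table.values.to_numpy(dtype=float)
    n = len(samples)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(vals[:, i], vals[:, j])
    return pd.DataFrame(out, index=samples, columns=samples)


@dataclass
class OrdinationResult:
    """PCA scores, explained-variance fractions and loadings."""

    scores: pd.DataFrame  # samples x components, plus a 'group' column
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # features x components


def pca_metabolites(
    table: FeatureTable,
    design: GroupDesign | None = None,
    n_components: int | None = 2,
    log_transform: bool = True,
) -> OrdinationResult:
    """PCA of metabolite profiles after log transform and autoscaling.

    Each feature is log-transformed (zeros imputed) and standardized to
    zero mean / unit variance — i.e. intensities are mapped to a normal
    score around a zero mean — then samples are decomposed by PCA.
    Zero-variance features are dropped with a log message. The sign of
    each component is fixed by forcing its largest-magnitude loading
    positive, so results are deterministic across platforms.
    """
    if len(table.sample_ids) < 2 or len(table.feature_ids) < 2:
        raise ValueError("PCA needs at least 2 samples and 2 features")
    vals = impute_pseudo_intensity(table.values)
    X = vals.to_numpy(dtype=float).T  # samples x features
    if log_transform:
        if (X <= 0).any():
            raise ValueError("log transform requires positive intensities")
        X = np.log(X)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [f for f, k in zip(table.feature_ids, keep) if not k]
        logger.warning("PCA: dropped %d zero-variance feature(s): %s",
                       len(dropped), dropped[:5])
    features = [f for f, k in zip(table.feature_ids, keep) if k]
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    max_rank = min(X.shape)
    k = max_rank if n_components is None else min(n_components, max_rank)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # features x components

    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    comp_names = [f"PC{j + 1}" for j in range(k)]
    score_df = pd.DataFrame(scores, index=table.sample_ids, columns=comp_names)
    if design is not None:
        score_df["group"] = design.assignments.reindex(score_df.index)
    return OrdinationResult(
        scores=score_df,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        loadings=pd.DataFrame(loadings, index=features, columns=comp_names),
    )
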