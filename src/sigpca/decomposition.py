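"""Expression standardization, variance filtering, PCA, and the permutation
test that fixes the number of principal components to analyse.

Expression matrices are pandas DataFrames with genes in rows and samples in
columns (log-scale continuous values).  PCA treats genes as variables and
samples as observations; loadings are therefore per-gene weights.  Genes are
centered but not rescaled before PCA; standardization (per-gene z-scores) is
applied only when signature expression profiles are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


@dataclass
class PcaModel:
    """Fitted PCA of an expression matrix (genes as variables).

    ``loadings`` is genes x D with unit-norm columns; ``scores`` is
    samples x D; ``var_frac`` is the fraction of total variance explained
    per component, non-increasing.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    var_frac: np.ndarray
    D: int


def validate_expression(E: pd.DataFrame) -> pd.DataFrame:
    """Validate a genes x samples expression DataFrame."""
    if E.shape[0] < 2 or E.shape[1] < 2:
        raise ValueError("expression matrix needs at least 2 genes and 2 samples")
    if E.index.duplicated().any():
        dups = E.index[E.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene names: {dups[:5]}")
    values = E.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    return E


def standardize(E: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores: each row to mean 0, sample sd (n-1 denominator) 1.

    Standardization puts all genes on a common scale so that a signature's
    expression can be an unweighted average of its member genes.  Genes with
    zero variance cannot be standardized and raise an error naming the gene;
    variance-filter first.
    """
    values = E.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    zero = np.nonzero(sd.ravel() == 0)[0]
    if zero.size:
        raise ValueError(
            f"cannot standardize zero-variance gene(s): "
            f"{E.index[zero[:5]].tolist()}"
        )
    return pd.DataFrame((values - mu) / sd, index=E.index, columns=E.columns)


def variance_filter(E: pd.DataFrame, top_n: int) -> tuple[pd.DataFrame, float]:
    """Keep the ``top_n`` most variable genes.

    Restricting to variable genes both speeds up the analysis and avoids
    biasing enrichment toward gene sets overrepresented among non-expressed
    genes.  Ties at the boundary are broken by gene name (lexicographically
    smaller names kept first), making the selection deterministic.

    Returns the filtered matrix and the fraction of total (per-gene summed)
    variance removed.
    """
    if not 1 <= top_n <= E.shape[0]:
        raise ValueError(f"top_n={top_n} out of range for {E.shape[0]} genes")
    var = E.var(axis=1, ddof=1)
    order = sorted(E.index, key=lambda g: (-var[g], g))
    pos = {g: i for i, g in enumerate(E.index)}
    kept = sorted(order[:top_n], key=pos.__getitem__)  # preserve row order
    total = float(var.sum())
    removed_frac = 0.0 if total == 0 else float(1.0 - var[kept].sum() / total)
    logger.info(
        "variance_filter: kept %d/%d genes, removed %.1f%% of total variance",
        top_n, E.shape[0], 100 * removed_frac,
    )
    return E.loc[kept], removed_frac


def fit_pca(E: pd.DataFrame, n_components: int) -> PcaModel:
    """PCA with genes as variables and samples as observations.

    Genes are centered across samples (no rescaling).  Deterministic up to
    the usual per-component sign convention, which scikit-learn fixes.
    """
    n_genes, n_samples = E.shape
    max_comp = min(n_genes, n_samples - 1)
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds min(genes, samples-1)={max_comp}"
        )
    X = E.to_numpy(dtype=float).T  # observations x variables
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i+1}" for i in range(n_components)]
    return PcaModel(
        loadings=pd.DataFrame(pca.components_.T, index=E.index, columns=cols),
        scores=pd.DataFrame(scores, index=E.columns, columns=cols),
        var_frac=pca.explained_variance_ratio_.copy(),
        D=n_components,
    )


def estimate_num_pcs(
    E: pd.DataFrame,
    n_perm: int = 15,
    z_threshold: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> int:
    """Permutation test for the number of non-trivial principal components.

    Each gene's values are permuted independently across samples, destroying
    inter-gene correlation while preserving each gene's marginal
    distribution.  For each of ``n_perm`` permuted matrices the fraction of
    variance explained by the *first* PC is recorded; the mean and sample sd
    of these values yield a null reference against which every real
    component's variance fraction is z-scored.  D is the length of the
    initial run of components with z >= ``z_threshold`` — using the first
    permuted component as the reference for all real components is slightly
    conservative for later components.

    Deterministic given ``seed``.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = E.to_numpy(dtype=float)
    n_genes, n_samples = values.shape
    max_comp = min(n_genes, n_samples - 1)

    null_vf = np.empty(n_perm)
    for b in range(n_perm):
        perm = values.copy()
        for i in range(n_genes):
            rng.shuffle(perm[i])
        pca = PCA(n_components=1, svd_solver="full")
        pca.fit(perm.T)
        null_vf[b] = pca.explained_variance_ratio_[0]
    mu = null_vf.mean()
    sigma = null_vf.std(ddof=1)
    if sigma == 0:
        raise ValueError("degenerate permutation distribution (sd = 0)")

    real = PCA(n_components=max_comp, svd_solver="full")
    real.fit(values.T)
    z = (real.explained_variance_ratio_ - mu) / sigma
    passing = z >= z_threshold
    D = 0
    while D < max_comp and passing[D]:
        D += 1
    if passing[D:].any():
        later = int(np.nonzero(passing[D:])[0][0]) + D + 1
        logger.warning(
            "estimate_num_pcs: component %d also passes the z-threshold but "
            "lies beyond the initial run (D=%d); it is not retained", later, D,
        )
    logger.info(
        "estimate_num_pcs: D=%d (null vf %.4f +/- %.4f, threshold z>=%.1f)",
        D, mu, sigma, z_threshold,
    )
    return D
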