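"""The signature-discovery engine.

Given an expression matrix and a curated gene-set collection, the engine

1. restricts the analysis to the most variable genes (optional),
2. fixes the number of principal components D by a permutation test,
3. fits PCA with genes as variables,
4. for each PC, ranks genes by loading (descending and ascending — the two
   tails of a component carry opposite expression patterns) and tests every
   gene set for enrichment at the top of each ranking with the exact XL-mHG
   test under a Bonferroni-style fixed threshold,
5. applies a *local* filter within each ranking (greedy removal of sets that
   lose significance once the driving genes of stronger enrichments are
   deleted) and a *global* filter across components (a set related to one
   that already generated a signature is suppressed; earlier components are
   prioritized because they capture more variance),
6. turns each surviving enrichment into a *signature*: a seed of the most
   mutually correlated driving genes, extended by driving genes whose
   correlation with the seed reaches ``r_corr``, whose expression profile is
   the unweighted mean of the members' standardized expression.

The result is a small signatures x samples matrix with functional labels.
:class:`SignaturePCA` packages the engine as a scikit-learn style estimator;
:func:`run_gopca` is the functional entry point.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.base import BaseEstimator, TransformerMixin

from .decomposition import (
    PcaModel,
    estimate_num_pcs,
    fit_pca,
    standardize,
    validate_expression,
    variance_filter,
)
from .enrichment import (
    CutoffConstraints,
    EnrichmentResult,
    fold_enrichment,
    term_constraints,
    xlmhg_pvalue_dp,
    xlmhg_statistic,
)
from .ontology import GeneSetCollection, Ontology

logger = logging.getLogger(__name__)

_NS_PREFIX = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold ``alpha / n_tests``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class GopcaConfig:
    """All tunable parameters of the engine.

    ``alpha_b`` is a *fixed* per-test threshold (default 1e-6, comfortably
    below 0.05 divided by the ~20,000 tests per component that a full
    ontology implies); it is deliberately not divided further by the number
    of components tested, so that re-running with a different D leaves the
    signatures of the shared leading components unchanged.
    """

    x_frac: float = 0.25          # min fraction of a set above a tested cutoff
    x_min: int = 5                # absolute floor for X
    l_rank: int | None = None     # max tested rank; None -> floor(N / 8)
    alpha_b: float = 1e-6         # fixed per-test significance threshold
    r_corr: float = 0.5           # seed-correlation threshold for membership
    z_threshold: float = 2.0      # permutation-test z cutoff for keeping a PC
    n_perm: int = 15              # permutations for the D estimate
    d_override: int | None = None
    top_n_variance: int | None = None
    seed: int = 0
    pca_scale: bool = False       # rescale genes to unit variance before PCA
    global_filter_transitive: bool = True  # relatedness = transitive, not direct

    def __post_init__(self):
        if not 0 < self.alpha_b < 1:
            raise ValueError("alpha_b must be in (0, 1)")
        if not -1 <= self.r_corr <= 1:
            raise ValueError("r_corr must be in [-1, 1]")
        if self.x_min < 1:
            raise ValueError("x_min must be >= 1")


@dataclass
class Signature:
    """A labeled, correlation-coherent gene set with its expression profile.

    ``expression`` is the unweighted mean of the member genes' standardized
    expression, hence has (near-)zero mean across samples.  ``K_total`` is
    the number of genes in the analysis annotated with the generating term.
    """

    term_id: str
    name: str
    namespace: str
    pc_index: int
    genes: tuple[str, ...]
    expression: pd.Series
    enrichment: EnrichmentResult
    K_total: int

    @property
    def label(self) -> str:
        prefix = _NS_PREFIX.get(
            self.namespace, self.namespace[:2].upper() if self.namespace else "GS"
        )
        pc = str(self.pc_index) if self.pc_index < 0 else str(self.pc_index)
        return f"{prefix} {self.name} ({pc}, {len(self.genes)}, {self.K_total})"


@dataclass
class GopcaResult:
    """Full output of one engine run."""

    config: GopcaConfig
    D: int
    signatures: list[Signature]
    matrix: pd.DataFrame  # signatures x samples, rows in persisted order
    provenance: dict = field(default_factory=dict)

    @property
    def n_signatures(self) -> int:
        return len(self.signatures)

    def term_ids(self) -> list[str]:
        return [s.term_id for s in self.signatures]


# ---------------------------------------------------------------------------
# Pipeline stages


def rank_by_loadings(pca: PcaModel, pc: int, direction: int) -> list[str]:
    """Genes ordered by their loading on component ``pc`` (1-based).

    ``direction=+1`` sorts descending (most positive loadings first),
    ``direction=-1`` ascending.  Ties are broken by gene name so the ranking
    is a deterministic function of the loadings.
    """
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    if not 1 <= pc <= pca.D:
        raise ValueError(f"pc={pc} out of range 1..{pca.D}")
    loadings = pca.loadings[f"PC{pc}"]
    return sorted(loadings.index, key=lambda g: (-direction * loadings[g], g))


def _test_term(
    term_id: str,
    members: Sequence[str],
    gene_pos: dict[str, int],
    N: int,
    config: GopcaConfig,
    l_rank: int,
    X_override: int | None = None,
) -> tuple[float, float, int, int, int, CutoffConstraints] | None:
    """XL-mHG test of one gene set against one ranking.

    Returns ``(s, p, n_star, k_star, K, constraints)`` or None when the set
    is too small to ever satisfy its X constraint.  The p-value is computed
    only when the statistic alone could clear ``alpha_b`` (s <= p always, so
    s > alpha_b already implies non-significance).
    """
    positions = sorted(gene_pos[g] for g in members if g in gene_pos)
    K = len(positions)
    if K == 0:
        return None
    if X_override is None:
        c = term_constraints(K, N, config.x_frac, config.x_min, min(l_rank, N))
    else:
        c = CutoffConstraints(X=X_override, L=min(l_rank, N))
    if c.X > K:
        return None
    v = np.zeros(N, dtype=np.int8)
    v[positions] = 1
    s, n_star, k_star = xlmhg_statistic(v, c)
    if n_star == 0:
        return s, 1.0, n_star, k_star, K, c
    if s > config.alpha_b:
        return s, max(s, float("nan")), n_star, k_star, K, c  # p not needed
    p = max(s, xlmhg_pvalue_dp(N, K, c, s))
    return s, p, n_star, k_star, K, c


def enrich_ranking(
    ranked: Sequence[str],
    collection: GeneSetCollection,
    config: GopcaConfig,
    pc_index: int = 0,
    l_rank: int | None = None,
) -> list[EnrichmentResult]:
    """Test every gene set against one ranking; keep significant results.

    Genes of a set absent from the ranked list (i.e. not in the expression
    data after variance filtering) are dropped before testing; K is the
    post-intersection count.  A result is kept iff its exact p-value is at
    or below ``config.alpha_b``.
    """
    N = len(ranked)
    if l_rank is None:
        l_rank = config.l_rank or max(1, N // 8)
    gene_pos = {g: i for i, g in enumerate(ranked)}
    results: list[EnrichmentResult] = []
    for term_id in collection.sets:
        members = collection.sets[term_id]
        out = _test_term(term_id, members, gene_pos, N, config, l_rank)
        if out is None:
            continue
        s, p, n_star, k_star, K, c = out
        if n_star == 0 or not p <= config.alpha_b:
            continue
        driving = tuple(
            g for g in ranked[:n_star] if g in members
        )
        name, namespace = collection.term_meta[term_id]
        results.append(
            EnrichmentResult(
                term_id=term_id,
                term_name=name,
                namespace=namespace,
                pc_index=pc_index,
                s_mhg=s,
                p_mhg=p,
                n_star=n_star,
                k_star=k_star,
                K=K,
                N=N,
                X=c.X,
                L=c.resolve_L(N),
                escore=fold_enrichment(k_star, n_star, K, N),
                driving_genes=driving,
            )
        )
    logger.debug(
        "enrich_ranking(pc=%+d): %d of %d sets significant at %.1e",
        pc_index, len(results), collection.m, config.alpha_b,
    )
    return results


def local_filter(
    results: list[EnrichmentResult],
    ranked: Sequence[str],
    collection: GeneSetCollection,
    config: GopcaConfig,
) -> list[EnrichmentResult]:
    """Greedy within-ranking redundancy filter.

    Sets are visited in order of decreasing fold enrichment (effect size;
    stronger enrichments are presumed better labels).  The driving genes of
    every accepted set accumulate in a "seen" pool; each subsequent set is
    re-tested on the ranking with seen genes deleted (ranks close up, K is
    recomputed) using its original X and the configured L clipped to the
    shrunken list.  Sets that lose significance are redundant with stronger
    ones and are dropped.
    """
    if not results:
        return []
    ordered = sorted(results, key=lambda r: (-r.escore, r.p_mhg, r.term_id))
    kept = [ordered[0]]
    seen: set[str] = set(ordered[0].driving_genes)
    for r in ordered[1:]:
        shrunk = [g for g in ranked if g not in seen]
        gene_pos = {g: i for i, g in enumerate(shrunk)}
        out = _test_term(
            r.term_id,
            collection.sets[r.term_id],
            gene_pos,
            len(shrunk),
            config,
            min(r.L, len(shrunk)),
            X_override=r.X,
        )
        if out is None:
            continue
        s, p, n_star, _, _, _ = out
        if n_star != 0 and p <= config.alpha_b:
            kept.append(r)
            seen.update(r.driving_genes)
    logger.debug("local_filter: kept %d of %d", len(kept), len(results))
    return kept


def global_filter(
    per_pc_results: list[EnrichmentResult], ontology: Ontology | None
) -> list[EnrichmentResult]:
    """Cross-component redundancy filter.

    Input must be ordered by (|pc| ascending, positive direction first).  A
    set is suppressed if it, or any related set (transitive ancestors and
    descendants in the ontology), has already generated a kept result —
    earlier components are prioritized because they capture more variance.
    Suppression also applies between the two rankings of the same component,
    so the output never contains two related terms.  Without an ontology
    (plain gene-set mode) only exact duplicates are suppressed.
    """
    kept: list[EnrichmentResult] = []
    blocked: set[str] = set()
    for r in per_pc_results:
        if r.term_id in blocked:
            logger.debug("global_filter: dropping %s (related term kept earlier)", r.term_id)
            continue
        kept.append(r)
        blocked.add(r.term_id)
        if ontology is not None and r.term_id in ontology:
            blocked |= ontology.related_terms(r.term_id)
    return kept


def _row_corr(profiles: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``profiles`` with ``reference``."""
    p = profiles - profiles.mean(axis=1, keepdims=True)
    ref = reference - reference.mean()
    denom = np.sqrt((p**2).sum(axis=1) * (ref**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (p @ ref) / denom
    return np.where(np.isfinite(corr), corr, 0.0)


def build_signature(
    result: EnrichmentResult,
    E_std: pd.DataFrame,
    config: GopcaConfig,
) -> Signature:
    """Seed-and-extend signature construction from one enrichment.

    The average standardized profile of the driving genes is computed; the X
    driving genes most correlated with it form the *seed* (all of them when
    there are at most X); any remaining driving gene joins the signature if
    its correlation with the seed profile is at least ``r_corr``.  The
    signature expression is the unweighted mean of the members' standardized
    profiles.  Seed members are always included, so the signature is never
    empty.
    """
    driving = [g for g in result.driving_genes if g in E_std.index]
    if not driving:
        raise ValueError(f"no driving genes of {result.term_id} present in matrix")
    profiles = E_std.loc[driving].to_numpy()
    avg = profiles.mean(axis=0)
    corr_avg = _row_corr(profiles, avg)
    X = result.X
    if len(driving) <= X:
        seed_genes = list(driving)
    else:
        order = sorted(range(len(driving)), key=lambda i: (-corr_avg[i], driving[i]))
        seed_genes = [driving[i] for i in order[:X]]
    seed_profile = E_std.loc[seed_genes].to_numpy().mean(axis=0)
    corr_seed = _row_corr(profiles, seed_profile)
    members = set(seed_genes)
    for i, g in enumerate(driving):
        if g not in members and corr_seed[i] >= config.r_corr:
            members.add(g)
    corr_by_gene = dict(zip(driving, corr_seed))
    genes = tuple(sorted(members, key=lambda g: (-corr_by_gene[g], g)))
    expression = E_std.loc[list(genes)].mean(axis=0)
    return Signature(
        term_id=result.term_id,
        name=result.term_name,
        namespace=result.namespace,
        pc_index=result.pc_index,
        genes=genes,
        expression=expression,
        enrichment=result,
        K_total=result.K,
    )


def order_signatures(
    signatures: Sequence[Signature] | GopcaResult,
    method: Literal["cluster", "pc"] = "cluster",
) -> list[int]:
    """Display ordering of signatures.

    ``cluster``: leaf order of average-linkage agglomeration on correlation
    distance (1 - r) between the signature expression profiles, which places
    co-expressed signatures next to each other.  ``pc``: by (|pc|,
    direction, descending enrichment score).
    """
    if isinstance(signatures, GopcaResult):
        signatures = signatures.signatures
    n = len(signatures)
    if n == 0:
        return []
    if n == 1:
        return [0]
    if method == "pc":
        return sorted(
            range(n),
            key=lambda i: (
                abs(signatures[i].pc_index),
                -np.sign(signatures[i].pc_index),
                -signatures[i].enrichment.escore,
            ),
        )
    profiles = np.vstack([s.expression.to_numpy() for s in signatures])
    linkage = sch.linkage(profiles, method="average", metric="correlation")
    return [int(i) for i in sch.leaves_list(linkage)]


def _hash_frame(E: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(E.to_numpy(dtype=float)).tobytes())
    h.update("\x00".join(map(str, E.index)).encode())
    h.update("\x00".join(map(str, E.columns)).encode())
    return h.hexdigest()


def run_gopca(
    E: pd.DataFrame,
    collection: GeneSetCollection,
    ontology: Ontology | None = None,
    config: GopcaConfig | None = None,
) -> GopcaResult:
    """Run the full pipeline; see the module docstring for the stages.

    Fully deterministic given ``config.seed``.  ``D = 0`` (no component
    passes the permutation test) yields an empty result with a warning, not
    an error.
    """
    config = config or GopcaConfig()
    E = validate_expression(E)

    # drop zero-variance genes: they carry no information and cannot be
    # standardized
    var = E.var(axis=1, ddof=1)
    if (var == 0).any():
        n0 = int((var == 0).sum())
        logger.warning("dropping %d zero-variance genes", n0)
        E = E.loc[var > 0]
    if config.top_n_variance is not None and config.top_n_variance < E.shape[0]:
        E, removed = variance_filter(E, config.top_n_variance)
    else:
        removed = 0.0

    N = E.shape[0]
    l_rank = config.l_rank or max(1, N // 8)
    rng = np.random.default_rng(config.seed)

    E_pca = standardize(E) if config.pca_scale else E
    if config.d_override is not None:
        D = config.d_override
    else:
        D = estimate_num_pcs(E_pca, config.n_perm, config.z_threshold, rng)
    max_comp = min(E.shape[0], E.shape[1] - 1)
    D = min(D, max_comp)

    provenance = {
        "input_hash": _hash_frame(E),
        "n_genes": int(E.shape[0]),
        "n_samples": int(E.shape[1]),
        "n_gene_sets": collection.m,
        "l_rank": int(l_rank),
        "variance_removed": float(removed),
    }

    if D == 0:
        logger.warning("no principal component passes the permutation test; "
                       "empty result")
        return GopcaResult(
            config=config, D=0, signatures=[],
            matrix=pd.DataFrame(columns=E.columns), provenance=provenance,
        )

    pca = fit_pca(E_pca, D)
    E_std = standardize(E)

    all_results: list[EnrichmentResult] = []
    for pc in range(1, D + 1):
        for direction in (+1, -1):
            ranked = rank_by_loadings(pca, pc, direction)
            pc_index = pc * direction
            results = enrich_ranking(ranked, collection, config, pc_index, l_rank)
            results = local_filter(results, ranked, collection, config)
            all_results.extend(results)
    if config.global_filter_transitive or ontology is None:
        surviving = global_filter(all_results, ontology)
    else:  # direct-neighbor relatedness variant
        surviving = _global_filter_direct(all_results, ontology)

    signatures = [build_signature(r, E_std, config) for r in surviving]
    order = order_signatures(signatures, "cluster")
    signatures = [signatures[i] for i in order]
    if signatures:
        matrix = pd.DataFrame(
            [s.expression.to_numpy() for s in signatures],
            index=[s.label for s in signatures],
            columns=E.columns,
        )
    else:
        matrix = pd.DataFrame(columns=E.columns)
    logger.info("pipeline: D=%d, %d signatures", D, len(signatures))
    return GopcaResult(
        config=config, D=D, signatures=signatures, matrix=matrix,
        provenance=provenance,
    )


def _global_filter_direct(
    per_pc_results: list[EnrichmentResult], ontology: Ontology
) -> list[EnrichmentResult]:
    """Variant of the cross-PC filter using direct parents/children only."""
    kept: list[EnrichmentResult] = []
    blocked: set[str] = set()
    for r in per_pc_results:
        if r.term_id in blocked:
            continue
        kept.append(r)
        blocked.add(r.term_id)
        if r.term_id in ontology:
            blocked |= ontology.parents(r.term_id) | ontology.children(r.term_id)
    return kept


# ---------------------------------------------------------------------------
# scikit-learn style estimator


class SignaturePCA(TransformerMixin, BaseEstimator):
    """Signature discovery as a scikit-learn transformer.

    Combines PCA on the expression matrix with exact nonparametric gene-set
    enrichment on the component loadings to reduce the matrix to a small set
    of functionally labeled signatures.

    Parameters mirror :class:`GopcaConfig`; ``gene_sets`` (a
    :class:`~sigpca.ontology.GeneSetCollection`) is required at ``fit`` time
    or may be passed at construction.  ``fit`` expects a genes x samples
    DataFrame (the domain's conventional orientation — note this transposes
    scikit-learn's usual samples x features layout); ``transform`` projects
    samples onto the fitted signatures using the per-gene standardization
    learned during ``fit`` and returns a samples x signatures DataFrame.

    Attributes
    ----------
    result_ : GopcaResult
        Full structured result.
    signatures_ : list of Signature
    signature_matrix_ : DataFrame, signatures x samples
    n_components_ : int
        Number of principal components tested (D).
    gene_means_, gene_sds_ : Series
        Standardization parameters of the analysed genes.

    Examples
    --------
    >>> est = SignaturePCA(gene_sets=collection, ontology=onto, seed=0)
    >>> est.fit(expression)                          # doctest: +SKIP
    >>> est.signature_matrix_                        # doctest: +SKIP
    """

    def __init__(
        self,
        gene_sets: GeneSetCollection | None = None,
        ontology: Ontology | None = None,
        x_frac: float = 0.25,
        x_min: int = 5,
        l_rank: int | None = None,
        alpha_b: float = 1e-6,
        r_corr: float = 0.5,
        z_threshold: float = 2.0,
        n_perm: int = 15,
        d_override: int | None = None,
        top_n_variance: int | None = None,
        seed: int = 0,
        pca_scale: bool = False,
        global_filter_transitive: bool = True,
    ):
        self.gene_sets = gene_sets
        self.ontology = ontology
        self.x_frac = x_frac
        self.x_min = x_min
        self.l_rank = l_rank
        self.alpha_b = alpha_b
        self.r_corr = r_corr
        self.z_threshold = z_threshold
        self.n_perm = n_perm
        self.d_override = d_override
        self.top_n_variance = top_n_variance
        self.seed = seed
        self.pca_scale = pca_scale
        self.global_filter_transitive = global_filter_transitive

    def _config(self) -> GopcaConfig:
        return GopcaConfig(
            x_frac=self.x_frac,
            x_min=self.x_min,
            l_rank=self.l_rank,
            alpha_b=self.alpha_b,
            r_corr=self.r_corr,
            z_threshold=self.z_threshold,
            n_perm=self.n_perm,
            d_override=self.d_override,
            top_n_variance=self.top_n_variance,
            seed=self.seed,
            pca_scale=self.pca_scale,
            global_filter_transitive=self.global_filter_transitive,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "SignaturePCA":
        """Run the pipeline on a genes x samples expression DataFrame."""
        if self.gene_sets is None:
            raise ValueError("gene_sets must be provided")
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a genes x samples DataFrame with labels")
        result = run_gopca(X, self.gene_sets, self.ontology, self._config())
        self.result_ = result
        self.signatures_ = result.signatures
        self.signature_matrix_ = result.matrix
        self.n_components_ = result.D
        analysed = X.loc[X.var(axis=1, ddof=1) > 0]
        if result.config.top_n_variance is not None and \
                result.config.top_n_variance < analysed.shape[0]:
            analysed, _ = variance_filter(analysed, result.config.top_n_variance)
        self.gene_means_ = analysed.mean(axis=1)
        self.gene_sds_ = analysed.std(axis=1, ddof=1)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Project samples onto the fitted signatures.

        Gene expression is standardized with the means/sds learned at fit
        time, then averaged over each signature's member genes.  Returns a
        samples x signatures DataFrame.
        """
        if not hasattr(self, "result_"):
            raise ValueError("SignaturePCA instance is not fitted yet")
        out = {}
        for sig in self.signatures_:
            genes = [g for g in sig.genes if g in X.index]
            if not genes:
                raise ValueError(
                    f"none of the genes of signature {sig.label!r} are in X"
                )
            z = (
                X.loc[genes].sub(self.gene_means_[genes], axis=0)
                .div(self.gene_sds_[genes], axis=0)
            )
            out[sig.label] = z.mean(axis=0)
        return pd.DataFrame(out, index=X.columns)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        if not hasattr(self, "result_"):
            raise ValueError("SignaturePCA instance is not fitted yet")
        return np.asarray([s.label for s in self.signatures_], dtype=object)
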