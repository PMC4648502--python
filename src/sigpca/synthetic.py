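"""Synthetic expression data with planted, annotated, correlated gene modules.

The generator emulates the structure that the pipeline is designed to find
in real transcriptomes: blocks of mutually correlated genes overexpressed in
a subset of samples (think of a cell-type-specific program in a heterogeneous
sample panel), embedded in i.i.d. Gaussian noise on the log-expression
scale, together with a gene-set collection in which each planted module has
a matching annotation (plus decoy sets of random genes) and a miniature
DAG-structured ontology so that related-term logic can be exercised.

The accompanying :class:`SyntheticTruth` records exactly what was planted,
so precision/recall of any downstream result can be computed without
re-reading the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ontology import GeneSetCollection, Ontology, OntologyTerm

__all__ = ["ModuleSpec", "SyntheticTruth", "make_dataset", "make_ranked_list"]


@dataclass(frozen=True)
class ModuleSpec:
    """One planted module: ``size`` genes shifted by ``effect`` (in noise-sd
    units) in a fraction ``sample_fraction`` of samples."""

    size: int
    sample_fraction: float
    effect: float

    def __post_init__(self):
        if self.size < 1:
            raise ValueError("module size must be >= 1")
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset."""

    planted_terms: list[str]
    module_genes: dict[str, frozenset[str]]
    active_samples: dict[str, frozenset[str]]
    effect_size: dict[str, float]
    noise_sd: float
    seed: int
    parent_terms: dict[str, str] = field(default_factory=dict)

    def precision_recall(self, recovered_terms: list[str]) -> tuple[float, float]:
        """Precision/recall of recovered term ids against the planted ones."""
        recovered = set(recovered_terms)
        planted = set(self.planted_terms)
        tp = len(recovered & planted)
        precision = tp / len(recovered) if recovered else 1.0
        recall = tp / len(planted) if planted else 1.0
        return precision, recall


def _term_id(i: int) -> str:
    return f"SYN:{i:07d}"


def make_dataset(
    n_genes: int = 1000,
    n_samples: int = 60,
    modules: list[ModuleSpec | tuple[int, float, float]] = (),
    n_decoy_sets: int = 500,
    seed: int = 0,
    noise_sd: float = 1.0,
    decoy_size_range: tuple[int, int] = (5, 50),
    contamination: float = 0.0,
    include_parents: bool = False,
) -> tuple[pd.DataFrame, GeneSetCollection, Ontology, SyntheticTruth]:
    """Generate an expression matrix with planted annotated modules.

    Background values are drawn i.i.d. from Normal(0, ``noise_sd``); the
    genes of each module receive ``+effect`` (in absolute units; effects are
    quoted in noise-sd units since ``noise_sd`` defaults to 1) in that
    module's active samples.  Modules occupy pairwise-disjoint gene blocks;
    active samples are drawn independently per module, so sample subsets may
    overlap between modules.

    Each planted module is annotated by exactly one term (optionally plus a
    ``contamination`` fraction of random extra genes, probing the X
    constraint); ``n_decoy_sets`` additional terms annotate random gene
    draws.  With ``include_parents`` every planted term also gets an
    ontology parent annotating a strict superset of the module, for
    related-term tests.

    Deterministic per ``seed``.
    """
    rng = np.random.default_rng(seed)
    modules = [m if isinstance(m, ModuleSpec) else ModuleSpec(*m) for m in modules]
    total_module_genes = sum(m.size for m in modules)
    if total_module_genes > n_genes:
        raise ValueError(
            f"modules need {total_module_genes} genes but only {n_genes} available"
        )
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"S{j:04d}" for j in range(n_samples)]
    values = rng.normal(0.0, noise_sd, size=(n_genes, n_samples))

    terms: dict[str, OntologyTerm] = {}
    sets: dict[str, frozenset[str]] = {}
    meta: dict[str, tuple[str, str]] = {}
    truth = SyntheticTruth(
        planted_terms=[], module_genes={}, active_samples={},
        effect_size={}, noise_sd=noise_sd, seed=seed,
    )

    cursor = 0
    for i, mod in enumerate(modules):
        term = _term_id(i + 1)
        block = genes[cursor:cursor + mod.size]
        cursor += mod.size
        n_active = max(1, round(mod.sample_fraction * n_samples))
        active = rng.choice(n_samples, size=n_active, replace=False)
        for j in active:
            values[cursor - mod.size:cursor, j] += mod.effect
        annotated = set(block)
        if contamination > 0:
            n_extra = round(contamination * mod.size)
            pool = [g for g in genes if g not in annotated]
            annotated |= set(rng.choice(pool, size=min(n_extra, len(pool)),
                                        replace=False))
        name = f"planted module {i + 1}"
        terms[term] = OntologyTerm(id=term, name=name,
                                   namespace="biological_process")
        sets[term] = frozenset(annotated)
        meta[term] = (name, "biological_process")
        truth.planted_terms.append(term)
        truth.module_genes[term] = frozenset(block)
        truth.active_samples[term] = frozenset(samples[j] for j in active)
        truth.effect_size[term] = mod.effect
        if include_parents:
            parent = _term_id(9000 + i + 1)
            extra = rng.choice(
                [g for g in genes if g not in annotated], size=5, replace=False
            )
            pname = f"planted module {i + 1} parent"
            terms[parent] = OntologyTerm(id=parent, name=pname,
                                         namespace="biological_process")
            terms[term].is_a_parents.append(parent)
            sets[parent] = frozenset(annotated | set(extra))
            meta[parent] = (pname, "biological_process")
            truth.parent_terms[term] = parent

    lo, hi = decoy_size_range
    for d in range(n_decoy_sets):
        term = _term_id(1000 + d + 1)
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        name = f"decoy set {d + 1}"
        terms[term] = OntologyTerm(id=term, name=name,
                                   namespace="biological_process")
        sets[term] = frozenset(members)
        meta[term] = (name, "biological_process")

    E = pd.DataFrame(values, index=genes, columns=samples)
    collection = GeneSetCollection(sets=sets, term_meta=meta)
    ontology = Ontology(terms)
    return E, collection, ontology, truth


def make_ranked_list(
    N: int,
    K: int,
    arrangement: str = "random",
    seed: int = 0,
) -> np.ndarray:
    """A ranked binary list for enrichment unit tests.

    ``top_block`` places all K ones at the best ranks, ``bottom_block`` at
    the worst, ``random`` uniformly at random (seeded).
    """
    if not 0 <= K <= N:
        raise ValueError("need 0 <= K <= N")
    v = np.zeros(N, dtype=np.int8)
    if arrangement == "top_block":
        v[:K] = 1
    elif arrangement == "bottom_block":
        v[N - K:] = 1
    elif arrangement == "random":
        rng = np.random.default_rng(seed)
        v[rng.choice(N, size=K, replace=False)] = 1
    else:
        raise ValueError(f"unknown arrangement: {arrangement}")
    return v
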