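"""Bootstrap robustness assessment of expression signatures.

Samples (columns) are resampled with replacement and the full pipeline is
re-run on each replicate with the original parameters.  A signature of the
original run counts as *detected* in a replicate if the replicate contains a
signature based on the exact same term (``exact`` mode) or on any related —
ancestral or descendant — term (``related`` mode).  Detection is summarised
overall, as a function of the number of leading principal components
considered, and as a function of (sub)sample size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GopcaConfig, GopcaResult, run_gopca
from .decomposition import validate_expression
from .ontology import GeneSetCollection, Ontology

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionReport",
    "resample_samples",
    "bootstrap_gopca",
    "detection_rates",
    "pc_prefix_detection",
    "build_report",
]


@dataclass
class DetectionReport:
    """Per-signature bootstrap detection rates.

    ``exact_rate``/``related_rate`` are indexed by the original signatures'
    term ids; ``related_rate >= exact_rate`` holds pointwise because a
    signature matching exactly also matches in related mode.
    """

    exact_rate: pd.Series
    related_rate: pd.Series
    pc_prefix: pd.DataFrame          # signatures x n (leading PCs considered)
    size_rates: pd.DataFrame         # signatures x resample size (exact mode)
    B: int
    sizes: list[int] = field(default_factory=list)
    run_summary: pd.DataFrame | None = None  # per size: median/IQR of D, #sigs


def resample_samples(
    E: pd.DataFrame, size: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Draw ``size`` columns i.i.d. uniformly with replacement.

    Gene rows are unchanged.  Duplicated sample names are disambiguated by a
    positional suffix so column labels stay unique.
    """
    validate_expression(E)
    if size < 2:
        raise ValueError("resample size must be >= 2 (standardization needs "
                         "at least two samples)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, E.shape[1], size=size)
    out = E.iloc[:, idx].copy()
    out.columns = [f"{E.columns[i]}.b{j}" for j, i in enumerate(idx)]
    return out


def _sizes_from_fractions(n: int, fractions: list[float] | None) -> list[int]:
    if not fractions:
        return [n]
    # round half-up, floor at 2
    return [max(2, int(np.floor(f * n + 0.5))) for f in fractions]


def bootstrap_gopca(
    E: pd.DataFrame,
    collection: GeneSetCollection,
    ontology: Ontology | None,
    config: GopcaConfig,
    B: int = 50,
    sizes: list[float] | None = None,
) -> dict[int, list[GopcaResult]]:
    """Run ``B`` bootstrap replicates of the pipeline per resample size.

    ``sizes`` are fractions of the original sample count (``None`` means the
    full size only).  Every replicate derives its seed as
    ``config.seed + replicate index`` (offset per size), so any single
    replicate can be reproduced in isolation.  A replicate whose run fails
    is recorded as an empty result and excluded from nothing — an empty
    signature list simply never matches — with the failure logged.
    """
    n = E.shape[1]
    size_list = _sizes_from_fractions(n, sizes)
    out: dict[int, list[GopcaResult]] = {}
    for si, size in enumerate(size_list):
        runs: list[GopcaResult] = []
        for b in range(B):
            rep_seed = int(config.seed) + si * B + b
            Eb = resample_samples(E, size, np.random.default_rng(rep_seed))
            cfg_b = GopcaConfig(**{**config.__dict__, "seed": rep_seed})
            try:
                runs.append(run_gopca(Eb, collection, ontology, cfg_b))
            except Exception:
                logger.exception(
                    "bootstrap replicate %d at size %d failed; counted as "
                    "zero detections", b, size,
                )
                runs.append(GopcaResult(
                    config=cfg_b, D=0, signatures=[],
                    matrix=pd.DataFrame(columns=Eb.columns),
                ))
        out[size] = runs
        logger.info(
            "bootstrap: size=%d, B=%d, median D=%.1f, median #signatures=%.1f",
            size, B,
            float(np.median([r.D for r in runs])),
            float(np.median([r.n_signatures for r in runs])),
        )
    return out


def _detected(
    term_id: str, run: GopcaResult, ontology: Ontology | None, mode: str,
    max_abs_pc: int | None = None,
) -> bool:
    terms = {
        s.term_id for s in run.signatures
        if max_abs_pc is None or abs(s.pc_index) <= max_abs_pc
    }
    if term_id in terms:
        return True
    if mode == "related" and ontology is not None and term_id in ontology:
        return bool(ontology.related_terms(term_id) & terms)
    return False


def detection_rates(
    original: GopcaResult,
    runs: list[GopcaResult],
    ontology: Ontology | None = None,
    mode: str = "exact",
) -> pd.Series:
    """Fraction of runs in which each original signature is re-detected.

    Matching ignores the PC index and direction: a signature re-discovered
    on a different component still counts (component identity is analysed
    separately by :func:`pc_prefix_detection`).
    """
    if mode not in ("exact", "related"):
        raise ValueError("mode must be 'exact' or 'related'")
    if not runs:
        raise ValueError("runs must be nonempty")
    rates = {}
    for sig in original.signatures:
        hits = sum(_detected(sig.term_id, r, ontology, mode) for r in runs)
        rates[sig.term_id] = hits / len(runs)
    return pd.Series(rates, name=f"{mode}_rate", dtype=float)


def pc_prefix_detection(
    original: GopcaResult,
    runs: list[GopcaResult],
    ontology: Ontology | None = None,
    mode: str = "exact",
) -> pd.DataFrame:
    """Detection rates when only the first ``n`` components are considered.

    Cell (signature, n) is the fraction of runs containing a matching
    signature generated by a component of absolute index <= n.  Rows are
    non-decreasing in n; at the largest D across runs each row equals the
    overall detection rate.
    """
    if not runs:
        raise ValueError("runs must be nonempty")
    max_d = max((r.D for r in runs), default=0)
    max_d = max(max_d, 1)
    data = {}
    for sig in original.signatures:
        row = [
            sum(_detected(sig.term_id, r, ontology, mode, max_abs_pc=n)
                for r in runs) / len(runs)
            for n in range(1, max_d + 1)
        ]
        data[sig.term_id] = row
    return pd.DataFrame.from_dict(
        data, orient="index", columns=[f"n={n}" for n in range(1, max_d + 1)]
    )


def build_report(
    original: GopcaResult,
    runs_by_size: dict[int, list[GopcaResult]],
    ontology: Ontology | None = None,
    full_size: int | None = None,
) -> DetectionReport:
    """Assemble the full robustness report from bootstrap runs.

    Overall and PC-prefix rates are computed on the full-size runs (the
    largest size when ``full_size`` is not given); per-size rates (exact
    mode) cover all sizes.
    """
    sizes = sorted(runs_by_size)
    if full_size is None:
        full_size = sizes[-1]
    full_runs = runs_by_size[full_size]
    exact = detection_rates(original, full_runs, ontology, "exact")
    related = detection_rates(original, full_runs, ontology, "related")
    prefix = pc_prefix_detection(original, full_runs, ontology, "exact")
    size_rates = pd.DataFrame({
        size: detection_rates(original, runs_by_size[size], ontology, "exact")
        for size in sizes
    })
    summary = pd.DataFrame({
        size: {
            "median_D": float(np.median([r.D for r in runs_by_size[size]])),
            "iqr_D": float(np.subtract(*np.percentile(
                [r.D for r in runs_by_size[size]], [75, 25]))),
            "median_signatures": float(np.median(
                [r.n_signatures for r in runs_by_size[size]])),
            "iqr_signatures": float(np.subtract(*np.percentile(
                [r.n_signatures for r in runs_by_size[size]], [75, 25]))),
        }
        for size in sizes
    }).T
    return DetectionReport(
        exact_rate=exact,
        related_rate=related,
        pc_prefix=prefix,
        size_rates=size_rates,
        B=len(full_runs),
        sizes=sizes,
        run_summary=summary,
    )
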