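"""Association between signatures and known sample groups.

For each signature, the group with the highest median signature expression
is compared against the runner-up group using a two-sided Mann-Whitney U
(rank-sum) test; p-values are Bonferroni-corrected over the number of
signatures at a family-wise alpha of 0.05.  This asks whether a signature
singles out one group rather than varying smoothly across all of them.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .core import GopcaResult

logger = logging.getLogger(__name__)

#: Combined group size up to which the exact null distribution is enumerated.
_EXACT_MAX_N = 12


def rank_sum_pvalue(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration of rank splits when the combined size is at most 12
    and there are no ties (reproducible at toy scale); normal approximation
    with continuity and tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    if len(combined) <= _EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method,
                       use_continuity=True)
    return float(res.pvalue)


def signature_group_association(
    result: GopcaResult,
    groups: Mapping[str, str] | pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test each signature for association with its top-expressing group.

    Parameters
    ----------
    result
        A fitted pipeline result with at least one signature.
    groups
        Sample -> group label.  Groups with fewer than two samples are
        excluded with a warning; at least two eligible groups are required.
    alpha
        Family-wise significance level; the per-test threshold is
        ``alpha / n_signatures``.

    Returns
    -------
    DataFrame with one row per signature: the top two groups by median
    signature expression, their medians, the raw two-sided p-value, and
    whether it clears the Bonferroni-corrected threshold.
    """
    if result.n_signatures < 1:
        raise ValueError("result has no signatures")
    groups = pd.Series(groups)
    samples = result.matrix.columns
    groups = groups.reindex(samples).dropna()
    counts = groups.value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        logger.warning("excluding groups with <2 samples: %s", small)
        groups = groups[~groups.isin(small)]
    if groups.nunique() < 2:
        raise ValueError("need at least two groups with >= 2 samples each")

    threshold = alpha / result.n_signatures
    rows = []
    for sig in result.signatures:
        expr = result.matrix.loc[sig.label]
        medians = expr.groupby(groups).median().sort_values(ascending=False)
        top, second = medians.index[0], medians.index[1]
        p = rank_sum_pvalue(
            expr[groups[groups == top].index],
            expr[groups[groups == second].index],
        )
        rows.append({
            "signature": sig.label,
            "term_id": sig.term_id,
            "best_group": top,
            "second_group": second,
            "best_median": float(medians.iloc[0]),
            "second_median": float(medians.iloc[1]),
            "p_value": p,
            "significant": p <= threshold,
        })
    return pd.DataFrame(rows)
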