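"""Treatment-set comparison and hypergeometric over-representation.

Two HV gene lists (one per treatment arm) are partitioned by exact set
algebra into common and arm-specific sets. Over-representation of an
annotation term in a gene list is scored with the exact hypergeometric
upper tail: drawing n genes (the list) from a background of N, of which K
belong to the term, the p-value is P(X >= k) for the observed overlap k,
summed exactly (scipy's log-domain tail, no normal approximation). A group
of related terms gets a DAVID-style enrichment score: the arithmetic mean
of -log10 p over its members (equivalently -log10 of their geometric
mean). Term grouping itself is supplied by the caller.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneSetCollection, SetPartition
from .errors import BackgroundMismatch

__all__ = [
    "partition_hv_sets",
    "hypergeometric_enrichment",
    "enrichment_score",
]

_P_FLOOR = 1e-300


def partition_hv_sets(
    hv_a: Iterable[str],
    hv_b: Iterable[str],
    label_a: str = "a",
    label_b: str = "b",
) -> SetPartition:
    """Split two HV sets into common / only-a / only-b (exact set algebra)."""
    a, b = frozenset(hv_a), frozenset(hv_b)
    return SetPartition(
        common=a & b,
        only_a=a - b,
        only_b=b - a,
        label_a=label_a,
        label_b=label_b,
    )


def hypergeometric_enrichment(
    gene_list: Iterable[str],
    gene_sets: GeneSetCollection,
    background: Iterable[str],
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Exact upper-tail hypergeometric test of each set against the list.

    Each set is intersected with the background before testing; the gene
    list must be a subset of the background. Returns a DataFrame indexed by
    term_id with columns term_name, overlap_k, set_size_K, list_size_n,
    background_N, p_upper (and p_bh when ``bh_correction``).
    """
    bg = frozenset(background)
    lst = frozenset(gene_list)
    if not lst <= bg:
        missing = sorted(lst - bg)[:5]
        raise BackgroundMismatch(
            f"{len(lst - bg)} list genes absent from background, e.g. {missing}"
        )
    N, n = len(bg), len(lst)
    rows = []
    for s in gene_sets:
        members = s.members & bg
        K = len(members)
        k = len(members & lst)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "term_id": s.term_id,
                "term_name": s.term_name,
                "overlap_k": k,
                "set_size_K": K,
                "list_size_n": n,
                "background_N": N,
                "p_upper": min(max(p, 0.0), 1.0),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "term_name",
            "overlap_k",
            "set_size_K",
            "list_size_n",
            "background_N",
            "p_upper",
        ],
    ).set_index("term_id")
    if bh_correction and len(out):
        out["p_bh"] = multipletests(out["p_upper"].to_numpy(), method="fdr_bh")[1]
    return out


def enrichment_score(p_values: Sequence[float]) -> float:
    """DAVID-style cluster enrichment score: mean of -log10 p.

    Zero p-values are floored at 1e-300 with a warning rather than mapped
    to infinity.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("enrichment_score needs at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p = 0 floored at 1e-300 in enrichment score")
        p = np.maximum(p, _P_FLOOR)
    return float(np.mean(-np.log10(p)))
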