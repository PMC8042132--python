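"""Overrepresentation analysis (ORA) with BH false-discovery control.

A query gene list is tested against each gene set with the hypergeometric
upper tail: p = P(overlap >= k) when drawing |query| genes without
replacement from a universe of N genes of which K belong to the set. The
enrichment ratio is observed overlap divided by the expected overlap
``|query| * K / N``. Sets overlapping the query in fewer than
``min_overlap`` genes (default 5) are excluded BEFORE Benjamini-Hochberg
adjustment — the adjustment m counts only the tested sets, matching common
web-tool behavior — and significance requires adjusted p < 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from guiltnet.io import GeneSetCollection

DEFAULT_MIN_OVERLAP = 5
DEFAULT_ALPHA_ADJ = 0.05


def hypergeom_upper(k: int, n_query: int, K_set: int, N_universe: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X ~ Hypergeometric(N_universe, K_set, n_query). k = 0 gives p = 1.
    """
    if not (0 <= k <= min(n_query, K_set)):
        raise ValueError(
            f"inconsistent counts: k={k}, n_query={n_query}, K_set={K_set}"
        )
    if K_set > N_universe or n_query > N_universe:
        raise ValueError("set or query larger than the universe")
    return float(stats.hypergeom.sf(k - 1, N_universe, K_set, n_query))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    p_adj_(i) = min_{j>=i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(
    query: list[str],
    sets: GeneSetCollection,
    universe: list[str],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    alpha_adj: float = DEFAULT_ALPHA_ADJ,
    top: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of ``query`` in each gene set.

    Gene sets are intersected with the universe before testing; the query
    must be a subset of the universe. Returns a DataFrame with columns
    set_name, overlap, set_size, expected, enrichment_ratio, p, p_adj,
    significant, sorted by p_adj ascending then enrichment_ratio
    descending; ``top`` limits the output to the first rows after sorting.
    An empty tested list (all overlaps below ``min_overlap``) yields an
    empty frame, not an error.
    """
    uni = set(universe)
    qset = set(query)
    for g in sorted(qset):
        if g not in uni:
            raise ValueError(f"query gene {g!r} is not in the universe")
    n_query = len(qset)
    n_universe = len(uni)
    rows = []
    for s in sets:
        members = set(s.genes) & uni
        if not members:
            continue
        overlap = len(qset & members)
        if overlap < min_overlap:
            continue
        K = len(members)
        expected = n_query * K / n_universe
        rows.append(
            (
                s.name,
                overlap,
                K,
                expected,
                overlap / expected,
                hypergeom_upper(overlap, n_query, K, n_universe),
            )
        )
    out = pd.DataFrame(
        rows,
        columns=["set_name", "overlap", "set_size", "expected",
                 "enrichment_ratio", "p"],
    )
    if out.empty:
        out["p_adj"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p_adj"] < alpha_adj
    out = out.sort_values(
        ["p_adj", "enrichment_ratio"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
    if top is not None:
        out = out.head(top)
    return out
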