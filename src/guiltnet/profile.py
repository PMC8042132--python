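"""Robust expression profiling: modified Z-scores and abundance ratios.

Genes are ranked within a tissue panel by the modified Z-score of their
mean expression, the Iglewicz-Hoaglin robust standardization

    z_i = 0.6745 * (x_i - median(x)) / MAD(x),   MAD = median(|x - median|),

whose 0.6745 factor makes z comparable to an ordinary Z-score under
normality while being insensitive to the heavy upper tail typical of
expression panels. Summarization order is mean-over-samples first, then z
across genes. A cross-gene abundance ratio (group-mean of one gene over
another) supports fold-difference statements between family members.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from guiltnet.io import validate_expression

MODIFIED_Z_CONSISTENCY = 0.6745
#: consistency factor for the mean-absolute-deviation fallback scale
MEANAD_CONSISTENCY = 0.7979


def modified_z(values, *, fallback_meanad: bool = False) -> np.ndarray:
    """Modified Z-score of each entry of ``values`` (length >= 3).

    Raises ``ValueError`` when the MAD is zero, which would leave the score
    undefined; passing ``fallback_meanad=True`` switches, in that case only
    by explicit request, to 0.7979*(x - median)/meanAD.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("modified Z-score needs >=3 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        if not fallback_meanad:
            raise ValueError(
                "MAD is zero; re-run with fallback_meanad=True to use the "
                "mean-absolute-deviation scale"
            )
        meanad = np.mean(np.abs(x - med))
        if meanad == 0:
            raise ValueError("all values identical; scale undefined")
        return MEANAD_CONSISTENCY * (x - med) / meanad
    return MODIFIED_Z_CONSISTENCY * (x - med) / mad


def profile(
    expr: pd.DataFrame,
    cutoff: float,
    *,
    fallback_meanad: bool = False,
) -> pd.DataFrame:
    """Rank genes by the modified Z-score of their panel-mean expression.

    Returns a DataFrame with columns gene_id, mean_expr, modified_z, high
    (z > cutoff), sorted by modified_z descending.
    """
    validate_expression(expr)
    means = expr.mean(axis=1)
    z = modified_z(means.to_numpy(), fallback_meanad=fallback_meanad)
    out = pd.DataFrame(
        {
            "gene_id": expr.index,
            "mean_expr": means.to_numpy(),
            "modified_z": z,
            "high": z > cutoff,
        }
    )
    return out.sort_values("modified_z", ascending=False, kind="stable").reset_index(
        drop=True
    )


def abundance_ratio(
    expr: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    sample_group: list[str] | None = None,
) -> float:
    """Ratio of group-mean expression of ``gene_a`` over ``gene_b``.

    ``sample_group`` restricts the mean to the named samples (default: all).
    The denominator mean must be positive.
    """
    for g in (gene_a, gene_b):
        if g not in expr.index:
            raise ValueError(f"gene {g!r} not in the expression matrix")
    cols = list(expr.columns) if sample_group is None else list(sample_group)
    if not cols:
        raise ValueError("sample group is empty")
    missing = [c for c in cols if c not in expr.columns]
    if missing:
        raise ValueError(f"unknown sample id(s): {', '.join(missing)}")
    mean_a = float(expr.loc[gene_a, cols].mean())
    mean_b = float(expr.loc[gene_b, cols].mean())
    if mean_b <= 0:
        raise ValueError(f"denominator gene {gene_b!r} has non-positive mean")
    return mean_a / mean_b
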