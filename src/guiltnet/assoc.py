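"""Strain-panel Pearson association screening (gene vs phenotype or gene).

Every (gene, trait) pair is tested with the sample Pearson coefficient and
its two-sided p-value from the t transform ``t = r*sqrt((n-2)/(1-r^2))``
with n-2 degrees of freedom, after pairwise deletion of missing trait
values. Significance is reported at raw p < alpha (default 0.05) with NO
multiple-testing correction: this mirrors the screening convention of
recombinant-inbred strain panel databases, where the raw threshold is the
published filter; FDR control belongs to the enrichment stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class AssociationResult:
    gene_id: str
    trait_id: str
    r: float
    n: int
    p: float
    significant: bool


def pearson_assoc(x, y) -> tuple[float, int, float]:
    """Pearson r, paired n, and two-sided p for two vectors.

    Missing values (NaN) are dropped pairwise. Requires >=3 complete pairs
    and nonzero variance in both vectors (a degenerate trait must surface as
    an error, not a silent r=0). |r| = 1 returns p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >=3 paired non-missing values, got {n}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the vectors")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-14:  # exact linear dependence up to rounding
        return float(np.sign(r)), n, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, n, float(min(p, 1.0))


def screen_associations(
    expr: pd.DataFrame,
    traits: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[pd.DataFrame, list[str]]:
    """Test every gene (row of ``expr``) against every trait column.

    Samples are matched by id between the expression columns and the trait
    rows; at least 3 must overlap. Traits with fewer than 3 non-missing
    values on the shared samples (or zero variance) are skipped and listed
    in the second return value; the screen continues.

    Returns a DataFrame with columns gene_id, trait_id, n, r, p,
    significant, sorted by p ascending then gene_id, and the list of
    skipped trait ids.
    """
    shared = [s for s in expr.columns if s in set(traits.index)]
    if len(shared) < 3:
        raise ValueError(
            f"expression and trait tables share only {len(shared)} sample ids; "
            "need >=3"
        )
    expr = expr[shared]
    traits = traits.loc[shared]
    rows = []
    skipped: list[str] = []
    for trait_id in traits.columns:
        tv = traits[trait_id].to_numpy(dtype=float)
        ok = np.isfinite(tv)
        if ok.sum() < 3 or np.nanstd(tv) == 0:
            skipped.append(trait_id)
            continue
        for gene_id in expr.index:
            gv = expr.loc[gene_id].to_numpy(dtype=float)
            try:
                r, n, p = pearson_assoc(gv, tv)
            except ValueError:
                # degenerate gene (zero variance on this trait's samples)
                continue
            rows.append((gene_id, trait_id, n, r, p, p < alpha))
    out = pd.DataFrame(
        rows, columns=["gene_id", "trait_id", "n", "r", "p", "significant"]
    )
    out = out.sort_values(["p", "gene_id"], kind="stable").reset_index(drop=True)
    return out, skipped
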