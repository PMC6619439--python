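"""Reference-gene stability and two-step -ddCt normalization.

Step 1 normalizes each sample's Ct values to the geometric mean of the most
stable housekeeping assays *within that sample*; because Ct is already a log2
quantity, the log of the geometric mean of linear abundances is exactly the
arithmetic mean of the Ct values (a common pitfall is averaging on the linear
scale).  The result, -dCt = mean(ref Ct) - Ct(gene), corrects for RNA input.

Step 2 median-centers each gene across all samples of the chosen scope,
yielding -ddCt: relative expression comparable across treatments and batches.

Reference stability is scored two ways and combined by rank:

* expression variance of the raw Ct across samples (lower = more stable);
* the geNorm M value: for candidates j, k the pairwise variation
  V_jk = SD over samples of (Ct_j - Ct_k), and M_j = mean of V_jk over k != j.
  Iteratively removing the worst (highest-M) candidate gives an exclusion
  order ending in the most stable pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CtMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class StabilityRanking:
    """Variance + geNorm stability scores for candidate reference assays."""

    table: pd.DataFrame  # per-assay: variance, m_value, var_rank, m_rank, combined_rank
    exclusion_order: list[str]  # worst first; last two are the final pair
    m_by_round: list[pd.Series] = field(default_factory=list)
    selected_reference_set: tuple[str, ...] = ()


def _pairwise_sd(values: pd.DataFrame, j: str, k: str, min_shared: int) -> float:
    diff = (values[j] - values[k]).dropna()
    if len(diff) < min_shared:
        raise ValueError(
            f"candidates {j!r} and {k!r} share only {len(diff)} detected samples "
            f"(need >= {min_shared})"
        )
    return float(diff.std(ddof=1))


def genorm_m(
    ct: CtMatrix | pd.DataFrame,
    candidates,
    min_shared: int = 3,
) -> StabilityRanking:
    """Compute geNorm M values with the iterative exclusion order.

    Returns a :class:`StabilityRanking` whose ``table`` holds the full-set M
    values together with Ct variances and rank combination, and whose
    ``m_by_round`` records the M values recomputed after each exclusion.
    """
    values = ct.values if isinstance(ct, CtMatrix) else ct
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("geNorm needs at least 2 candidate reference assays")
    absent = [c for c in candidates if c not in values.columns]
    if absent:
        raise ValueError(f"candidate assays not in matrix: {absent}")

    def m_values(assays: list[str]) -> pd.Series:
        m = {}
        for j in assays:
            sds = [_pairwise_sd(values, j, k, min_shared) for k in assays if k != j]
            m[j] = float(np.mean(sds))
        return pd.Series(m, name="m_value")

    full_m = m_values(candidates)
    variance = values[candidates].var(ddof=1)

    current = list(candidates)
    order: list[str] = []
    rounds: list[pd.Series] = [full_m]
    while len(current) > 2:
        m = rounds[-1] if len(rounds[-1]) == len(current) else m_values(current)
        # worst assay out; ties broken by higher variance, then name
        worst = sorted(current, key=lambda a: (-m[a], -variance[a], a))[0]
        current.remove(worst)
        order.append(worst)
        rounds.append(m_values(current))
    order.extend(sorted(current, key=lambda a: (full_m[a], variance[a], a), reverse=True))

    var_rank = variance.rank(method="average")
    m_rank = full_m[candidates].rank(method="average")
    table = pd.DataFrame(
        {
            "variance": variance,
            "m_value": full_m[candidates],
            "var_rank": var_rank,
            "m_rank": m_rank,
            "combined_rank": (var_rank + m_rank) / 2.0,
        }
    )
    return StabilityRanking(table=table, exclusion_order=order, m_by_round=rounds)


def select_reference_genes(
    ranking: StabilityRanking,
    n_refs: int = 2,
    never_select=(),
) -> list[str]:
    """Pick the ``n_refs`` most stable assays by combined rank.

    The combined rank is the unweighted mean of the variance rank and the
    geNorm M rank; ties go to the lower-variance assay (then name, for
    determinism).  Assays in ``never_select`` (designated independent
    controls such as Gapdh) are excluded from candidacy.
    """
    table = ranking.table.drop(index=[g for g in never_select if g in ranking.table.index])
    if n_refs > len(table):
        raise ValueError(f"n_refs={n_refs} exceeds {len(table)} selectable candidates")
    # stable tie-break: combined rank, then variance, then name
    ordered = sorted(table.index, key=lambda a: (table.at[a, "combined_rank"], table.at[a, "variance"], a))
    return list(ordered[:n_refs])


def neg_delta_ct(
    ct: CtMatrix,
    refs,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Step 1: -dCt(s, g) = mean of reference Ct in sample s - Ct(s, g).

    Samples in which any reference assay is a non-detect cannot be
    normalized and are dropped (returned in the second element with
    reasons).  Masked cells stay masked.
    """
    refs = list(refs)
    absent = [r for r in refs if r not in ct.assay_ids]
    if absent:
        raise ValueError(f"reference assays not in matrix: {absent}")
    ref_ct = ct.values[refs]
    ok = ref_ct.notna().all(axis=1)
    dropped = [
        (sid, f"reference non-detect: {', '.join(ref_ct.columns[ref_ct.loc[sid].isna()])}")
        for sid in ct.sample_ids[~ok]
    ]
    for sid, reason in dropped:
        logger.info("dropping sample %s: %s", sid, reason)
    if not ok.any():
        raise ValueError("no sample has all reference assays detected")
    vals = ct.values.loc[ok]
    ref_mean = vals[refs].mean(axis=1)  # arithmetic mean of Ct == log2 geometric mean
    ndct = ref_mean.to_numpy()[:, None] - vals
    return ndct, dropped


def median_center(
    ndct: pd.DataFrame,
    scope: str = "global",
    groups: pd.Series | None = None,
    reference_genes=(),
    control_genes=(),
) -> ExpressionMatrix:
    """Step 2: subtract each gene's median over the centering scope.

    ``scope="global"`` centers over all samples; ``scope="per-group"``
    centers within the groups given by ``groups`` (e.g. cell type).
    """
    if scope == "global":
        centered = ndct - ndct.median(axis=0, skipna=True)
    elif scope == "per-group":
        if groups is None:
            raise ValueError("per-group centering needs a groups series")
        centered = ndct.groupby(groups.loc[ndct.index]).transform(lambda x: x - x.median())
    else:
        raise ValueError(f"unknown centering scope: {scope!r}")
    empty = centered.columns[centered.notna().sum(axis=0) == 0]
    if len(empty):
        logger.warning("genes with no detected values after centering: %s", list(empty))
    return ExpressionMatrix(
        values=centered,
        reference_genes=tuple(reference_genes),
        centering_scope=scope,
        control_genes=tuple(control_genes),
    )


def normalize(
    ct: CtMatrix,
    refs,
    scope: str = "global",
    groups: pd.Series | None = None,
    control_genes=(),
) -> tuple[ExpressionMatrix, list[tuple[str, str]]]:
    """Full two-step -ddCt normalization (convenience wrapper)."""
    ndct, dropped = neg_delta_ct(ct, refs)
    expr = median_center(
        ndct, scope=scope, groups=groups,
        reference_genes=tuple(refs), control_genes=tuple(control_genes),
    )
    return expr, dropped


def zscore_by_gene(expr: ExpressionMatrix | pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene z-scores for heat-map display.

    Genes with zero variance (or a single observation) are flagged and set
    to 0 rather than producing infinities.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    mean = values.mean(axis=0, skipna=True)
    sd = values.std(axis=0, ddof=1, skipna=True)
    flagged = [g for g in values.columns if not np.isfinite(sd[g]) or sd[g] == 0.0]
    safe_sd = sd.replace(0.0, np.nan)
    z = (values - mean) / safe_sd
    z[flagged] = values[flagged].notna() * 0.0
    if flagged:
        logger.info("zero-variance genes set to z=0: %s", flagged)
    return z, flagged
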