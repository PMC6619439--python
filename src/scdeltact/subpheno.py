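"""Bimodal expression subphenotypes within a condition.

Some genes split one treatment's samples into distinct high- and
low-expressing subgroups (e.g. Mapk1 or cFos in withdrawal).  Detection
fits 1- vs 2-component Gaussian mixtures and calls bimodality when the
2-component model wins by a BIC margin AND both components carry enough
samples; the split point is the equal-posterior boundary between the two
component means.  Sample partitions anchored on one bimodal gene are then
profiled gene-by-gene (subgroup medians), optionally re-expressed relative
to the mean of a Placebo reference group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


@dataclass
class BimodalityCall:
    gene: str
    condition: str
    is_bimodal: bool
    split_point: float = np.nan
    means: tuple[float, float] = (np.nan, np.nan)
    sds: tuple[float, float] = (np.nan, np.nan)
    weights: tuple[float, float] = (np.nan, np.nan)
    delta_bic: float = np.nan  # BIC(1) - BIC(2); larger favors two components
    n: int = 0
    status: str = "ok"


def _fit_gmm(x: np.ndarray, k: int, seed: int):
    import warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        tol=1e-8,
        max_iter=500,
        n_init=3,
        init_params="k-means++",
        random_state=seed,
    )
    with warnings.catch_warnings():
        # the tight EM tolerance routinely trips the iteration cap on some
        # of the n_init restarts; the best restart is still well converged
        warnings.simplefilter("ignore", ConvergenceWarning)
        gm.fit(x)
    return gm


def equal_posterior_split(means, sds, weights) -> float:
    """x between the component means where the two posteriors are equal."""
    (m1, s1, w1), (m2, s2, w2) = sorted(zip(means, sds, weights))

    def diff(x):
        return w1 * stats.norm.pdf(x, m1, s1) - w2 * stats.norm.pdf(x, m2, s2)

    lo, hi = m1, m2
    if diff(lo) * diff(hi) < 0:
        return float(optimize.brentq(diff, lo, hi))
    # no crossing strictly between the means (rare, heavy overlap): midpoint
    return float((m1 + m2) / 2.0)


def detect_bimodality(
    values,
    gene: str = "",
    condition: str = "",
    min_group: int = 3,
    criterion_threshold: float = 6.0,
    seed: int = 0,
) -> BimodalityCall:
    """Call bimodality for one gene in one condition.

    ``criterion_threshold`` is the required BIC margin by which the
    2-component mixture must beat the single Gaussian (default 6, a
    conventional strong-evidence margin).  Too-small or degenerate inputs
    return a non-bimodal call with an explanatory status, not an exception.
    """
    x = pd.Series(values).dropna().to_numpy(dtype=float)
    n = len(x)
    if n < 2 * min_group:
        return BimodalityCall(gene, condition, False, n=n, status="insufficient data")
    if np.ptp(x) == 0.0:
        return BimodalityCall(gene, condition, False, n=n, status="degenerate (constant)")
    X = x.reshape(-1, 1)
    g1 = _fit_gmm(X, 1, seed)
    g2 = _fit_gmm(X, 2, seed)
    delta = float(g1.bic(X) - g2.bic(X))
    means = tuple(sorted(float(m) for m in g2.means_.ravel()))
    order = np.argsort(g2.means_.ravel())
    sds = tuple(float(np.sqrt(g2.covariances_.ravel()[i])) for i in order)
    weights = tuple(float(g2.weights_[i]) for i in order)
    call = BimodalityCall(
        gene, condition, False,
        means=means, sds=sds, weights=weights, delta_bic=delta, n=n,
    )
    if delta <= criterion_threshold:
        call.status = "BIC favors one component"
        return call
    if min(weights) < min_group / n:
        call.status = "minor component below weight floor"
        return call
    split = equal_posterior_split(means, sds, weights)
    low = int((x <= split).sum())
    high = n - low
    if min(low, high) < min_group:
        call.status = f"subgroup of {min(low, high)} below min_group={min_group}"
        return call
    call.is_bimodal = True
    call.split_point = split
    return call


def scan_bimodality(
    expr,
    meta: pd.DataFrame,
    conditions=None,
    genes=None,
    **kwargs,
) -> pd.DataFrame:
    """Run detection for every (treatment, gene); returns a tidy table."""
    values = expr.values if hasattr(expr, "analysis_genes") else expr
    if genes is None:
        genes = expr.analysis_genes() if hasattr(expr, "analysis_genes") else list(values.columns)
    trt = meta.loc[values.index, "treatment"]
    # a condition is a treatment within one cell type (distributions pooled
    # across cell types would mask cell-type-specific splits)
    if "cell_type" in meta.columns and meta.loc[values.index, "cell_type"].nunique() > 1:
        cell = meta.loc[values.index, "cell_type"]
        groups = trt.astype(str) + ":" + cell.astype(str)
    else:
        groups = trt.astype(str)
    if conditions is not None:
        keep = groups.map(lambda g: any(g == c or g.startswith(f"{c}:") for c in conditions))
    else:
        keep = pd.Series(True, index=groups.index)
    rows = []
    for cond, idx in groups[keep].groupby(groups[keep]).groups.items():
        sub = values.loc[idx]
        for g in genes:
            call = detect_bimodality(sub[g], gene=g, condition=str(cond), **kwargs)
            rows.append(vars(call))
    return pd.DataFrame(rows)


@dataclass
class SubgroupProfiles:
    anchor_gene: str
    split_point: float
    low_samples: list[str]
    high_samples: list[str]
    profiles: pd.DataFrame = field(default_factory=pd.DataFrame)  # genes x {low, high}


def split_and_profile(
    expr,
    call: BimodalityCall,
    placebo_ref: pd.DataFrame | None = None,
    min_group: int = 3,
) -> SubgroupProfiles:
    """Partition a condition's samples at the anchor gene's split point.

    ``expr`` holds the condition subset (samples x genes).  When
    ``placebo_ref`` is given (Placebo samples x the same genes), profiles
    are expressed relative to the mean of Placebo expression per gene.
    """
    if not call.is_bimodal:
        raise ValueError(f"anchor gene {call.gene!r} was not called bimodal ({call.status})")
    values = expr.values if hasattr(expr, "analysis_genes") else expr
    anchor = values[call.gene].dropna()
    low = anchor.index[anchor <= call.split_point].tolist()
    high = anchor.index[anchor > call.split_point].tolist()
    if min(len(low), len(high)) < min_group:
        raise ValueError(
            f"subgroup of {min(len(low), len(high))} samples below min_group={min_group}"
        )
    prof = pd.DataFrame(
        {
            "low": values.loc[low].median(axis=0, skipna=True),
            "high": values.loc[high].median(axis=0, skipna=True),
        }
    )
    if placebo_ref is not None:
        prof = prof.sub(placebo_ref.mean(axis=0, skipna=True), axis=0)
    return SubgroupProfiles(
        anchor_gene=call.gene,
        split_point=call.split_point,
        low_samples=low,
        high_samples=high,
        profiles=prof,
    )
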