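"""Quality control for Ct matrices.

Two gene-level/sample-level rules plus a marker-based cell-identity check:

* an assay that fails within *any one* batch (non-detect fraction at or above
  a threshold, default complete failure) is excluded from the entire dataset,
  never batch-locally — a partially contaminated assay cannot be trusted in
  the batches where it "worked";
* a sample is dropped when too much of it is missing or its housekeeping Ct
  values fall outside a plausible window (too little or too much input RNA);
* each cell type must express its own marker (NeuN for neurons, Maf for
  microglia, Gfap for astrocytes) above the other cell types' markers.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import CtMatrix, QcReport, count_datapoints

logger = logging.getLogger(__name__)


def exclude_failed_assays(
    ct: CtMatrix,
    meta: pd.DataFrame,
    failure_rule: float = 1.0,
) -> tuple[CtMatrix, QcReport]:
    """Remove assays that failed within any single batch, from all batches.

    ``failure_rule`` is the per-batch non-detect fraction at which an assay
    counts as failed in that batch (1.0 = only complete failure triggers).
    """
    if not 0.0 < failure_rule <= 1.0:
        raise ValueError("failure_rule must be in (0, 1]")
    if "batch_id" not in meta.columns:
        raise ValueError("batch_id required for batch-failure QC")
    batches = meta.loc[ct.sample_ids, "batch_id"]
    nondetect_frac = (~ct.detect).groupby(batches).mean()  # batches x assays
    failed = {}
    for assay in ct.assay_ids:
        over = nondetect_frac.index[nondetect_frac[assay] >= failure_rule]
        if len(over):
            failed[assay] = str(over[0])
    keep = [a for a in ct.assay_ids if a not in failed]
    if not keep:
        raise ValueError("no assays survive QC")
    out = ct.subset(assays=keep)
    report = QcReport(
        excluded_assays=[
            (a, f"non-detect fraction >= {failure_rule:g} in batch {b}")
            for a, b in failed.items()
        ],
        n_datapoints_retained=count_datapoints(out),
    )
    for a, reason in report.excluded_assays:
        logger.info("excluding assay %s: %s", a, reason)
    return out, report


def sample_qc(
    ct: CtMatrix,
    max_missing_frac: float = 0.3,
    hk_genes=(),
    hk_ct_range: tuple[float, float] = (5.0, 35.0),
) -> tuple[CtMatrix, QcReport]:
    """Drop samples with excess missingness or implausible housekeeping Ct."""
    missing = [g for g in hk_genes if g not in ct.assay_ids]
    if missing:
        raise ValueError(f"housekeeping assays not in matrix: {missing}")
    dropped: list[tuple[str, str]] = []
    miss_frac = (~ct.detect).mean(axis=1)
    lo, hi = hk_ct_range
    for sid in ct.sample_ids:
        if miss_frac[sid] > max_missing_frac:
            dropped.append((sid, f"missing fraction {miss_frac[sid]:.2f} > {max_missing_frac:g}"))
            continue
        for g in hk_genes:
            v = ct.values.at[sid, g]
            if np.isfinite(v) and not (lo <= v <= hi):
                dropped.append((sid, f"housekeeping {g} Ct {v:.2f} outside [{lo:g}, {hi:g}]"))
                break
    bad = {s for s, _ in dropped}
    keep = [s for s in ct.sample_ids if s not in bad]
    if not keep:
        raise ValueError("all samples dropped by sample QC")
    out = ct.subset(samples=keep)
    for s, reason in dropped:
        logger.info("dropping sample %s: %s", s, reason)
    report = QcReport(excluded_samples=dropped, n_datapoints_retained=count_datapoints(out))
    return out, report


def validate_celltype_markers(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    marker_map: dict[str, str],
) -> pd.DataFrame:
    """Check that each cell type's own marker dominates the others' markers.

    For every cell type the median expression of each marker assay is
    computed over that cell type's samples; the check passes iff the own
    marker's median is strictly the greatest.

    Returns a frame indexed by cell type with one median column per marker
    plus a boolean ``passed`` column.
    """
    markers = list(marker_map.values())
    absent = [m for m in markers if m not in expr.columns]
    if absent:
        raise ValueError(f"marker assays not in expression matrix: {absent}")
    cts = meta.loc[expr.index, "cell_type"]
    rows = {}
    for cell_type, own in marker_map.items():
        sub = expr.loc[cts == cell_type, markers]
        med = sub.median(axis=0)
        others = med.drop(own)
        rows[cell_type] = {
            **{f"median_{m}": med[m] for m in markers},
            "own_marker": own,
            "passed": bool(np.isfinite(med[own]) and (med[own] > others).all()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
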