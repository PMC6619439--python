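"""Core data containers shared across the pipeline.

The unit of measurement throughout is a *sample*: a 10-cell pool of
laser-captured cells of one type (or one cecal specimen for the microbiome
panel).  Raw measurements are qPCR cycle-threshold (Ct) values; a lower Ct
means more template.  Non-detects (reactions that never crossed threshold)
are encoded as NaN and propagate as missing — they are never imputed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Treatment labels in canonical order.
TREATMENTS = ("Placebo", "Morphine", "Naltrexone", "Withdrawal")

#: Cell types of the brain panels plus the cecal (gut) panel.
CELL_TYPES = ("neuron", "microglia", "astrocyte", "cecal")

#: Required columns of a sample-annotation table (besides the sample_id index).
META_COLUMNS = ("animal_id", "treatment", "cell_type", "batch_id")


@dataclass
class CtMatrix:
    """Raw Ct values, samples x assays, with non-detects as NaN.

    Parameters
    ----------
    values
        DataFrame indexed by sample_id with assay_ids as columns.  NaN marks
        a non-detect / failed reaction.
    ct_range
        Plausible Ct range in PCR cycles.  Detected values outside it raise a
        warning (they are retained; dropping is a QC policy decision).
    """

    values: pd.DataFrame
    ct_range: tuple[float, float] = (0.0, 40.0)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate assay ids: {dups}")
        self.values = self.values.astype(float)
        lo, hi = self.ct_range
        vals = self.values.to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            bad = np.nansum((vals < lo) | (vals > hi))
        if bad:
            warnings.warn(
                f"{int(bad)} detected Ct values outside plausible range {self.ct_range}",
                stacklevel=2,
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def assay_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def detect(self) -> pd.DataFrame:
        """Boolean detect mask (False = non-detect)."""
        return self.values.notna()

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_assays(self) -> int:
        return self.values.shape[1]

    def subset(self, samples=None, assays=None) -> "CtMatrix":
        vals = self.values
        if samples is not None:
            vals = vals.loc[list(samples)]
        if assays is not None:
            vals = vals[list(assays)]
        return CtMatrix(vals.copy(), ct_range=self.ct_range)


@dataclass
class ExpressionMatrix:
    """Normalized relative expression (-ddCt), samples x assays.

    Values are on the log2 scale: one unit is one PCR cycle, i.e. a two-fold
    change in template.  Higher values mean more expressed.  The container
    records its normalization provenance: which reference assays were used
    and over which grouping the per-gene median was centered.
    """

    values: pd.DataFrame
    reference_genes: tuple[str, ...] = ()
    centering_scope: str = "global"
    control_genes: tuple[str, ...] = ()

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def assay_ids(self) -> pd.Index:
        return self.values.columns

    def analysis_genes(self) -> list[str]:
        """Assays eligible for differential/network analysis.

        Reference genes are excluded by construction (their -ddCt carries no
        biology); designated control assays (e.g. Gapdh) are retained.
        """
        drop = set(self.reference_genes)
        return [g for g in self.values.columns if g not in drop]


@dataclass
class QcReport:
    """Exact bookkeeping of what QC removed and why."""

    excluded_assays: list[tuple[str, str]] = field(default_factory=list)
    excluded_samples: list[tuple[str, str]] = field(default_factory=list)
    n_datapoints_retained: int = 0

    def merged_with(self, other: "QcReport") -> "QcReport":
        return QcReport(
            excluded_assays=self.excluded_assays + other.excluded_assays,
            excluded_samples=self.excluded_samples + other.excluded_samples,
            n_datapoints_retained=other.n_datapoints_retained,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [("assay", a, r) for a, r in self.excluded_assays]
        rows += [("sample", s, r) for s, r in self.excluded_samples]
        return pd.DataFrame(rows, columns=["kind", "id", "reason"])


def count_datapoints(ct: CtMatrix) -> int:
    """Retained data points = cells of the matrix that are detected."""
    return int(ct.detect.to_numpy().sum())


def validate_sample_meta(meta: pd.DataFrame, ct: CtMatrix | None = None) -> pd.DataFrame:
    """Check a sample-annotation table against the nested design invariants.

    Every sample must map to exactly one (animal, treatment); every animal to
    exactly one treatment.  Returns the validated frame (indexed by
    sample_id) unchanged.
    """
    if meta.index.name != "sample_id":
        if "sample_id" in meta.columns:
            meta = meta.set_index("sample_id")
        else:
            raise ValueError("sample annotations need a sample_id column or index")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample annotations missing columns: {missing}")
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in annotations: {dups}")
    per_animal = meta.groupby("animal_id")["treatment"].nunique()
    conflicted = per_animal[per_animal > 1].index.tolist()
    if conflicted:
        raise ValueError(f"animals mapped to multiple treatments: {conflicted}")
    if ct is not None:
        absent = ct.sample_ids.difference(meta.index).tolist()
        if absent:
            raise ValueError(f"samples without annotations: {absent[:10]}")
    if "pool_size" not in meta.columns:
        meta = meta.copy()
        meta["pool_size"] = 10
    return meta
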