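"""Readers and writers for the delimited tables the pipeline consumes.

Ct tables are wide TSV/CSV with samples either in rows or in columns;
non-detects may be encoded by sentinel tokens ("999", "NA", empty cell).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CtMatrix, QcReport, validate_sample_meta

logger = logging.getLogger(__name__)

DEFAULT_NONDETECT_TOKENS = ("999", "NA", "N/A", "ND", "NaN", "nan", "")


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)


def read_ct_matrix(
    path,
    layout: str = "samples-in-rows",
    nondetect_tokens=DEFAULT_NONDETECT_TOKENS,
    ct_range=(0.0, 40.0),
) -> CtMatrix:
    """Read a wide Ct table into a :class:`CtMatrix`.

    Parameters
    ----------
    layout
        ``"samples-in-rows"`` (default) or ``"samples-in-columns"``; the
        latter is transposed on read so both orientations yield the same
        matrix.
    nondetect_tokens
        Cell contents mapped to the non-detect mask.  Anything else must
        parse as a number; a non-numeric cell is a hard error naming its
        row and column.
    """
    if layout not in {"samples-in-rows", "samples-in-columns"}:
        raise ValueError(f"unknown layout: {layout!r}")
    raw = _read_table(path)
    if layout == "samples-in-columns":
        raw = raw.T
    raw.index.name = None
    raw.columns.name = None
    tokens = {str(t).strip() for t in nondetect_tokens}
    values = pd.DataFrame(np.nan, index=raw.index, columns=raw.columns)
    for col in raw.columns:
        stripped = raw[col].str.strip()
        mask = ~stripped.isin(tokens)
        parsed = pd.to_numeric(stripped[mask], errors="coerce")
        bad = parsed.index[parsed.isna()]
        if len(bad):
            raise ValueError(
                f"non-numeric Ct value {raw.loc[bad[0], col]!r} at "
                f"sample {bad[0]!r}, assay {col!r}"
            )
        values.loc[mask, col] = parsed.astype(float)
    ct = CtMatrix(values, ct_range=ct_range)
    logger.info(
        "read %d samples x %d assays from %s (%d non-detects)",
        ct.n_samples, ct.n_assays, path, int((~ct.detect).to_numpy().sum()),
    )
    return ct


def read_sample_meta(path) -> pd.DataFrame:
    """Read a sample-annotation TSV/CSV and validate the nested design."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    meta = pd.read_csv(path, sep=sep, dtype=str)
    if "pool_size" in meta.columns:
        meta["pool_size"] = pd.to_numeric(meta["pool_size"])
    return validate_sample_meta(meta)


def write_ct_matrix(ct: CtMatrix, path, nondetect_token: str = "NA") -> None:
    out = ct.values.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep=nondetect_token)


def write_qc_report(report: QcReport, tsv_path, json_path=None) -> None:
    report.to_frame().to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {
            "excluded_assays": [list(x) for x in report.excluded_assays],
            "excluded_samples": [list(x) for x in report.excluded_samples],
            "n_datapoints_retained": report.n_datapoints_retained,
        }
        Path(json_path).write_text(json.dumps(payload, indent=2))
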