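"""Gut-microflora relative abundance and the Firmicutes:Bacteroides ratio.

Taxon qPCR panels are normalized exactly like the brain panels, with the
pan-bacterial / universal primer controls as the reference assays, yielding
per-taxon -ddCt relative abundances.  The headline dysbiosis statistic is
the Firmicutes-to-Bacteroides ratio, displayed per treatment as

    (F + NF) : (B + NF)   with  NF = 1 - F,

where F and B are the per-treatment median -ddCt of the dedicated
phylum-level Firmicutes and Bacteroides assays.  The normalization factor
NF anchors the Firmicutes side to exactly 1 so the right-hand side alone
carries the comparison; NF is recomputed per treatment, never a fixed
constant.  An explicit NF override is accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import TREATMENTS, CtMatrix, ExpressionMatrix
from .normalization import normalize

logger = logging.getLogger(__name__)

RANKS = ("phylum", "class", "genus", "species", "subgroup")

#: Fig-8-style significance tiers for induced/suppressed taxa.
ABUNDANCE_TIERS = ((0.0009, "***"), (0.008, "**"), (0.05, "*"), (0.1, "#"))


@dataclass
class TaxonPanel:
    """Taxon assay annotations: rank, phylum membership, control flag."""

    table: pd.DataFrame  # index = assay; columns: rank, phylum, is_control

    def __post_init__(self) -> None:
        need = {"rank", "phylum", "is_control"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"taxon panel missing columns: {sorted(missing)}")
        self.table = self.table.copy()
        self.table["is_control"] = self.table["is_control"].astype(bool)
        if not self.table["is_control"].any():
            raise ValueError("taxon panel needs at least one control assay")
        taxa = self.table[~self.table["is_control"]]
        unranked = taxa.index[~taxa["rank"].isin(RANKS)].tolist()
        if unranked:
            raise ValueError(f"taxa with missing/unknown rank: {unranked}")

    @property
    def control_assays(self) -> list[str]:
        return self.table.index[self.table["is_control"]].tolist()

    def phylum_assay(self, phylum: str) -> str:
        hit = self.table.index[
            (self.table["rank"] == "phylum") & (self.table["phylum"] == phylum)
        ]
        if len(hit) != 1:
            raise ValueError(f"need exactly one phylum-level assay for {phylum!r}, found {len(hit)}")
        return str(hit[0])

    def members(self, phylum: str) -> list[str]:
        sub = self.table[~self.table["is_control"]]
        return sub.index[(sub["phylum"] == phylum) & (sub["rank"] != "phylum")].tolist()


def read_taxon_panel(path) -> TaxonPanel:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    table = pd.read_csv(path, sep=sep, index_col="assay")
    if table["is_control"].dtype == object:
        table["is_control"] = table["is_control"].astype(str).str.lower().isin(
            {"true", "1", "yes"}
        )
    return TaxonPanel(table)


def normalize_abundance(
    ct: CtMatrix,
    panel: TaxonPanel,
    scope: str = "global",
) -> tuple[ExpressionMatrix, list[tuple[str, str]]]:
    """Two-step -ddCt of the taxon panel against the pan-bacterial controls.

    Shares the brain pipeline's normalization code path; samples whose
    control assays are non-detects are dropped and logged.
    """
    return normalize(ct, refs=panel.control_assays, scope=scope)


def display_round(x: float, decimals: int = 2) -> float:
    """Half-even rounding on the decimal representation (display convention)."""
    return float(Decimal(f"{x:.10f}").quantize(Decimal(10) ** -decimals, ROUND_HALF_EVEN))


def ratio_from_medians(f: float, b: float, nf: float | None = None) -> dict:
    """NF-adjusted ratio from phylum medians: (F+NF):(B+NF) with NF = 1 - F.

    The left side is exactly 1 by construction.  Returns the full-precision
    right-hand side plus its 2-decimal display value; a non-positive
    B + NF makes the ratio undefined and is flagged, never clipped.
    """
    nf = (1.0 - f) if nf is None else float(nf)
    rhs = b + nf
    defined = rhs > 0
    if not defined:
        logger.warning("F:B ratio undefined: B + NF = %.4f <= 0", rhs)
    return {
        "F": f,
        "B": b,
        "NF": nf,
        "ratio_rhs": rhs if defined else np.nan,
        "ratio_display": f"1 : {display_round(rhs)}" if defined else "undefined",
        "defined": defined,
    }


@dataclass
class RatioReport:
    table: pd.DataFrame  # rows F, B, NF, ratio_rhs; columns = treatments
    display: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.loc["ratio"] = [self.display[t] for t in out.columns]
        return out


def fb_ratio(
    expr,
    panel: TaxonPanel,
    meta: pd.DataFrame,
    treatments=TREATMENTS,
    nf_override: float | None = None,
) -> RatioReport:
    """Per-treatment Firmicutes:Bacteroides ratio report.

    F and B are the medians of the dedicated phylum-level assays over each
    treatment's samples (single assays, not aggregates over member taxa).
    """
    values = expr.values if hasattr(expr, "analysis_genes") else expr
    f_assay = panel.phylum_assay("Firmicutes")
    b_assay = panel.phylum_assay("Bacteroides")
    trt = meta.loc[values.index, "treatment"]
    cols, display = {}, {}
    for t in treatments:
        sub = values.loc[trt == t]
        if sub.empty:
            raise ValueError(f"no samples for treatment {t!r}")
        rec = ratio_from_medians(
            float(sub[f_assay].median(skipna=True)),
            float(sub[b_assay].median(skipna=True)),
            nf=nf_override,
        )
        cols[t] = [rec["F"], rec["B"], rec["NF"], rec["ratio_rhs"]]
        display[t] = rec["ratio_display"]
    table = pd.DataFrame(cols, index=["F", "B", "NF", "ratio_rhs"])
    return RatioReport(table=table, display=display)


def abundance_flag(p: float, tiers=ABUNDANCE_TIERS) -> str:
    if not np.isfinite(p):
        return ""
    for thr, sym in tiers:
        if p < thr:
            return sym
    return ""


def classify_direction(
    results: pd.DataFrame,
    expr,
    meta: pd.DataFrame,
    reference: str = "Placebo",
    target: str = "Withdrawal",
) -> pd.DataFrame:
    """Partition taxa into withdrawal-induced / -suppressed / unchanged.

    Direction is the sign of (target median - reference median); the
    significance tier flags the target-vs-reference contrast p at the
    0.1 / 0.05 / 0.008 / 0.0009 levels.
    """
    values = expr.values if hasattr(expr, "analysis_genes") else expr
    trt = meta.loc[values.index, "treatment"]
    out = []
    contrast_col = f"p_{target}_vs_{reference}"
    for taxon in results.index:
        delta = float(
            values.loc[trt == target, taxon].median(skipna=True)
            - values.loc[trt == reference, taxon].median(skipna=True)
        )
        if delta > 0:
            direction = "induced"
        elif delta < 0:
            direction = "suppressed"
        else:
            direction = "none"
        p = results.at[taxon, contrast_col] if contrast_col in results.columns else np.nan
        out.append(
            {
                "taxon": taxon,
                "delta_median": delta,
                "direction": direction,
                "p_contrast": p,
                "flag": abundance_flag(p) if direction != "none" else "",
            }
        )
    return pd.DataFrame(out).set_index("taxon")
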