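"""Differential expression and abundance statistics.

The experimental unit is the animal (n = 4 per treatment); 10-cell pools are
technical-level replicates nested within animals.  Testing treatment effects
against pool-level noise would treat correlated pools as independent and
inflate false positives, so the nested ANOVA uses the animal stratum as the
error term:

* ``animal_means`` (default, works unbalanced): average pools within each
  animal, then one-way ANOVA across treatments on the animal means;
* ``balanced_ems``: the classical expected-mean-square decomposition
  F = MS_treatment / MS_animal(treatment) with df (T-1, A-T).  On balanced
  data the two give identical F.

The microbiome panel uses a two-way treatment x taxon ANOVA plus the two
per-taxon contrasts the figures annotate (Withdrawal vs Morphine, Withdrawal
vs Placebo).  Multiple testing uses Benjamini-Hochberg q values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Significance tiers used to flag differential-expression results.
EXPRESSION_STARS = ((0.0001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class AnovaResult:
    f: float
    df1: int
    df2: int
    p: float
    method: str


def _check_design(treatment: pd.Series, animal: pd.Series) -> None:
    if treatment.nunique() < 2:
        raise ValueError("nested ANOVA needs >= 2 treatments")
    animals_per = treatment.groupby(animal).first().value_counts()
    thin = animals_per[animals_per < 2]
    if len(thin):
        raise ValueError(
            f"treatments with < 2 animals: {list(thin.index)} — no valid F test"
        )


def nested_anova(
    values: pd.Series,
    treatment: pd.Series,
    animal: pd.Series,
    method: str = "animal_means",
) -> AnovaResult:
    """Treatment F test with animals nested in treatments as the error term."""
    df = pd.DataFrame({"y": values, "trt": treatment, "animal": animal}).dropna()
    _check_design(df["trt"], df["animal"])
    if np.ptp(df["y"].to_numpy()) == 0.0:
        # no variation at all: nothing to explain
        t = df["trt"].nunique()
        a = df.groupby("trt")["animal"].nunique().sum()
        return AnovaResult(0.0, t - 1, int(a - t), 1.0, method)
    if method == "animal_means":
        means = df.groupby(["trt", "animal"], observed=True)["y"].mean()
        groups = [g.to_numpy() for _, g in means.groupby(level="trt", observed=True)]
        t = len(groups)
        a = sum(len(g) for g in groups)
        grand = np.concatenate(groups).mean()
        ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
        df1, df2 = t - 1, a - t
        if ss_w == 0.0:
            warnings.warn("zero between-animal variance; p undefined", stacklevel=2)
            return AnovaResult(np.inf if ss_b > 0 else 0.0, df1, df2, np.nan, method)
        f = (ss_b / df1) / (ss_w / df2)
        return AnovaResult(float(f), df1, df2, float(stats.f.sf(f, df1, df2)), method)
    if method == "balanced_ems":
        counts = df.groupby(["trt", "animal"], observed=True)["y"].count()
        if counts.nunique() != 1:
            raise ValueError("balanced_ems requires equal pools per animal")
        n_animals = df.groupby("trt")["animal"].nunique()
        if n_animals.nunique() != 1:
            raise ValueError("balanced_ems requires equal animals per treatment")
        n_p = int(counts.iloc[0])
        t = int(n_animals.size)
        a_per = int(n_animals.iloc[0])
        grand = df["y"].mean()
        trt_means = df.groupby("trt")["y"].mean()
        an_means = df.groupby(["trt", "animal"], observed=True)["y"].mean()
        ss_trt = (a_per * n_p * (trt_means - grand) ** 2).sum()
        ss_an = (n_p * (an_means - trt_means.reindex(an_means.index.get_level_values("trt")).to_numpy()) ** 2).sum()
        df1 = t - 1
        df2 = t * (a_per - 1)
        ms_trt = ss_trt / df1
        ms_an = ss_an / df2
        if ms_an == 0.0:
            warnings.warn("zero animal-stratum mean square; p undefined", stacklevel=2)
            return AnovaResult(np.inf if ms_trt > 0 else 0.0, df1, df2, np.nan, method)
        f = ms_trt / ms_an
        return AnovaResult(float(f), df1, df2, float(stats.f.sf(f, df1, df2)), method)
    raise ValueError(f"unknown method: {method!r}")


def pooled_anova(values: pd.Series, treatment: pd.Series) -> AnovaResult:
    """Naive one-way ANOVA on pools, ignoring the animal level.

    Provided for comparison only: with animal-level random effects its
    type-I error is inflated because pools from one animal are correlated.
    """
    df = pd.DataFrame({"y": values, "trt": treatment}).dropna()
    groups = [g.to_numpy() for _, g in df.groupby("trt")["y"]]
    f, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = len(df) - len(groups)
    return AnovaResult(float(f), df1, df2, float(p), "pooled")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q values (monotone); NaN p's stay NaN."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("bh_adjust: %d NaN p values excluded from adjustment", n_bad)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def significance_flag(p: float, tiers=EXPRESSION_STARS) -> str:
    if not np.isfinite(p):
        return ""
    for thr, sym in tiers:
        if p < thr:
            return sym
    return ""


def differential_table(
    expr,
    meta: pd.DataFrame,
    genes=None,
    method: str = "animal_means",
) -> pd.DataFrame:
    """Per-gene nested ANOVA with BH q values and per-treatment medians."""
    values = expr.values if hasattr(expr, "values") and not isinstance(expr, pd.DataFrame) else expr
    if genes is None:
        genes = expr.analysis_genes() if hasattr(expr, "analysis_genes") else list(values.columns)
    trt = meta.loc[values.index, "treatment"]
    animal = meta.loc[values.index, "animal_id"]
    rows = []
    for g in genes:
        try:
            res = nested_anova(values[g], trt, animal, method=method)
        except ValueError as exc:
            logger.warning("gene %s: %s", g, exc)
            continue
        row = {"gene": g, "F": res.f, "df1": res.df1, "df2": res.df2, "p": res.p}
        for t, grp in values[g].groupby(trt):
            row[f"median_{t}"] = float(grp.median())
        rows.append(row)
    out = pd.DataFrame(rows).set_index("gene")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["flag"] = [significance_flag(p) for p in out["p"]]
    return out


def two_way_anova(
    values: pd.Series,
    factor_a: pd.Series,
    factor_b: pd.Series,
    names: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA table with interaction (type II SS).

    Raises if any cell of the A x B design is empty, listing the cells.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": values, "fa": factor_a, "fb": factor_b}).dropna()
    cells = df.groupby(["fa", "fb"], observed=True).size()
    full = pd.MultiIndex.from_product([df["fa"].unique(), df["fb"].unique()])
    empty = [c for c in full if c not in cells.index]
    if empty:
        raise ValueError(f"empty design cells: {empty}")
    model = smf.ols("y ~ C(fa) * C(fb)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={
            "C(fa)": names[0],
            "C(fb)": names[1],
            "C(fa):C(fb)": f"{names[0]}:{names[1]}",
        }
    )
    return table


def differential_abundance(
    expr,
    meta: pd.DataFrame,
    taxa=None,
    design: str = "treatment_by_taxon",
    contrasts=(("Withdrawal", "Morphine"), ("Withdrawal", "Placebo")),
) -> pd.DataFrame:
    """Per-taxon treatment statistics for the microbial panel.

    ``design="treatment_by_taxon"`` fits the two-way treatment x taxon model
    once over the whole panel (the overall treatment and interaction terms
    are logged); ``design="per_taxon"`` runs an independent one-way
    treatment ANOVA per taxon.  Either way the table carries the per-taxon
    one-way p plus Welch contrasts for the listed treatment pairs.
    """
    values = expr.values if hasattr(expr, "values") and not isinstance(expr, pd.DataFrame) else expr
    if taxa is None:
        taxa = expr.analysis_genes() if hasattr(expr, "analysis_genes") else list(values.columns)
    trt = meta.loc[values.index, "treatment"]
    if design == "treatment_by_taxon":
        long = values[list(taxa)].stack().rename("y").reset_index()
        long.columns = ["sample_id", "taxon", "y"]
        long["treatment"] = trt.loc[long["sample_id"]].to_numpy()
        table = two_way_anova(
            long["y"], long["treatment"], long["taxon"], names=("treatment", "taxon")
        )
        logger.info("two-way treatment x taxon ANOVA:\n%s", table)
    elif design != "per_taxon":
        raise ValueError(f"unknown design: {design!r}")
    rows = []
    for taxon in taxa:
        y = values[taxon]
        groups = {t: g.dropna().to_numpy() for t, g in y.groupby(trt)}
        if np.ptp(np.concatenate(list(groups.values()))) == 0.0:
            f, p = 0.0, 1.0  # no variation anywhere: nothing to explain
        else:
            f, p = stats.f_oneway(*groups.values())
        row = {"taxon": taxon, "F": float(f), "p": float(p)}
        for t, g in groups.items():
            row[f"median_{t}"] = float(np.median(g)) if len(g) else np.nan
        for a, b in contrasts:
            if a in groups and b in groups:
                _, cp = stats.ttest_ind(groups[a], groups[b], equal_var=False)
                row[f"p_{a}_vs_{b}"] = float(cp)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("taxon")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
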