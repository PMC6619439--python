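"""Taxon panel normalization and the NF-adjusted F:B ratio."""

import numpy as np
import pandas as pd
import pytest

import scdeltact as sd
from scdeltact.microbiome import display_round
from scdeltact.simulate import default_taxon_table

# printed phylum medians: Placebo, Morphine, Naltrexone, Withdrawal
F_MEDIANS = {"Placebo": -0.487, "Morphine": 0.359, "Naltrexone": 0.151, "Withdrawal": -0.726}
B_MEDIANS = {"Placebo": -0.741, "Morphine": 0.391, "Naltrexone": -0.424, "Withdrawal": 2.943}


class TestRatioFromMedians:
    def test_withdrawal_worked_example(self):
        rec = sd.ratio_from_medians(-0.726, 2.943)
        assert rec["NF"] == pytest.approx(1.726)
        assert rec["ratio_display"] == "1 : 4.67"

    def test_placebo_worked_example(self):
        rec = sd.ratio_from_medians(-0.487, -0.741)
        assert rec["NF"] == pytest.approx(1.487)
        assert rec["ratio_display"] == "1 : 0.75"

    def test_left_side_is_exactly_one(self):
        for f in (-3.0, -0.5, 0.0, 0.7, 2.0):
            rec = sd.ratio_from_medians(f, 1.0)
            assert rec["F"] + rec["NF"] == pytest.approx(1.0)

    def test_equal_medians_give_one_to_one(self):
        for f in (-1.2, 0.0, 0.8):
            assert sd.ratio_from_medians(f, f)["ratio_display"] == "1 : 1.0"

    def test_nonpositive_denominator_flagged_not_clipped(self):
        rec = sd.ratio_from_medians(0.5, -2.0)  # B + NF = -1.5
        assert not rec["defined"]
        assert np.isnan(rec["ratio_rhs"])

    def test_shift_invariance_only_when_nf_recomputed(self):
        base = sd.ratio_from_medians(-0.5, 1.0)
        shifted = sd.ratio_from_medians(-0.5 + 2.0, 1.0 + 2.0)
        assert shifted["ratio_rhs"] == pytest.approx(base["ratio_rhs"])
        fixed_nf = sd.ratio_from_medians(-0.5 + 2.0, 1.0 + 2.0, nf=base["NF"])
        assert fixed_nf["ratio_rhs"] != pytest.approx(base["ratio_rhs"])

    def test_display_rounding_half_even(self):
        assert display_round(0.425) == 0.42
        assert display_round(0.435) == 0.44
        assert display_round(4.669) == 4.67


@pytest.fixture(scope="module")
def table1_run():
    cfg = sd.table1_calibrated_config(seed=5, firmicutes=F_MEDIANS, bacteroides=B_MEDIANS)
    ct, meta, panel, truth = sd.generate_microbiome(cfg)
    expr, dropped = sd.normalize_abundance(ct, panel)
    assert dropped == []
    return expr, panel, meta


class TestCalibratedGenerator:
    def test_reproduces_printed_table(self, table1_run):
        expr, panel, meta = table1_run
        rep = sd.fb_ratio(expr, panel, meta)
        for trt, f in F_MEDIANS.items():
            assert rep.table.at["F", trt] == pytest.approx(f, abs=1e-9)
            assert rep.table.at["B", trt] == pytest.approx(B_MEDIANS[trt], abs=1e-9)
        assert rep.display["Placebo"] == "1 : 0.75"
        assert rep.display["Morphine"] == "1 : 1.03"
        assert rep.display["Withdrawal"] == "1 : 4.67"

    def test_member_taxa_shift_with_their_phylum(self, table1_run):
        """Subgroup medians move in the same direction as the phylum."""
        expr, panel, meta = table1_run
        trt = meta["treatment"]
        for phylum in ("Firmicutes", "Bacteroides"):
            assay = panel.phylum_assay(phylum)
            phylum_delta = (
                expr.values.loc[trt == "Withdrawal", assay].median()
                - expr.values.loc[trt == "Placebo", assay].median()
            )
            for m in panel.members(phylum):
                member_delta = (
                    expr.values.loc[trt == "Withdrawal", m].median()
                    - expr.values.loc[trt == "Placebo", m].median()
                )
                assert np.sign(member_delta) == np.sign(phylum_delta)


class TestNormalizeAbundance:
    def test_taxon_equal_to_control_is_zero(self):
        idx = [f"s{i}" for i in range(6)]
        values = pd.DataFrame(
            {"Firmicutes": [12.0] * 6, "Pan Bacteria": [12.0] * 6, "Universal": [12.0] * 6},
            index=idx,
        )
        panel = sd.TaxonPanel(
            pd.DataFrame(
                {
                    "rank": ["phylum", "phylum", "phylum"],
                    "phylum": ["Firmicutes", "other", "other"],
                    "is_control": [False, True, True],
                },
                index=["Firmicutes", "Pan Bacteria", "Universal"],
            )
        )
        expr, _ = sd.normalize_abundance(sd.CtMatrix(values), panel)
        assert np.allclose(expr.values["Firmicutes"], 0.0)

    def test_planted_enrichment_shifts_median(self):
        cfg = sd.MicrobiomeConfig(seed=2, animal_sd=0.0, resid_sd=0.0, control_sd=0.0,
                                  shifts={"Bacteroides": {"Withdrawal": 2.0}})
        ct, meta, panel, truth = sd.generate_microbiome(cfg)
        expr, _ = sd.normalize_abundance(ct, panel)
        trt = meta["treatment"]
        delta = (
            expr.values.loc[trt == "Withdrawal", "Bacteroides"].median()
            - expr.values.loc[trt == "Placebo", "Bacteroides"].median()
        )
        assert delta == pytest.approx(2.0, abs=1e-9)

    def test_shares_brain_normalization_code_path(self, rng):
        idx = [f"s{i}" for i in range(8)]
        values = pd.DataFrame(
            rng.uniform(10, 25, size=(8, 4)),
            index=idx, columns=["t1", "t2", "Pan Bacteria", "Universal"],
        )
        panel = sd.TaxonPanel(
            pd.DataFrame(
                {
                    "rank": ["genus", "genus", "phylum", "phylum"],
                    "phylum": ["Firmicutes", "Bacteroides", "other", "other"],
                    "is_control": [False, False, True, True],
                },
                index=values.columns,
            )
        )
        via_panel, _ = sd.normalize_abundance(sd.CtMatrix(values), panel)
        direct, _ = sd.normalize(sd.CtMatrix(values), ["Pan Bacteria", "Universal"])
        pd.testing.assert_frame_equal(via_panel.values, direct.values)


class TestClassifyDirection:
    def test_partition_and_flags(self):
        cfg = sd.MicrobiomeConfig(seed=4)
        ct, meta, panel, truth = sd.generate_microbiome(cfg)
        expr, _ = sd.normalize_abundance(ct, panel)
        taxa = [a for a in expr.analysis_genes() if not panel.table.at[a, "is_control"]]
        results = sd.differential_abundance(expr, meta, taxa=taxa, design="per_taxon")
        directions = sd.classify_direction(results, expr, meta)
        assert directions.loc["Bacteroides", "direction"] == "induced"
        assert directions.loc["Firmicutes", "direction"] == "suppressed"
        assert set(directions["direction"]) <= {"induced", "suppressed", "none"}
        # every taxon appears exactly once
        assert sorted(directions.index) == sorted(taxa)

    def test_zero_shift_taxon_is_none(self):
        idx = [f"s{i}" for i in range(8)]
        vals = pd.DataFrame({"t1": [1.0] * 8}, index=idx)
        meta = pd.DataFrame(
            {"treatment": ["Placebo"] * 4 + ["Withdrawal"] * 4}, index=idx
        )
        results = sd.differential_abundance(vals, meta, design="per_taxon",
                                            contrasts=(("Withdrawal", "Placebo"),))
        d = sd.classify_direction(results, vals, meta)
        assert d.loc["t1", "direction"] == "none"
        assert d.loc["t1", "flag"] == ""


def test_panel_requires_control_assay():
    table = default_taxon_table()
    table["is_control"] = False
    with pytest.raises(ValueError, match="control"):
        sd.TaxonPanel(table)
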