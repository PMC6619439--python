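"""Nested and two-way ANOVA plus BH adjustment."""

import numpy as np
import pandas as pd
import pytest

import scdeltact as sd


def make_design(n_trt=3, n_animal=4, n_pool=5):
    rows = []
    for t in range(n_trt):
        for a in range(n_animal):
            for p in range(n_pool):
                rows.append((f"T{t}", f"T{t}a{a}", f"T{t}a{a}p{p}"))
    df = pd.DataFrame(rows, columns=["trt", "animal", "sample"]).set_index("sample")
    return df


def nested_f_oracle(y, trt, animal):
    """Brute-force sums of squares for the balanced nested decomposition."""
    df = pd.DataFrame({"y": y, "t": trt, "a": animal})
    grand = df["y"].mean()
    ss_t = 0.0
    ss_a = 0.0
    for t, sub in df.groupby("t"):
        tm = sub["y"].mean()
        ss_t += len(sub) * (tm - grand) ** 2
        for a, asub in sub.groupby("a"):
            ss_a += len(asub) * (asub["y"].mean() - tm) ** 2
    n_t = df["t"].nunique()
    n_a = df.groupby("t")["a"].nunique().sum()
    return (ss_t / (n_t - 1)) / (ss_a / (n_a - n_t))


class TestNestedAnova:
    def test_all_identical_values(self):
        d = make_design()
        y = pd.Series(3.0, index=d.index)
        res = sd.nested_anova(y, d["trt"], d["animal"])
        assert res.f == 0.0 and res.p == 1.0

    def test_balanced_toy_matches_sums_of_squares_oracle(self, rng):
        d = make_design(3, 4, 5)
        y = pd.Series(rng.integers(0, 10, size=len(d)).astype(float), index=d.index)
        expected = nested_f_oracle(y, d["trt"], d["animal"])
        for method in ("animal_means", "balanced_ems"):
            res = sd.nested_anova(y, d["trt"], d["animal"], method=method)
            assert res.f == pytest.approx(expected, rel=1e-10), method

    def test_balanced_closed_form_equals_animal_collapse(self, rng):
        d = make_design(4, 3, 6)
        y = pd.Series(
            rng.normal(0, 1, len(d)) + rng.normal(0, 0.5, 12).repeat(6), index=d.index
        )
        a = sd.nested_anova(y, d["trt"], d["animal"], method="animal_means")
        b = sd.nested_anova(y, d["trt"], d["animal"], method="balanced_ems")
        assert a.f == pytest.approx(b.f, rel=1e-10)
        assert a.p == pytest.approx(b.p, rel=1e-10)
        assert (a.df1, a.df2) == (b.df1, b.df2)

    def test_single_animal_treatment_rejected(self):
        d = make_design(2, 1, 4)
        y = pd.Series(np.arange(len(d), dtype=float), index=d.index)
        with pytest.raises(ValueError, match="2 animals"):
            sd.nested_anova(y, d["trt"], d["animal"])

    def test_naive_pooling_inflates_type_one_error(self):
        """The reason nesting exists: correlated pools are not replicates."""
        rng = np.random.default_rng(99)
        d = make_design(4, 4, 8)
        animal_codes = d["animal"].astype("category").cat.codes.to_numpy()
        rej_nested = rej_pooled = 0
        reps = 300
        for _ in range(reps):
            y = pd.Series(
                rng.normal(0, 0.5, 16)[animal_codes] + rng.normal(0, 0.5, len(d)),
                index=d.index,
            )
            if sd.nested_anova(y, d["trt"], d["animal"]).p < 0.05:
                rej_nested += 1
            if sd.pooled_anova(y, d["trt"]).p < 0.05:
                rej_pooled += 1
        assert rej_pooled / reps > 0.10
        assert rej_nested / reps < 0.10


class TestTwoWayAnova:
    def test_toy_2x2_matches_textbook_computation(self):
        # 2 replicates per cell; hand-computed type-II sums of squares
        df = pd.DataFrame(
            {
                "y": [3.0, 5, 7, 9, 4, 6, 10, 12],
                "a": ["a1", "a1", "a1", "a1", "a2", "a2", "a2", "a2"],
                "b": ["b1", "b1", "b2", "b2", "b1", "b1", "b2", "b2"],
            }
        )
        # oracle: balanced design, SS_A = sum n(mean_A - grand)^2 etc.
        grand = df["y"].mean()
        ss_a = sum(len(g) * (g["y"].mean() - grand) ** 2 for _, g in df.groupby("a"))
        ss_b = sum(len(g) * (g["y"].mean() - grand) ** 2 for _, g in df.groupby("b"))
        ss_cells = sum(
            len(g) * (g["y"].mean() - grand) ** 2 for _, g in df.groupby(["a", "b"])
        )
        ss_ab = ss_cells - ss_a - ss_b
        table = sd.two_way_anova(df["y"], df["a"], df["b"], names=("a", "b"))
        assert table.at["a", "sum_sq"] == pytest.approx(ss_a)
        assert table.at["b", "sum_sq"] == pytest.approx(ss_b)
        assert table.at["a:b", "sum_sq"] == pytest.approx(ss_ab)

    def test_empty_cell_is_error_listing_cells(self):
        df = pd.DataFrame(
            {
                "y": [1.0, 2, 3],
                "a": ["a1", "a1", "a2"],
                "b": ["b1", "b2", "b1"],
            }
        )
        with pytest.raises(ValueError, match="a2"):
            sd.two_way_anova(df["y"], df["a"], df["b"])

    def test_all_equal_abundances_give_p_one(self):
        df = pd.DataFrame(
            {
                "y": [2.0] * 8,
                "a": ["a1", "a2"] * 4,
                "b": ["b1"] * 4 + ["b2"] * 4,
            }
        )
        idx = pd.Index([f"s{i}" for i in range(8)], name="sample_id")
        vals = pd.DataFrame({"tax1": [2.0] * 8}, index=idx)
        meta = pd.DataFrame(
            {"treatment": ["Placebo", "Morphine", "Naltrexone", "Withdrawal"] * 2},
            index=idx,
        )
        res = sd.differential_abundance(vals, meta, design="per_taxon")
        assert np.isnan(res.at["tax1", "F"]) or res.at["tax1", "p"] == pytest.approx(1.0)

    def test_planted_withdrawal_shift_detected_with_power(self):
        """2-unit shift, sigma 0.5, n=4 animals: contrast significant often."""
        rng = np.random.default_rng(123)
        hits = 0
        reps = 200
        idx = pd.Index([f"s{i}" for i in range(16)], name="sample_id")
        meta = pd.DataFrame(
            {"treatment": np.repeat(["Placebo", "Morphine", "Naltrexone", "Withdrawal"], 4)},
            index=idx,
        )
        for _ in range(reps):
            y = rng.normal(0, 0.5, 16)
            y[meta["treatment"] == "Withdrawal"] += 2.0
            vals = pd.DataFrame({"tax1": y}, index=idx)
            res = sd.differential_abundance(vals, meta, design="per_taxon")
            if res.at["tax1", "p_Withdrawal_vs_Placebo"] < 0.05:
                hits += 1
        assert hits / reps >= 0.90


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert sd.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_example(self):
        q = sd.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert sd.bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.random(50)
        q = sd.bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_permutation_invariance(self, rng):
        p = rng.random(30)
        perm = rng.permutation(30)
        q = sd.bh_adjust(p)
        q_perm = sd.bh_adjust(p[perm])
        assert q_perm == pytest.approx(q[perm])

    def test_nan_preserved(self):
        q = sd.bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and np.isfinite(q[0])


def test_differential_table_flags_planted_gene(brain_expression):
    expr, meta, truth = brain_expression
    table = sd.differential_table(expr, meta)
    assert table.at["Tnf", "p"] < 0.05
    assert table.at["Tnf", "q"] >= table.at["Tnf", "p"]
    assert table.at["Tnf", "median_Withdrawal"] > table.at["Tnf", "median_Placebo"]
    assert "Ldha" not in table.index  # references excluded by default
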