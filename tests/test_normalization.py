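"""Reference-gene stability and the two-step -ddCt transform."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scdeltact as sd


def brute_force_m(values: pd.DataFrame, candidates) -> dict:
    """Independent oracle: M_j = mean over k of SD(Ct_j - Ct_k)."""
    m = {}
    for j in candidates:
        sds = []
        for k in candidates:
            if k == j:
                continue
            diff = (values[j] - values[k]).dropna().to_numpy()
            mean = diff.mean()
            sds.append(np.sqrt(((diff - mean) ** 2).sum() / (len(diff) - 1)))
        m[j] = float(np.mean(sds))
    return m


class TestGenorm:
    def test_constant_ratio_gives_zero_m(self):
        values = pd.DataFrame({"a": [20.0, 21.0, 22.0], "b": [18.0, 19.0, 20.0]})
        rank = sd.genorm_m(values, ["a", "b"])
        assert rank.table["m_value"].to_numpy() == pytest.approx([0.0, 0.0])

    def test_small_integer_table_matches_hand_computation(self):
        values = pd.DataFrame(
            {"a": [20.0, 22, 21, 23], "b": [19.0, 20, 22, 21], "c": [25.0, 24, 26, 27]}
        )
        rank = sd.genorm_m(values, ["a", "b", "c"])
        expected = brute_force_m(values, ["a", "b", "c"])
        for g, m in expected.items():
            assert rank.table.at[g, "m_value"] == pytest.approx(m)

    def test_matches_brute_force_on_random_instances(self, rng):
        """Exhaustive pairwise-SD oracle over 200 random small instances."""
        for _ in range(200):
            n_c = int(rng.integers(2, 7))
            n_s = int(rng.integers(4, 21))
            cand = [f"hk{j}" for j in range(n_c)]
            values = pd.DataFrame(
                rng.normal(25, 2, size=(n_s, n_c)), columns=cand
            )
            rank = sd.genorm_m(values, cand)
            expected = brute_force_m(values, cand)
            got = rank.table["m_value"].to_dict()
            assert got == pytest.approx(expected, rel=1e-12)

    def test_noisy_candidate_excluded_first(self, rng):
        n = 30
        base = rng.normal(0, 0.1, size=n)
        values = pd.DataFrame(
            {
                "stable1": 20 + base + rng.normal(0, 0.05, n),
                "stable2": 22 + base + rng.normal(0, 0.05, n),
                "stable3": 24 + base + rng.normal(0, 0.1, n),
                "stable4": 21 + base + rng.normal(0, 0.15, n),
                "noisy": 23 + base + rng.normal(0, 1.5, n),
            }
        )
        rank = sd.genorm_m(values, list(values.columns))
        assert rank.exclusion_order[0] == "noisy"

    def test_insufficient_shared_samples_is_error(self):
        values = pd.DataFrame({"a": [20.0, np.nan, np.nan, 21], "b": [np.nan, 19.0, 20, np.nan]})
        with pytest.raises(ValueError, match="share"):
            sd.genorm_m(values, ["a", "b"])


class TestSelectReferences:
    def test_planted_stable_pair_selected(self, brain_sim):
        cfg, ct, meta, truth = brain_sim
        rank = sd.genorm_m(ct, list(cfg.housekeeping_sd))
        refs = sd.select_reference_genes(rank, 2, never_select=(cfg.control_gene,))
        assert set(refs) == set(truth.stable_pair)

    def test_control_gene_never_selectable(self, brain_sim):
        cfg, ct, meta, truth = brain_sim
        rank = sd.genorm_m(ct, list(cfg.housekeeping_sd))
        refs = sd.select_reference_genes(rank, 4, never_select=(cfg.control_gene,))
        assert cfg.control_gene not in refs

    def test_all_candidates_returned_when_requested(self):
        values = pd.DataFrame(np.random.default_rng(0).normal(25, 1, (10, 3)),
                              columns=["a", "b", "c"])
        rank = sd.genorm_m(values, ["a", "b", "c"])
        assert len(sd.select_reference_genes(rank, 3)) == 3

    def test_tie_broken_by_lower_variance(self):
        # b and c perfectly mirror each other's rank scores; a is worst
        table = pd.DataFrame(
            {
                "variance": [1.0, 0.2, 0.3],
                "m_value": [1.0, 0.4, 0.3],
                "var_rank": [3.0, 1.0, 2.0],
                "m_rank": [3.0, 2.0, 1.0],
                "combined_rank": [3.0, 1.5, 1.5],
            },
            index=["a", "b", "c"],
        )
        rank = sd.normalization.StabilityRanking(table=table, exclusion_order=[])
        assert sd.select_reference_genes(rank, 1) == ["b"]


class TestNegDeltaCt:
    def test_worked_arithmetic(self):
        values = pd.DataFrame({"r1": [20.0], "r2": [22.0], "gene": [25.0]}, index=["s"])
        ndct, dropped = sd.neg_delta_ct(sd.CtMatrix(values), ["r1", "r2"])
        assert ndct.at["s", "gene"] == pytest.approx(-4.0)
        assert dropped == []

    def test_gene_equal_to_ref_mean_is_zero(self, rng):
        r1 = rng.uniform(18, 22, 8)
        r2 = rng.uniform(20, 24, 8)
        values = pd.DataFrame({"r1": r1, "r2": r2, "gene": (r1 + r2) / 2})
        ndct, _ = sd.neg_delta_ct(sd.CtMatrix(values), ["r1", "r2"])
        assert np.allclose(ndct["gene"], 0.0)

    def test_matches_naive_loop(self, rng):
        values = pd.DataFrame(
            rng.uniform(18, 32, size=(12, 6)),
            index=[f"s{i}" for i in range(12)],
            columns=["r1", "r2", "g1", "g2", "g3", "g4"],
        )
        values = values.mask(rng.random(values.shape) < 0.1)
        values[["r1", "r2"]] = values[["r1", "r2"]].fillna(21.0)
        ndct, _ = sd.neg_delta_ct(sd.CtMatrix(values), ["r1", "r2"])
        for s in values.index:
            ref = (values.at[s, "r1"] + values.at[s, "r2"]) / 2
            for g in values.columns:
                expected = ref - values.at[s, g]
                got = ndct.at[s, g]
                assert (np.isnan(expected) and np.isnan(got)) or got == pytest.approx(expected)

    def test_reference_nondetect_drops_sample(self, tiny_ct):
        ct = sd.CtMatrix(tiny_ct.values.copy())
        ct.values.at["s1", "Ldha"] = np.nan
        ndct, dropped = sd.neg_delta_ct(ct, ["Ldha", "Actb"])
        assert "s1" not in ndct.index
        assert dropped[0][0] == "s1" and "Ldha" in dropped[0][1]

    @given(shift=st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_samplewise_ct_shift_invariance(self, shift):
        """Adding a constant to every Ct of a sample cancels in -dCt."""
        rng = np.random.default_rng(4)
        values = pd.DataFrame(
            rng.uniform(18, 30, size=(6, 5)), columns=["r1", "r2", "a", "b", "c"]
        )
        shifted = values.copy()
        shifted.iloc[2] += shift
        a, _ = sd.neg_delta_ct(sd.CtMatrix(values), ["r1", "r2"])
        b, _ = sd.neg_delta_ct(sd.CtMatrix(shifted), ["r1", "r2"])
        assert np.abs(a.to_numpy() - b.to_numpy()).max() < 1e-12


class TestMedianCenter:
    def test_median_zero_after_centering(self, rng):
        ndct = pd.DataFrame(rng.normal(size=(15, 6)))
        expr = sd.median_center(ndct)
        assert np.abs(expr.values.median(axis=0)).max() < 1e-12

    def test_constant_gene_becomes_zero(self):
        ndct = pd.DataFrame({"g": [2.5] * 7})
        assert (sd.median_center(ndct).values["g"] == 0).all()

    def test_odd_n_has_exact_zero_per_gene(self, rng):
        ndct = pd.DataFrame(rng.normal(size=(9, 4)))
        centered = sd.median_center(ndct).values
        assert ((centered == 0).sum(axis=0) >= 1).all()

    def test_per_group_scope(self, rng):
        ndct = pd.DataFrame(rng.normal(size=(12, 3)), index=[f"s{i}" for i in range(12)])
        groups = pd.Series(["x"] * 6 + ["y"] * 6, index=ndct.index)
        expr = sd.median_center(ndct, scope="per-group", groups=groups)
        for g in ("x", "y"):
            sub = expr.values.loc[groups == g]
            assert np.abs(sub.median(axis=0)).max() < 1e-12


class TestZscore:
    def test_unit_moments_per_gene(self, rng):
        expr = pd.DataFrame(rng.normal(2, 3, size=(20, 5)))
        z, flagged = sd.zscore_by_gene(expr)
        assert flagged == []
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_constant_gene_flagged_and_zero(self):
        expr = pd.DataFrame({"flat": [1.0] * 5, "var": [1.0, 2, 3, 4, 5]})
        z, flagged = sd.zscore_by_gene(expr)
        assert flagged == ["flat"]
        assert (z["flat"] == 0).all()

    def test_matches_two_pass_oracle(self, rng):
        expr = pd.DataFrame(rng.normal(size=(11, 3)))
        z, _ = sd.zscore_by_gene(expr)
        for c in expr.columns:
            x = expr[c].to_numpy()
            expected = (x - x.mean()) / x.std(ddof=1)
            assert z[c].to_numpy() == pytest.approx(expected)
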