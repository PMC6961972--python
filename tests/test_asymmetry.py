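"""Fluctuating-asymmetry scoring under both weighting schemes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neuroasym import (
    PairedTable,
    compare_methods,
    default_partition,
    directional_ttests,
    fluctuating_asymmetry_equal,
    fluctuating_asymmetry_proportional,
    regional_summary,
    subset_scores,
)
from neuroasym.errors import (
    DegenerateInputError,
    InsufficientSampleError,
)
from .conftest import random_paired


def oracle_equal(paired):
    """Step-by-step re-implementation of the equal-contribution procedure."""
    df = paired.data
    da = {}
    for _, row in df.iterrows():
        da[(row["participant_id"], row["region"])] = row["L"] - row["R"]
    region_means = {}
    for region in df["region"].unique():
        vals = [v for (p, r), v in da.items() if r == region]
        region_means[region] = sum(vals) / len(vals)
    scores = {}
    for pid in df["participant_id"].unique():
        vals = []
        for _, row in df[df["participant_id"] == pid].iterrows():
            centered = da[(pid, row["region"])] - region_means[row["region"]]
            vals.append(abs(centered) / ((row["L"] + row["R"]) / 2))
        scores[pid] = sum(vals) / len(vals)
    return scores


def oracle_proportional(paired):
    df = paired.data
    totals = {}
    for pid in df["participant_id"].unique():
        sub = df[df["participant_id"] == pid]
        totals[pid] = (sub["L"].sum(), sub["R"].sum())
    diffs = {p: l - r for p, (l, r) in totals.items()}
    mean_diff = sum(diffs.values()) / len(diffs)
    return {p: abs(diffs[p] - mean_diff) / ((l + r) / 2)
            for p, (l, r) in totals.items()}


class TestEqualMethod:
    def test_worked_example(self, tiny_paired):
        res = fluctuating_asymmetry_equal(tiny_paired)
        # DAs are +1 and -1, sample mean 0, bilateral mean 1.5
        np.testing.assert_allclose(res.scores.to_numpy(), [2 / 3, 2 / 3])
        np.testing.assert_allclose(res.per_region["centered"].mean(), 0, atol=1e-15)

    def test_perfect_symmetry_scores_zero(self):
        data = pd.DataFrame({"participant_id": ["a", "b"], "region": ["r"] * 2,
                             "L": [2.0, 3.0], "R": [2.0, 3.0]})
        res = fluctuating_asymmetry_equal(PairedTable("thickness", data))
        # centering removes the (zero) directional mean; all deviations vanish
        assert (res.scores == 0).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_step_by_step_oracle(self, seed):
        paired = random_paired(seed)
        res = fluctuating_asymmetry_equal(paired)
        oracle = oracle_equal(paired)
        for pid, val in oracle.items():
            assert res.scores[pid] == pytest.approx(val, rel=1e-12)

    def test_single_participant_rejected(self):
        data = pd.DataFrame({"participant_id": ["a"], "region": ["r"],
                             "L": [2.0], "R": [1.0]})
        with pytest.raises(InsufficientSampleError):
            fluctuating_asymmetry_equal(PairedTable("thickness", data))

    def test_zero_bilateral_mean_rejected(self):
        data = pd.DataFrame({"participant_id": ["a", "b"], "region": ["r"] * 2,
                             "L": [1.0, 0.5], "R": [-1.0, 0.5]})
        with pytest.raises(DegenerateInputError):
            fluctuating_asymmetry_equal(PairedTable("thickness", data))

    def test_missing_region_uses_available_mean(self):
        # participant b lacks region r2: their score averages over r1 only
        data = pd.DataFrame({
            "participant_id": ["a", "a", "b"],
            "region": ["r1", "r2", "r1"],
            "L": [2.0, 3.0, 1.0], "R": [1.0, 3.5, 2.0],
        })
        res = fluctuating_asymmetry_equal(PairedTable("thickness", data))
        assert res.dropped_regions == ("r2",)  # only one participant has r2
        assert len(res.scores) == 2

    def test_scale_invariance_single_region(self, small_cohort):
        from neuroasym import pair_hemispheres
        paired = pair_hemispheres(small_cohort.regional["thickness"])
        base = fluctuating_asymmetry_equal(paired)
        scaled = paired.data.copy()
        mask = scaled["region"] == "bankssts"
        scaled.loc[mask, ["L", "R"]] *= 10.0
        res = fluctuating_asymmetry_equal(PairedTable("thickness", scaled))
        np.testing.assert_allclose(res.scores.to_numpy(),
                                   base.scores.to_numpy(), rtol=1e-12)

    def test_hemisphere_swap_invariance(self, small_cohort):
        from neuroasym import pair_hemispheres
        paired = pair_hemispheres(small_cohort.regional["surface_area"])
        base = fluctuating_asymmetry_equal(paired)
        swapped = paired.data.rename(columns={"L": "R", "R": "L"})
        res = fluctuating_asymmetry_equal(PairedTable("surface_area", swapped))
        np.testing.assert_allclose(res.scores.to_numpy(),
                                   base.scores.to_numpy(), rtol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           n=st.integers(2, 8), k=st.integers(1, 6))
    def test_property_nonnegative_and_oracle_equal(self, seed, n, k):
        paired = random_paired(seed, n_participants=n, n_regions=k)
        res = fluctuating_asymmetry_equal(paired)
        assert (res.scores >= 0).all()
        oracle = oracle_equal(paired)
        for pid, val in oracle.items():
            assert res.scores[pid] == pytest.approx(val, rel=1e-10)


class TestProportionalMethod:
    def test_worked_example_totals(self):
        data = pd.DataFrame({
            "participant_id": ["a", "a", "b", "b"],
            "region": ["r1", "r2", "r1", "r2"],
            "L": [60.0, 40.0, 50.0, 40.0],
            "R": [50.0, 40.0, 55.0, 45.0],
        })
        res = fluctuating_asymmetry_proportional(PairedTable("surface_area", data))
        # totals (100, 90) and (90, 100): differences +10/-10, mean 0
        np.testing.assert_allclose(sorted(res.scores), [10 / 95, 10 / 95])

    def test_single_region_rescaling_changes_proportional_only(self, small_cohort):
        from neuroasym import pair_hemispheres
        paired = pair_hemispheres(small_cohort.regional["volume"])
        base = fluctuating_asymmetry_proportional(paired)
        scaled = paired.data.copy()
        mask = scaled["region"] == "superiorfrontal"
        scaled.loc[mask, ["L", "R"]] *= 10.0
        res = fluctuating_asymmetry_proportional(PairedTable("volume", scaled))
        assert not np.allclose(res.scores.to_numpy(), base.scores.to_numpy())

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_oracle(self, seed):
        paired = random_paired(seed)
        res = fluctuating_asymmetry_proportional(paired)
        oracle = oracle_proportional(paired)
        for pid, val in oracle.items():
            assert res.scores[pid] == pytest.approx(val, rel=1e-12)


class TestSubsets:
    def test_all_subset_is_identity(self, small_cohort):
        from neuroasym import pair_hemispheres
        paired = pair_hemispheres(small_cohort.regional["thickness"])
        full = fluctuating_asymmetry_equal(paired)
        sub = subset_scores(paired, default_partition(), "all", "equal")
        np.testing.assert_allclose(sub.scores.to_numpy(), full.scores.to_numpy())

    def test_pfit_uses_exactly_ten_regions(self, small_cohort):
        from neuroasym import pair_hemispheres
        paired = pair_hemispheres(small_cohort.regional["surface_area"])
        sub = subset_scores(paired, default_partition(), "pfit", "equal")
        assert len(sub.regions_used) == 10

    def test_region_count_weighted_average_identity(self, small_cohort):
        from neuroasym import pair_hemispheres
        paired = pair_hemispheres(small_cohort.regional["volume"])
        part = default_partition()
        full = fluctuating_asymmetry_equal(paired)
        pf = subset_scores(paired, part, "pfit", "equal")
        npf = subset_scores(paired, part, "non_pfit", "equal")
        combined = (10 * pf.scores + 24 * npf.scores) / 34
        np.testing.assert_allclose(combined.to_numpy(), full.scores.to_numpy(),
                                   rtol=1e-10)

    def test_empty_subset_rejected(self, tiny_paired):
        with pytest.raises(InsufficientSampleError):
            subset_scores(tiny_paired, default_partition(), "pfit", "equal")


class TestSummariesAndTests:
    def test_regional_summary_worked_example(self, tiny_paired):
        res = fluctuating_asymmetry_equal(tiny_paired)
        summary = regional_summary(res)
        assert summary.iloc[0]["mean"] == pytest.approx(2 / 3)
        assert summary.iloc[0]["sd"] == pytest.approx(0.0, abs=1e-15)

    def test_regional_summary_matches_direct(self):
        paired = random_paired(7, n_participants=12, n_regions=4)
        res = fluctuating_asymmetry_equal(paired)
        summary = regional_summary(res).set_index("region")
        direct = res.per_region.groupby("region")["normalized"].agg(["mean", "std"])
        np.testing.assert_allclose(summary["mean"], direct["mean"])
        np.testing.assert_allclose(summary["sd"], direct["std"])

    def test_directional_ttest_closed_forms(self):
        # DAs {-1, +1}: t = 0, p = 1.  DAs {0, 2}: t = 1 on 1 df, p = 0.5.
        d1 = pd.DataFrame({"participant_id": ["a", "b"], "region": ["r"] * 2,
                           "L": [1.5, 2.0], "R": [2.5, 1.0]})
        out = directional_ttests(PairedTable("thickness", d1))
        assert out.iloc[0]["t"] == pytest.approx(0.0, abs=1e-12)
        assert out.iloc[0]["p"] == pytest.approx(1.0)
        d2 = pd.DataFrame({"participant_id": ["a", "b"], "region": ["r"] * 2,
                           "L": [2.0, 3.0], "R": [2.0, 1.0]})
        out = directional_ttests(PairedTable("thickness", d2))
        assert out.iloc[0]["t"] == pytest.approx(1.0)
        assert out.iloc[0]["df"] == 1
        assert out.iloc[0]["p"] == pytest.approx(0.5)

    def test_directional_ttest_matches_formula(self):
        paired = random_paired(11, n_participants=20, n_regions=3)
        out = directional_ttests(paired).set_index("region")
        df = paired.data
        for region, sub in df.groupby("region"):
            da = (sub["L"] - sub["R"]).to_numpy()
            t = da.mean() / (da.std(ddof=1) / np.sqrt(len(da)))
            assert out.loc[region, "t"] == pytest.approx(t, rel=1e-12)

    def test_zero_sd_is_error(self):
        data = pd.DataFrame({"participant_id": ["a", "b"], "region": ["r"] * 2,
                             "L": [2.0, 3.0], "R": [1.0, 2.0]})  # DA = 1, 1
        with pytest.raises(DegenerateInputError):
            directional_ttests(PairedTable("thickness", data))


class TestMethodComparison:
    def test_identical_scores_give_r_one(self):
        paired = random_paired(13)
        eq = fluctuating_asymmetry_equal(paired)
        cmp_ = compare_methods(eq, eq)
        assert cmp_.r == pytest.approx(1.0)

    def test_matches_direct_pearson(self):
        paired = random_paired(17)
        eq = fluctuating_asymmetry_equal(paired)
        pr = fluctuating_asymmetry_proportional(paired)
        cmp_ = compare_methods(eq, pr)
        merged = pd.concat([eq.scores, pr.scores], axis=1).dropna()
        r = np.corrcoef(merged.iloc[:, 0], merged.iloc[:, 1])[0, 1]
        assert cmp_.r == pytest.approx(r, rel=1e-12)

    def test_constant_vector_is_degenerate(self):
        data = pd.DataFrame({"participant_id": list("abc"), "region": ["r"] * 3,
                             "L": [2.0, 2.0, 2.0], "R": [2.0, 2.0, 2.0]})
        eq = fluctuating_asymmetry_equal(PairedTable("thickness", data))
        with pytest.raises(DegenerateInputError):
            compare_methods(eq, eq)

    def test_too_few_pairs(self, tiny_paired):
        eq = fluctuating_asymmetry_equal(tiny_paired)
        with pytest.raises(InsufficientSampleError):
            compare_methods(eq, eq)
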