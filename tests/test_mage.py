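"""Pooled-competition fitness estimation from read-count tables."""

import numpy as np
import pandas as pd
import pytest

from divlimit.exceptions import ConfigurationError, InsufficientDataError
from divlimit.mage import (
    DEFAULT_DILUTION_PER_HOUR,
    MageCountTable,
    median_normalize,
    relative_growth_rates,
    site_fitness_profile,
    split_half_consistency,
)
from divlimit.simulate import simulate_mage

TIMES = tuple(float(t) for t in range(0, 16, 2))


def make_table(count_rows, times=TIMES, meta=None):
    """Build a MageCountTable from {mutant_id: [counts per time]}."""
    n = len(count_rows)
    meta = meta or {}
    df = pd.DataFrame(
        {
            "mutant_id": list(count_rows),
            "position": meta.get("position", list(range(n))),
            "codon": meta.get("codon", [f"c{i}" for i in range(n)]),
            "aa": meta.get("aa", ["A"] * n),
            "wt_aa": meta.get("wt_aa", ["G"] * n),
            "batch": meta.get("batch", [0] * n),
        }
    )
    for j, t in enumerate(times):
        df[MageCountTable.time_col(t)] = [counts[j] for counts in count_rows.values()]
    return MageCountTable(df=df, times=times)


class TestMageCountTable:
    def test_wt_row_required(self):
        with pytest.raises(ConfigurationError):
            make_table({"m1": [10] * 8})

    def test_tsv_roundtrip(self, tmp_path):
        tab = simulate_mage({"m1": -0.1, "m2": 0.0}, depth_per_timepoint=1000, seed=0)
        p = tmp_path / "counts.tsv"
        tab.to_tsv(p)
        back = MageCountTable.from_tsv(p)
        assert back.times == tab.times
        assert np.allclose(back.counts(), tab.counts())


class TestMedianNormalize:
    def test_equal_counts_unchanged(self):
        tab = make_table({"WT": [100] * 8, "m1": [50] * 8, "m2": [50] * 8, "m3": [50] * 8})
        norm = median_normalize(tab)
        assert np.allclose(norm.counts(), tab.counts())

    def test_batch_total_preserved_and_ratio_kept(self):
        tab = make_table(
            {"WT": [100] * 8, "m1": [20] * 8, "m2": [20] * 8, "m3": [40] * 8}
        )
        norm = median_normalize(tab)
        sub = norm.df[norm.df["mutant_id"] != "WT"]
        col = MageCountTable.time_col(0.0)
        vals = sub[col].to_numpy()
        assert vals.sum() == pytest.approx(80.0)  # batch total preserved
        # the doubled mutant stays at twice the batch median
        assert vals[2] == pytest.approx(2 * np.median(vals))

    def test_single_mutant_batch_unchanged(self):
        tab = make_table({"WT": [100] * 8, "m1": [37] * 8})
        norm = median_normalize(tab)
        assert np.allclose(
            norm.df[norm.df["mutant_id"] == "m1"][norm.count_columns],
            37.0,
        )

    def test_zero_median_batch_flagged_and_untouched(self):
        tab = make_table({"WT": [100] * 8, "m1": [0] * 8, "m2": [0] * 8, "m3": [5] * 8})
        norm = median_normalize(tab)
        assert len(norm.df.attrs["zero_median_batches"]) == 8  # every time point
        assert np.allclose(norm.counts()[1:], tab.counts()[1:])

    def test_wt_untouched(self):
        tab = make_table({"WT": [123] * 8, "m1": [10] * 8, "m2": [90] * 8})
        norm = median_normalize(tab)
        assert np.allclose(norm.wt_counts(), 123.0)


class TestRelativeGrowthRates:
    def test_proportional_to_wt_gives_zero_slope(self):
        wt = [1000 * 2**j for j in range(8)]
        tab = make_table({"WT": wt, "m1": [c // 2 for c in wt]})
        g = relative_growth_rates(tab)
        assert g["slope"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert g["relative_growth"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_slope_to_relative_growth_arithmetic(self):
        # slope -0.137/h over dilution 1.37/h -> 10% slower than WT
        wt = [100000] * 8
        mut = [int(round(50000 * np.exp(-0.137 * t))) for t in TIMES]
        tab = make_table({"WT": wt, "m1": mut})
        g = relative_growth_rates(tab)
        assert g["relative_growth"].iloc[0] == pytest.approx(-0.10, abs=1e-3)

    def test_depth_invariance(self):
        # multiplying all counts at one time point by a constant changes nothing
        wt = [10000] * 8
        mut = [int(10000 * np.exp(-0.2 * t)) for t in TIMES]
        tab1 = make_table({"WT": wt, "m1": mut})
        wt2, mut2 = list(wt), list(mut)
        wt2[3] *= 7
        mut2[3] *= 7
        tab2 = make_table({"WT": wt2, "m1": mut2})
        g1 = relative_growth_rates(tab1)
        g2 = relative_growth_rates(tab2)
        assert g1["slope"].iloc[0] == pytest.approx(g2["slope"].iloc[0], rel=1e-9)

    @pytest.mark.parametrize("n_good, expect_filtered", [(4, True), (5, False)])
    def test_min_timepoint_filter_boundary(self, n_good, expect_filtered):
        wt = [1000] * 8
        # exactly n_good time points at/above the read threshold
        mut = [25] * n_good + [19] * (8 - n_good)
        tab = make_table({"WT": wt, "m1": mut})
        g = relative_growth_rates(tab, min_points=5, min_reads=20)
        assert bool(g["filtered"].iloc[0]) is expect_filtered
        if expect_filtered:
            assert np.isnan(g["slope"].iloc[0])

    def test_wt_zero_timepoint_dropped_for_all(self):
        wt = [1000] * 8
        wt[2] = 0
        mut = [500] * 8
        tab = make_table({"WT": wt, "m1": mut})
        g = relative_growth_rates(tab)
        assert g["n_usable_timepoints"].iloc[0] == 7

    def test_infinite_depth_recovery_is_exact(self):
        dms = {"m1": -0.2, "m2": -0.05, "m3": 0.0}
        tab = simulate_mage(dms, depth_per_timepoint=None)
        g = relative_growth_rates(tab, dilution=1.37)
        for mid, dm in dms.items():
            row = g[g["mutant_id"] == mid].iloc[0]
            assert row["slope"] == pytest.approx(dm, abs=1e-9)
            assert row["relative_growth"] == pytest.approx(dm / 1.37, abs=1e-9)

    def test_sampled_depth_estimator_unbiased(self):
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(30):
            tab = simulate_mage({"m1": -0.2}, depth_per_timepoint=100_000, seed=rng)
            g = relative_growth_rates(tab)
            errs.append(g["slope"].iloc[0] - (-0.2))
        assert abs(np.mean(errs)) < 0.01


class TestSiteFitnessProfile:
    def test_two_stage_average(self):
        # two codons for the same aa (-0.1, -0.3) collapse to -0.2; plus one
        # other aa at -0.2 -> site mean -0.2
        growth = pd.DataFrame(
            {
                "mutant_id": ["a", "b", "c"],
                "position": [1, 1, 1],
                "codon": ["AAA", "AAG", "TGG"],
                "aa": ["K", "K", "W"],
                "wt_aa": ["G", "G", "G"],
                "relative_growth": [-0.1, -0.3, -0.2],
                "filtered": [False, False, False],
            }
        )
        prof = site_fitness_profile(growth)
        assert prof["mean_fitness"].iloc[0] == pytest.approx(-0.2)
        assert prof["n_aa"].iloc[0] == 2

    def test_synonymous_excluded_by_default(self):
        growth = pd.DataFrame(
            {
                "mutant_id": ["a", "b"],
                "position": [1, 1],
                "codon": ["GGA", "TGG"],
                "aa": ["G", "W"],
                "wt_aa": ["G", "G"],
                "relative_growth": [0.001, -0.4],
                "filtered": [False, False],
            }
        )
        prof = site_fitness_profile(growth)
        assert prof["mean_fitness"].iloc[0] == pytest.approx(-0.4)

    def test_all_filtered_site_missing(self):
        growth = pd.DataFrame(
            {
                "mutant_id": ["a"],
                "position": [1],
                "codon": ["AAA"],
                "aa": ["K"],
                "wt_aa": ["G"],
                "relative_growth": [np.nan],
                "filtered": [True],
            }
        )
        prof = site_fitness_profile(growth)
        assert np.isnan(prof["mean_fitness"].iloc[0])

    def test_matches_hand_enumeration_on_toy_table(self):
        rows = []
        rng = np.random.default_rng(5)
        expected = {}
        for pos in (1, 2, 3):
            per_aa = {}
            for aa in "KWDE":
                vals = rng.normal(-0.1, 0.05, size=2)
                per_aa[aa] = np.mean(vals)
                for k, v in enumerate(vals):
                    rows.append(
                        dict(mutant_id=f"p{pos}{aa}{k}", position=pos,
                             codon=f"{aa}{k}", aa=aa, wt_aa="G",
                             relative_growth=v, filtered=False)
                    )
            expected[pos] = np.mean(list(per_aa.values()))
        prof = site_fitness_profile(pd.DataFrame(rows))
        for pos, exp in expected.items():
            got = prof[prof["position"] == pos]["mean_fitness"].iloc[0]
            assert got == pytest.approx(exp)


class TestSplitHalf:
    def _design(self, n_pos=12, seed=1):
        # 8 codons per site spanning 4 amino acids
        rng = np.random.default_rng(seed)
        rows = []
        for pos in range(1, n_pos + 1):
            site_effect = float(rng.uniform(-0.3, 0.0))
            for ci, aa in enumerate("KWDEKWDE"):
                rows.append(
                    dict(mutant_id=f"p{pos}c{ci}", position=pos, codon=f"cod{ci}",
                         aa=aa, wt_aa="G", batch=pos // 10,
                         dm=site_effect + 0.01 * ci)
                )
        return pd.DataFrame(rows)

    def test_noiseless_halves_agree(self):
        design = self._design()
        tab = simulate_mage(design, depth_per_timepoint=None)
        res = split_half_consistency(tab, seed=0)
        assert res["pearson_r"] > 0.99

    def test_sampled_depth_still_consistent(self):
        design = self._design()
        tab = simulate_mage(design, depth_per_timepoint=200_000, seed=3)
        res = split_half_consistency(tab, seed=0)
        assert res["pearson_r"] > 0.9

    def test_seed_changes_partition_not_conclusion(self):
        design = self._design()
        tab = simulate_mage(design, depth_per_timepoint=None)
        r1 = split_half_consistency(tab, seed=1)
        r2 = split_half_consistency(tab, seed=2)
        assert r1["half_a_codons"] != r2["half_a_codons"]
        assert r1["pearson_r"] > 0.99 and r2["pearson_r"] > 0.99

    def test_too_few_sites_rejected(self):
        tab = simulate_mage({"m1": -0.1, "m2": 0.0}, depth_per_timepoint=None)
        with pytest.raises(InsufficientDataError):
            split_half_consistency(tab, seed=0)
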