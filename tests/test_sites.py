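"""Per-site conservation profiles and stratified divergence curves."""

import numpy as np
import pandas as pd
import pytest

from divlimit.exceptions import ConfigurationError, InsufficientDataError
from divlimit.models import AlphabetParams, alphabet_to_limit, evaluate_model
from divlimit.simulate import evolve_independent_pairs, make_site_profile
from divlimit.sites import (
    assign_distance_shells,
    conserved_identity_share,
    fitness_binned_divergence,
    grouped_divergence,
    identity_prob_vs_fitness,
    shell_divergence,
    site_identity_profile,
    universal_site_fraction,
)

TOY_MSA = {
    "ref": "ACD-EF",
    "x1": "ACD-EF",
    "y1": "ACQ-EF",
    "x2": "AC-GEF",
    "y2": "ACNGEF",
}
TOY_PAIRS = [("x1", "y1"), ("x2", "y2")]


class TestSiteIdentityProfile:
    def test_all_identical_gives_ones(self):
        msa = {"ref": "ACDEF", "a": "ACDEF", "b": "ACDEF", "c": "ACDEF", "d": "ACDEF"}
        prof = site_identity_profile(msa, [("a", "b"), ("c", "d")], "ref")
        assert np.all(prof.fractions == 1.0)

    def test_counting_and_gap_rules(self):
        prof = site_identity_profile(TOY_MSA, TOY_PAIRS, "ref")
        # reference has 5 ungapped columns; column 4 of the MSA (ref gap)
        # is absent from the profile
        assert list(prof.positions) == [1, 2, 3, 4, 5]
        # site 3: pair1 mismatch (D vs Q), pair2 has a gap -> excluded
        assert prof.fractions[2] == 0.0
        assert prof.n_pairs_per_site[2] == 1

    def test_fraction_from_three_of_four_pairs(self):
        msa = {"ref": "AAA"}
        pairs = []
        for k, (x, y) in enumerate([("AAA", "AAA"), ("AAA", "AAA"), ("AAA", "AAA"),
                                    ("AAA", "ACA")]):
            msa[f"u{k}"] = x
            msa[f"v{k}"] = y
            pairs.append((f"u{k}", f"v{k}"))
        prof = site_identity_profile(msa, pairs, "ref")
        assert prof.fractions[1] == pytest.approx(0.75)

    def test_empty_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            site_identity_profile(TOY_MSA, [], "ref")

    def test_missing_reference_rejected(self):
        with pytest.raises(ConfigurationError):
            site_identity_profile(TOY_MSA, TOY_PAIRS, "nope")


class TestUniversalSites:
    def test_all_conserved(self):
        prof = site_identity_profile(
            {"ref": "AAA", "a": "AAA", "b": "AAA"}, [("a", "b")], "ref"
        )
        assert universal_site_fraction(prof) == 1.0

    def test_threshold_counting(self):
        prof = site_identity_profile(TOY_MSA, TOY_PAIRS, "ref")
        prof.fractions = np.array([0.95, 0.85, 0.91, 0.5])
        prof.positions = np.arange(1, 5)
        assert universal_site_fraction(prof, 0.9) == pytest.approx(0.5)
        assert universal_site_fraction(prof, 1.0) == 0.0

    def test_share_of_observed_identity(self):
        assert conserved_identity_share(0.14, 40.0) == pytest.approx(35.0)
        assert conserved_identity_share(0.0, 40.0) == 0.0
        assert conserved_identity_share(0.4, 40.0) == pytest.approx(100.0)
        with pytest.raises(InsufficientDataError):
            conserved_identity_share(0.1, 0.0)


class TestGroupedDivergence:
    def _sim_msa(self, sizes, lam, t, n_pairs, seed=0):
        profile = make_site_profile(len(sizes), sizes, lam, seed=seed)
        msa, pairs = evolve_independent_pairs(profile, t, n_pairs, seed=seed + 1)
        msa["ref"] = profile.ancestral
        return msa, {p: t for p in pairs}

    def test_single_group_reproduces_global_curve(self):
        msa, pair_times = self._sim_msa([4] * 60, 0.75, 1.0, 8)
        groups = {p: "all" for p in range(1, 61)}
        out = grouped_divergence(msa, pair_times, groups, [0.5, 1.5], "ref")
        # direct global identity of each pair
        ids = []
        for a, b in pair_times:
            sa, sb = msa[a], msa[b]
            ids.append(100 * np.mean([x == y for x, y in zip(sa, sb)]))
        assert out.loc[0, "mean_identity"] == pytest.approx(np.mean(ids), abs=1e-9)

    def test_partition_weighted_by_site_counts_recovers_global(self):
        msa, pair_times = self._sim_msa([4] * 40 + [2] * 20, 0.75, 1.0, 6)
        groups = {p: ("g1" if p <= 40 else "g2") for p in range(1, 61)}
        out = grouped_divergence(msa, pair_times, groups, [0.5, 1.5], "ref")
        # pairwise identities per group weighted by group size reproduce the
        # global identity because the MSA has no gaps
        g1 = out[out.group == "g1"]["mean_identity"].iloc[0]
        g2 = out[out.group == "g2"]["mean_identity"].iloc[0]
        combined = (40 * g1 + 20 * g2) / 60
        ids = [
            100 * np.mean([x == y for x, y in zip(msa[a], msa[b])])
            for a, b in pair_times
        ]
        assert combined == pytest.approx(np.mean(ids), abs=1e-9)

    def test_restricted_alphabet_groups_floor_at_inverse_a(self):
        # group 1: a=2 alphabets floor near 50%; group 2: a=8 floors near 12.5%
        sizes = [2] * 150 + [8] * 150
        msa, pair_times = self._sim_msa(sizes, 1.5, 12.0, 30, seed=3)
        groups = {p: ("a2" if p <= 150 else "a8") for p in range(1, 301)}
        out = grouped_divergence(msa, pair_times, groups, [10.0, 14.0], "ref")
        floor_a2 = out[out.group == "a2"]["mean_identity"].iloc[0]
        floor_a8 = out[out.group == "a8"]["mean_identity"].iloc[0]
        assert floor_a2 == pytest.approx(50.0, abs=3.0)
        assert floor_a8 == pytest.approx(12.5, abs=3.0)

    def test_empty_time_bin_reports_missing(self):
        msa, pair_times = self._sim_msa([4] * 20, 0.75, 1.0, 4)
        groups = {p: "all" for p in range(1, 21)}
        out = grouped_divergence(msa, pair_times, groups, [0.0, 0.5, 1.5], "ref")
        empty = out[(out.time_lo == 0.0)]
        assert np.isnan(empty["mean_identity"].iloc[0])
        assert empty["n_pairs"].iloc[0] == 0

    def test_fitness_quartile_binning_defaults(self):
        msa, pair_times = self._sim_msa([4] * 40, 0.75, 1.0, 5)
        fitness = {p: -0.01 * p for p in range(1, 41)}
        out = fitness_binned_divergence(msa, pair_times, fitness, None, [0.5, 1.5], "ref")
        assert out["group"].nunique() == 4


class TestIdentityProbVsFitness:
    def test_constant_fitness_single_bin_mean(self):
        prof = site_identity_profile(TOY_MSA, TOY_PAIRS, "ref")
        fitness = {int(p): -0.1 for p in prof.positions}
        out = identity_prob_vs_fitness(prof, fitness, [-0.2, 0.0])
        valid = prof.fractions[~np.isnan(prof.fractions)]
        assert out["mean_probability"].iloc[0] == pytest.approx(valid.mean())

    def test_binned_curve_matches_direct_enumeration(self):
        # conservation fractions constructed equal to clamp(fitness, 0, 1)
        rng = np.random.default_rng(4)
        fitness = {p: float(rng.uniform(-0.5, 1.2)) for p in range(1, 51)}
        fractions = np.clip([fitness[p] for p in range(1, 51)], 0, 1)
        prof = site_identity_profile(
            {"ref": "A" * 50, "a": "A" * 50, "b": "A" * 50}, [("a", "b")], "ref"
        )
        prof.fractions = np.asarray(fractions, dtype=float)
        bins = [-0.5, 0.0, 0.5, 1.0, 1.5]
        out = identity_prob_vs_fitness(prof, fitness, bins)
        for k in range(4):
            sel = [
                np.clip(fitness[p], 0, 1)
                for p in range(1, 51)
                if bins[k] <= fitness[p] < bins[k + 1]
            ]
            expected = np.mean(sel) if sel else np.nan
            got = out["mean_probability"].iloc[k]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)


class TestShells:
    def test_shell_assignment_rules(self):
        coords = {1: (0.0, 0.0, 0.0), 2: (7.1, 0.0, 0.0), 3: (2.0, 0.0, 0.0)}
        sm = assign_distance_shells(coords, [1], shell_width=5.0)
        assert sm.shells[1] == 0  # at the centroid
        assert sm.shells[2] == 1  # 7.1 A with 5 A shells
        assert sm.shells[3] == 0

    def test_single_active_site_centroid_is_itself(self):
        coords = {1: (1.0, 2.0, 3.0), 2: (1.0, 2.0, 8.1)}
        sm = assign_distance_shells(coords, [1], shell_width=5.0)
        assert sm.shells[1] == 0 and sm.shells[2] == 1

    def test_missing_coordinates_skipped_with_warning(self):
        coords = {1: (0.0, 0.0, 0.0), 2: (np.nan, 0.0, 0.0)}
        with pytest.warns(UserWarning):
            sm = assign_distance_shells(coords, [1], 5.0)
        assert 2 not in sm.shells

    def test_no_active_site_rejected(self):
        with pytest.raises(ConfigurationError):
            assign_distance_shells({1: (0, 0, 0)}, [], 5.0)

    def test_shell_curves_orderable_by_conservation(self):
        # shell 0 strictly slower than shell 2 -> higher identity at all bins
        sizes = [4] * 200
        rates = [0.2] * 100 + [2.0] * 100
        profile = make_site_profile(200, sizes, rates, seed=6)
        from divlimit.simulate import evolve_independent_pairs

        msa, pairs = evolve_independent_pairs(profile, 1.5, 25, seed=7)
        msa["ref"] = profile.ancestral
        coords = {p: (0.0, 0.0, 0.0) if p <= 100 else (12.0, 0.0, 0.0) for p in range(1, 201)}
        sm = assign_distance_shells(coords, [1], 5.0)
        out = shell_divergence(msa, {p: 1.5 for p in pairs}, sm, [1.0, 2.0], "ref")
        inner = out[out.group == 0]["mean_identity"].iloc[0]
        outer = out[out.group == 2]["mean_identity"].iloc[0]
        assert inner > outer
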