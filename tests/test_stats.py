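"""Permutation tests, FDR, Spearman and the gated batteries."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

import eegraph as eg


def exact_permutation_p(a, b):
    """Full enumeration of group assignments for small samples."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    observed = abs(np.mean(a) - np.mean(b))
    count, total = 0, 0
    for idx in combinations(range(n), na):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        diff = abs(pooled[mask].mean() - pooled[~mask].mean())
        count += diff >= observed - 1e-12
        total += 1
    return count / total


class TestPermutationTest:
    def test_identical_groups_give_p_one(self):
        res = eg.permutation_test(
            [1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3, n_perm=500, seed=0
        )
        assert res.observed_diff == 0.0
        assert res.p_value == 1.0

    def test_monte_carlo_matches_full_enumeration(self):
        a = np.array([1.2, 3.4, 2.2])
        b = np.array([4.1, 5.0, 3.9])
        exact = exact_permutation_p(a, b)
        res = eg.permutation_test(
            np.concatenate([a, b]), ["a"] * 3 + ["b"] * 3,
            n_perm=20000, seed=1,
        )
        # Monte-Carlo error: ~3 binomial SDs around the enumerated value
        se = np.sqrt(exact * (1 - exact) / 20000)
        assert abs(res.p_value - exact) < 3 * se + 2 / 20000

    def test_separated_groups_give_tiny_p(self, rng):
        a = rng.normal(10, 0.1, 10)
        b = rng.normal(0, 0.1, 10)
        res = eg.permutation_test(
            np.concatenate([a, b]), ["a"] * 10 + ["b"] * 10,
            n_perm=10000, seed=2,
        )
        assert res.p_value <= 0.001

    def test_p_respects_lower_bound(self):
        res = eg.permutation_test(
            [0, 0, 0, 9, 9, 9], ["a"] * 3 + ["b"] * 3, n_perm=100, seed=0
        )
        assert res.p_value >= 1 / 101

    def test_empty_group_fails(self):
        with pytest.raises(ValueError):
            eg.permutation_test([1, 2, 3], ["a", "a", "a"], n_perm=10)


class TestFdr:
    def test_step_up_by_hand(self):
        flags = eg.fdr_adjust([0.01, 0.02, 0.20], q=0.05)
        assert list(flags) == [True, True, False]

    def test_all_ones_reject_nothing(self):
        assert not eg.fdr_adjust([1.0, 1.0, 1.0]).any()

    def test_single_p_reduces_to_raw_threshold(self):
        assert eg.fdr_adjust([0.04]).all()
        assert not eg.fdr_adjust([0.06]).any()

    def test_bh_rejects_superset_of_bonferroni(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, 8) ** 2
            bh = eg.fdr_adjust(p, q=0.05)
            bonf = p <= 0.05 / len(p)
            assert np.all(bh[bonf])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            eg.fdr_adjust([])
        with pytest.raises(ValueError):
            eg.fdr_adjust([0.0, 0.5])


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        up = eg.spearman_correlate(x, np.exp(x), n_perm=200, seed=0)
        down = eg.spearman_correlate(x, [-v**3 for v in x], n_perm=200, seed=0)
        assert up.rho == pytest.approx(1.0)
        assert down.rho == pytest.approx(-1.0)

    def test_matches_rank_formula_with_tie_midranks(self, rng):
        a = np.array([1.0, 2.0, 2.0, 4.0, 5.0])
        b = rng.normal(size=5)
        res = eg.spearman_correlate(a, b, n_perm=100, seed=0)
        ra, rb = spstats.rankdata(a), spstats.rankdata(b)
        expected = np.corrcoef(ra, rb)[0, 1]
        assert res.rho == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_is_flagged_not_raised(self):
        res = eg.spearman_correlate([1, 1, 1, 1], [1, 2, 3, 4])
        assert not res.valid and np.isnan(res.rho)

    def test_too_short_fails(self):
        with pytest.raises(ValueError):
            eg.spearman_correlate([1, 2, 3], [1, 2, 3])


def _labels(n_a=10, n_b=6):
    return ["control"] * n_a + ["patient"] * n_b


def _frames(rng, bands=("delta",), n_a=10, n_b=6, shift=None):
    """Fabricated per-subject summaries for battery tests.

    ``shift``: dict of column -> additive offset applied to the patient arm.
    """
    n = n_a + n_b
    idx = [f"s{i}" for i in range(n)]
    shift = shift or {}
    glob = pd.DataFrame(
        {b: rng.normal(0.3, 0.01, n) for b in bands}, index=idx
    )
    regions = ["RF", "MC", "O"]
    within = pd.DataFrame(
        {(b, r): rng.normal(0.3, 0.01, n) for b in bands for r in regions},
        index=idx,
    )
    between = pd.DataFrame(
        {(b, f"{ra}|{rb}"): rng.normal(0.3, 0.01, n)
         for b in bands for ra, rb in combinations(regions, 2)},
        index=idx,
    )
    for df in (glob, within, between):
        multi = isinstance(df.columns[0], tuple)
        if multi:
            df.columns = pd.MultiIndex.from_tuples(df.columns)
        for col, delta in shift.items():
            # exact column matches only: a bare band name must not fan out
            # over every region column of a MultiIndex frame
            if isinstance(col, tuple) == multi and col in df.columns:
                df.loc[df.index[n_a:], [col]] = (
                    df.loc[df.index[n_a:], [col]] + delta
                )
    return glob, within, between


class TestConnectivityBattery:
    def test_duplicated_groups_never_reach_stage_two(self, rng):
        vals = rng.normal(0.3, 0.01, 8)
        glob = pd.DataFrame({"delta": np.concatenate([vals, vals])})
        labels = ["control"] * 8 + ["patient"] * 8
        _, within, between = _frames(rng, n_a=8, n_b=8)
        report = eg.run_connectivity_battery(
            glob, within, between, labels, n_perm=500, seed=0
        )
        assert report.stage1.passed.sum() == 0
        assert len(report.stage2) == 0

    def test_null_stage_one_pass_rate_is_near_alpha(self, rng):
        passes = 0
        n_rep = 200
        for rep in range(n_rep):
            glob = pd.DataFrame({"delta": rng.normal(0.3, 0.01, 16)})
            report = eg.run_connectivity_battery(
                glob, None, None, _labels(), n_perm=499, seed=rep
            )
            passes += int(report.stage1.passed.iloc[0])
        # binomial(200, 0.05): 3-sigma band around 10
        assert 1 <= passes <= 20

    def test_planted_rf_contrast_gates_delta_and_localizes(self, rng):
        hits_rf, hits_other, gates = 0, 0, 0
        for rep in range(5):
            shift = {
                "delta": -0.02,
                ("delta", "RF"): -0.03,
                ("delta", "RF|MC"): -0.03,
            }
            glob, within, between = _frames(
                np.random.default_rng(rep), shift=shift
            )
            report = eg.run_connectivity_battery(
                glob, within, between, _labels(), n_perm=2000, seed=rep
            )
            gates += "delta" in report.passed_bands
            sig = report.stage2[report.stage2.significant]
            hits_rf += int(sig["name"].str.contains("RF").sum())
            hits_other += int((~sig["name"].str.contains("RF")).sum())
        assert gates >= 3  # majority of replicates
        assert hits_rf > hits_other

    def test_gating_monotone_in_contrast_strength(self):
        # expected stage-2 discoveries must not increase as the planted
        # contrast weakens (3-point grid)
        counts = []
        for strength in (3.0, 1.0, 0.0):
            total = 0
            for rep in range(6):
                shift = {
                    "delta": -0.01 * strength,
                    ("delta", "RF"): -0.012 * strength,
                }
                glob, within, between = _frames(
                    np.random.default_rng(100 + rep), shift=shift
                )
                report = eg.run_connectivity_battery(
                    glob, within, between, _labels(), n_perm=999, seed=rep
                )
                total += int(report.stage2.significant.sum())
            counts.append(total)
        assert counts[0] >= counts[1] >= counts[2]


class TestTopologyBattery:
    def _topo_frames(self, rng, n=16, dissim_shift=0.0, tree_shift=0.0):
        idx = [f"s{i}" for i in range(n)]
        trad = pd.DataFrame(
            {("delta", m): rng.normal(1.0, 0.005, n)
             for m in ("Cw_hat", "Lw_hat", "S")}, index=idx,
        )
        trad.columns = pd.MultiIndex.from_tuples(trad.columns)
        dissim = pd.DataFrame({"delta": rng.normal(0.2, 0.02, n)}, index=idx)
        tree = pd.DataFrame(
            {("delta", m): rng.normal(0.5, 0.02, n)
             for m in ("k_star_max", "l_star", "d_star")}, index=idx,
        )
        tree.columns = pd.MultiIndex.from_tuples(tree.columns)
        dissim.iloc[10:, 0] += dissim_shift
        if tree_shift:
            tree.loc[tree.index[10:], ("delta", "k_star_max")] += tree_shift
        return trad, dissim, tree

    def test_identical_groups_have_no_discoveries(self, rng):
        trad, dissim, tree = self._topo_frames(rng)
        half = list(dissim["delta"][:8])
        dissim["delta"] = half + half
        report = eg.run_topology_battery(
            trad, dissim, tree, _labels(8, 8), n_perm=500, seed=0
        )
        assert len(report.stage2) == 0

    def test_dissimilarity_gate_opens_tree_tests(self, rng):
        trad, dissim, tree = self._topo_frames(
            rng, dissim_shift=0.15, tree_shift=-0.15
        )
        report = eg.run_topology_battery(
            trad, dissim, tree, _labels(), n_perm=2000, seed=0
        )
        assert report.passed_bands == ("delta",)
        sig = report.stage2[report.stage2.significant]
        assert (sig["name"] == "k_star_max").any()

    def test_traditional_family_is_fdr_corrected(self, rng):
        trad, dissim, tree = self._topo_frames(rng)
        report = eg.run_topology_battery(
            trad, dissim, tree, _labels(), n_perm=500, seed=0
        )
        t = report.stage1[report.stage1.kind == "traditional"]
        assert len(t) == 3
        assert not t.significant.any()
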