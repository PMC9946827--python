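"""Map-construction cascade: each stage against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau

from peatmap import linkage_map as lm
from peatmap import simdata as sim

from conftest import make_genotypes, toy_genotypes

M = lm.MISSING


class TestMissingnessFilter:
    def test_clean_matrix_passes_unchanged(self):
        g = toy_genotypes(np.zeros((4, 6)))
        out = lm.filter_samples_markers(g)
        assert out.n_markers == 4 and out.n_samples == 6

    def test_mostly_missing_sample_dropped(self):
        calls = np.zeros((10, 10), dtype=np.int8)
        calls[:8, 3] = M  # sample 3: 80% missing
        out = lm.filter_samples_markers(toy_genotypes(calls), marker_miss_max=1.0)
        assert out.n_samples == 9 and "ind003" not in out.samples

    def test_two_stage_rule_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            calls = rng.integers(0, 2, (5, 5)).astype(np.int8)
            calls[rng.random((5, 5)) < 0.4] = M
            g = toy_genotypes(calls)
            try:
                out = lm.filter_samples_markers(g, 0.5, 0.3)
            except ValueError:
                out = None
            # oracle: independent two-stage evaluation
            keep_s = [j for j in range(5) if np.mean(calls[:, j] == M) <= 0.5]
            keep_m = [i for i in range(5)
                      if keep_s and np.mean(calls[i][keep_s] == M) <= 0.3]
            if not keep_s or not keep_m:
                assert out is None
            else:
                assert out is not None
                assert (out.calls == calls[np.ix_(keep_m, keep_s)]).all()


class TestPhasing:
    def test_maternal_clone_is_all_A(self):
        mat = np.array([0, 1, 1, 0], dtype=np.int8)
        g = toy_genotypes(np.tile(mat[:, None], (1, 3)))
        out = lm.phase_by_maternal(g, mat)
        assert (out.calls == 0).all()

    def test_complement_is_all_B(self):
        mat = np.array([0, 1, 1, 0], dtype=np.int8)
        g = toy_genotypes(np.tile((1 - mat)[:, None], (1, 3)))
        out = lm.phase_by_maternal(g, mat)
        assert (out.calls == 1).all()

    def test_mixed_matrix_matches_cellwise_comparison(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 2, (3, 8)).astype(np.int8)
        calls[0, 2] = M
        mat = np.array([1, 0, M], dtype=np.int8)
        out = lm.phase_by_maternal(toy_genotypes(calls), mat)
        assert out.n_markers == 2  # marker with unknown maternal allele dropped
        for i in range(2):
            for j in range(8):
                exp = M if calls[i, j] == M else int(calls[i, j] != mat[i])
                assert out.calls[i, j] == exp


class TestRepresentationLD:
    def test_skewed_marker_removed(self):
        calls = np.zeros((2, 10), dtype=np.int8)
        calls[0, :5] = 1          # balanced, kept
        calls[1, 0] = 1           # 90% A, dropped
        out = lm.filter_representation_ld(toy_genotypes(calls))
        assert out.n_markers == 1 and out.markers["id"][0] == "m0"

    def test_duplicate_markers_leave_one_survivor(self):
        row = np.array([0, 1] * 5, dtype=np.int8)
        out = lm.filter_representation_ld(toy_genotypes([row, row, row]))
        assert out.n_markers == 1
        assert out.markers["pos"][0] == 1  # tie broken to lower coordinate

    def test_random_toys_match_brute_force_rules(self):
        rng = np.random.default_rng(2)
        base = rng.integers(0, 2, (10, 40)).astype(np.int8)
        calls = base[rng.integers(0, 10, 50)]  # duplicates guaranteed
        calls[rng.random(calls.shape) < 0.02] = M
        g = toy_genotypes(calls)
        out = lm.filter_representation_ld(g)
        # oracle: representation rule
        surv = []
        for i in range(50):
            ok = calls[i] != M
            bf = (calls[i][ok] == 1).mean()
            if 0.35 <= bf <= 0.65:
                surv.append(i)
        # oracle: concordance components among survivors
        def conc(a, b):
            ok = (a != M) & (b != M)
            return (a[ok] == b[ok]).mean() if ok.any() else 0.0
        parent = {i: i for i in surv}
        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x
        for i, j in itertools.combinations(surv, 2):
            if conc(calls[i], calls[j]) > 0.999:
                parent[find(j)] = find(i)
        comps = {}
        for i in surv:
            comps.setdefault(find(i), []).append(i)
        expect = sorted(
            min(c, key=lambda i: ((calls[i] == M).mean(), i)) for c in comps.values()
        )
        got = sorted(int(x[1:]) for x in out.markers["id"])
        assert got == expect


class TestCollapse:
    def test_unlinked_markers_untouched(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 2, (5, 100)).astype(np.int8)
        out = lm.collapse_cosegregating(toy_genotypes(calls))
        assert out.n_markers == 5

    def test_identical_triple_collapses_to_one(self):
        row = np.array([0, 1] * 10, dtype=np.int8)
        out = lm.collapse_cosegregating(toy_genotypes([row, row, row]))
        assert out.n_markers == 1

    def test_chain_is_a_single_component(self):
        # a-b and b-c at RF 0.005, a-c at RF 0.01: transitive closure -> 1 marker
        n = 200
        a = np.array(([0] * 100 + [1] * 100), dtype=np.int8)
        b = a.copy(); b[[0]] ^= 1            # RF 0.005 to a
        c = a.copy(); c[[0, 199]] ^= 1       # RF 0.005 to b, 0.01 to a
        out = lm.collapse_cosegregating(toy_genotypes([a, b, c]), rf_min=0.01)
        assert out.n_markers == 1


class TestPairwiseRfLod:
    def test_identical_markers_hit_the_zero_rf_limit(self):
        row = np.array([0, 1] * 5, dtype=np.int8)
        pl = lm.pairwise_rf_lod(toy_genotypes([row, row]))
        assert pl.r_hat[0, 1] == 0.0
        assert pl.lod[0, 1] == pytest.approx(10 * np.log10(2), abs=1e-9)

    def test_two_discordant_of_ten_matches_formula(self):
        a = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1], dtype=np.int8)
        b = a.copy(); b[[0, 1]] ^= 1
        pl = lm.pairwise_rf_lod(toy_genotypes([a, b]))
        assert pl.r_hat[0, 1] == pytest.approx(0.2)
        expect = 2 * np.log10(0.2) + 8 * np.log10(0.8) + 10 * np.log10(2)
        assert pl.lod[0, 1] == pytest.approx(expect, abs=1e-9)
        assert expect == pytest.approx(0.837, abs=5e-4)

    def test_half_rf_has_zero_lod(self):
        a = np.array([0, 1, 0, 1], dtype=np.int8)
        b = np.array([0, 0, 1, 1], dtype=np.int8)
        pl = lm.pairwise_rf_lod(toy_genotypes([a, b]))
        assert pl.r_hat[0, 1] == 0.5
        assert pl.lod[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matrix_is_symmetric_with_zero_diagonal(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(0, 2, (6, 30)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.1] = M
        pl = lm.pairwise_rf_lod(toy_genotypes(calls))
        assert np.allclose(pl.r_hat, pl.r_hat.T, equal_nan=True)
        assert np.allclose(np.diag(pl.r_hat), 0.0)


class TestGroupingAndOrdering:
    def test_two_simulated_chromosomes_give_two_groups(self):
        cfg = sim.SimConfig(seed=2, n_individuals=100,
                            chrom_lengths_bp=(5_000_000,) * 2,
                            marker_spacing_bp=500_000)
        markers, calls, _ = sim.sim_pedigree(cfg)
        pl = lm.pairwise_rf_lod(make_genotypes(markers, calls))
        groups, singles = lm.form_linkage_groups(pl)
        assert len(groups) == 2 and singles.size == 0

    def test_fully_linked_set_is_one_group(self):
        row = np.array([0, 1] * 20, dtype=np.int8)
        calls = np.array([row, row, row])
        pl = lm.pairwise_rf_lod(toy_genotypes(calls))
        groups, _ = lm.form_linkage_groups(pl)
        assert len(groups) == 1 and groups[0].size == 3

    def test_small_orders_match_exhaustive_minimum(self):
        rng = np.random.default_rng(5)
        for trial in range(10):
            m = rng.integers(3, 8)
            calls = rng.integers(0, 2, (m, 40)).astype(np.int8)
            g = toy_genotypes(calls)
            pl = lm.pairwise_rf_lod(g)
            R = pl.r_hat * pl.n_inf
            order, cost = lm.order_markers_tsp(np.arange(m), pl, g)
            best = min(
                sum(R[p[i], p[i + 1]] for i in range(m - 1))
                for p in itertools.permutations(range(m))
            )
            assert cost == pytest.approx(best)

    def test_noiseless_chromosome_order_recovered(self):
        cfg = sim.SimConfig(seed=6, n_individuals=150,
                            chrom_lengths_bp=(10_000_000,),
                            marker_spacing_bp=200_000)
        markers, calls, _ = sim.sim_pedigree(cfg)
        g = make_genotypes(markers, calls)
        pl = lm.pairwise_rf_lod(g)
        order, _ = lm.order_markers_tsp(np.arange(g.n_markers), pl, g)
        pos = g.markers["pos"].to_numpy()[order]
        tau = kendalltau(np.arange(pos.size), pos).statistic
        assert abs(tau) > 0.999


class TestDistancesAndThinning:
    def test_map_function_point_values(self):
        assert lm.haldane_cM(0.2) == pytest.approx(-50 * np.log(0.6))
        assert lm.haldane_cM(0.2) == pytest.approx(25.54, abs=0.01)
        assert lm.kosambi_cM(0.2) == pytest.approx(25 * np.log(1.4 / 0.6))
        assert lm.kosambi_cM(0.2) == pytest.approx(21.18, abs=0.01)
        assert lm.haldane_cM(0.0) == 0.0

    def test_inverse_map_functions_round_trip(self):
        r = np.linspace(0.01, 0.45, 10)
        assert np.allclose(lm.haldane_r(lm.haldane_cM(r)), r)
        assert np.allclose(lm.kosambi_r(lm.kosambi_cM(r)), r)

    def test_thinning_examples_and_greedy_oracle(self):
        df = pd.DataFrame({"chrom": "c", "pos": [1, 2, 3], "id": list("abc"),
                           "cM": [0.0, 0.5, 1.1]})
        out = lm.thin_markers(df)
        assert list(out["cM"]) == [0.0, 1.1]
        rng = np.random.default_rng(7)
        cm = np.sort(rng.uniform(0, 50, 40))
        df = pd.DataFrame({"chrom": "c", "pos": np.arange(40), "id": np.arange(40),
                           "cM": cm})
        out = lm.thin_markers(df, 1.0)
        keep, last = [], -np.inf
        for i, c in enumerate(cm):  # independent greedy oracle
            if c - last >= 1.0:
                keep.append(i)
                last = c
        assert list(out["pos"]) == keep

    def test_uniform_spacing_thinning_identity(self):
        df = pd.DataFrame({"chrom": "c", "pos": np.arange(10), "id": np.arange(10),
                           "cM": np.arange(10) * 2.0})
        assert len(lm.thin_markers(df)) == 10


class TestEndToEnd:
    def test_study_scale_simulation_recovers_the_map(self):
        cfg = sim.SimConfig(seed=3, n_individuals=184,
                            chrom_lengths_bp=(20_000_000,) * 3,
                            marker_spacing_bp=200_000,
                            genotyping_error=0.005, missing_rate=0.01)
        markers, calls, truth = sim.sim_pedigree(cfg)
        res = lm.build_map(make_genotypes(markers, calls))
        assert len(res.map.groups) == 3
        for grp in res.map.groups:
            pos = grp["pos"].to_numpy()
            assert abs(kendalltau(np.arange(pos.size), pos).statistic) >= 0.95
        truth_len = sum(truth.chrom_map_length_cM(c) for c in range(3))
        assert abs(res.map.total_length_cM - truth_len) / truth_len < 0.15

    def test_map_length_inflates_with_genotyping_error(self):
        lengths = []
        for eps in (0.0, 0.01, 0.05):
            cfg = sim.SimConfig(seed=8, n_individuals=120,
                                chrom_lengths_bp=(10_000_000,),
                                marker_spacing_bp=500_000,
                                genotyping_error=eps)
            markers, calls, _ = sim.sim_pedigree(cfg)
            g = make_genotypes(markers, calls)
            pl = lm.pairwise_rf_lod(g)
            order, _ = lm.order_markers_tsp(np.arange(g.n_markers), pl, g)
            pos = lm.estimate_positions(order, pl, g)
            lengths.append(pos["cM"].iloc[-1])
        assert lengths[0] < lengths[1] < lengths[2]

    def test_filters_are_idempotent(self):
        rng = np.random.default_rng(9)
        calls = rng.integers(0, 2, (30, 60)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.01] = M
        g = toy_genotypes(calls)
        once = lm.filter_samples_markers(g)
        twice = lm.filter_samples_markers(once)
        assert (once.calls == twice.calls).all()
        once = lm.filter_representation_ld(g)
        twice = lm.filter_representation_ld(once)
        assert (once.calls == twice.calls).all()
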