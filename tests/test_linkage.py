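"""Segregation typing, two-point estimation, grouping, ordering, distortion."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from clovermap.io import read_joinmap_loc
from clovermap.linkage import (
    UninformativeLocusError,
    build_parental_consensus,
    classify_segregation,
    distortion_scan,
    estimate_rf,
    group_loci,
    haldane_r,
    informative_loci,
    kosambi_d,
    kosambi_r,
    order_group,
    pairwise_linkage,
    transmission_table,
    transmissions,
)
from clovermap.popsim import SimConfig, simulate_population


class TestClassifySegregation:
    def test_four_allele_cross(self):
        seg, classes = classify_segregation((120, 124), (128, 132))
        assert seg == "abxcd"
        assert classes == {
            (120, 128): 0.25, (120, 132): 0.25, (124, 128): 0.25, (124, 132): 0.25,
        }

    def test_shared_allele_cross(self):
        seg, _ = classify_segregation((120, 124), (120, 128))
        assert seg == "abxac"

    def test_null_allele_collapses_classes(self):
        # hand enumeration: gametes {120, null} x {120, 124}
        seg, classes = classify_segregation((120, 0), (120, 124))
        assert seg == "abxcd_null"
        assert classes == {(120,): 0.5, (120, 124): 0.25, (124,): 0.25}

    def test_double_homozygote_uninformative(self):
        with pytest.raises(UninformativeLocusError):
            classify_segregation((120, 120), (120, 120))

    def test_transmission_decoding_matches_enumeration(self):
        p1, p2 = (120, 124), (128, 132)
        table = transmission_table(p1, p2)
        assert table[(120, 128)] == (0, 0)
        assert table[(124, 132)] == (1, 1)
        # shared-heterozygote class is undecodable for both parents
        table2 = transmission_table((120, 124), (120, 124))
        assert table2[(120, 124)] == (-1, -1)


class TestMappingFunctions:
    def test_kosambi_closed_form(self):
        assert kosambi_d(0.0) == 0.0
        assert kosambi_d(0.1) == pytest.approx(25 * math.log(1.2 / 0.8), abs=1e-9)
        assert kosambi_d(0.1) == pytest.approx(10.137, abs=1e-3)

    @pytest.mark.parametrize("r", [0.0, 0.01, 0.1, 0.25, 0.4, 0.49])
    def test_round_trip_identity(self, r):
        assert kosambi_r(kosambi_d(r)) == pytest.approx(r, abs=1e-10)

    def test_strictly_increasing_and_small_r_linear(self):
        rs = np.linspace(0, 0.49, 200)
        ds = kosambi_d(rs)
        assert np.all(np.diff(ds) > 0)
        for r in (0.001, 0.005, 0.01):
            assert abs(kosambi_d(r) - 100 * r) / (100 * r) < 0.01

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            kosambi_d(0.5)
        with pytest.raises(ValueError):
            kosambi_r(-1.0)


def _single_parent_pair(n, recombinants):
    """Calls for two loci informative in parent 1 only, with a given
    number of recombinant meioses."""
    p1a, p2a = (100, 102), (104, 104)
    p1b, p2b = (200, 202), (204, 204)
    calls_a, calls_b = [], []
    for i in range(n):
        t = i % 2
        t2 = 1 - t if i < recombinants else t
        calls_a.append(tuple(sorted({(100, 102)[t], 104})))
        calls_b.append(tuple(sorted({(200, 202)[t2], 204})))
    return (p1a, p2a), (p1b, p2b), calls_a, calls_b


class TestEstimateRf:
    def test_mle_is_recombinant_fraction(self):
        pa, pb, ca, cb = _single_parent_pair(90, 9)
        est = estimate_rf("A", "B", pa, pb, ca, cb)
        assert est.r == pytest.approx(0.1)
        assert est.n_informative == 90

    def test_closed_form_lod(self):
        pa, pb, ca, cb = _single_parent_pair(100, 10)
        est = estimate_rf("A", "B", pa, pb, ca, cb)
        expected = 90 * math.log10(1.8) + 10 * math.log10(0.2)
        assert est.lod == pytest.approx(expected, abs=1e-6)
        assert est.lod == pytest.approx(15.98, abs=0.005)

    def test_complete_linkage_gives_maximal_lod(self):
        pa, pb, ca, cb = _single_parent_pair(184, 0)
        est = estimate_rf("A", "B", pa, pb, ca, cb)
        assert est.r == 0.0
        assert est.lod == pytest.approx(184 * math.log10(2))

    def test_low_information_flag(self):
        pa, pb, ca, cb = _single_parent_pair(8, 1)
        assert estimate_rf("A", "B", pa, pb, ca, cb).low_confidence

    def test_vectorized_matches_scalar(self):
        cfg = SimConfig(rng_seed=21, n_chromosome_pairs=1, markers_per_group=8,
                        population_sizes=(80, 80))
        pop = simulate_population(cfg, 0)
        parents = {l: pop.locus_parent_genotypes(l) for l in pop.calls}
        loci = informative_loci(parents, pop.calls)
        r, lod, ninf = pairwise_linkage(loci, parents, pop.calls)
        for i in range(len(loci)):
            for j in range(i + 1, len(loci)):
                est = estimate_rf(loci[i], loci[j], parents[loci[i]], parents[loci[j]],
                                  pop.calls[loci[i]], pop.calls[loci[j]])
                assert r[i, j] == pytest.approx(est.r, abs=1e-9)
                assert ninf[i, j] == est.n_informative
                if est.n_informative >= 10 and est.r < 0.5:
                    assert lod[i, j] == pytest.approx(est.lod, abs=1e-6)

    def test_estimator_consistency_bias_shrinks_with_n(self):
        """r-hat approaches the Haldane truth as the population grows."""
        true_r = haldane_r(10.0)
        rmse = {}
        for n in (92, 1000):
            errs = []
            for seed in range(12):
                cfg = SimConfig(rng_seed=seed, n_chromosome_pairs=1, markers_per_group=2,
                                chromosome_length=10.0, population_sizes=(n, n),
                                force_heterozygosity=True, null_allele_probability=0.0,
                                missing_data_rate=0.0, dual_homoeolocus_probability=0.0,
                                joining_marker_fraction=0.0)
                pop = simulate_population(cfg, 0)
                parents = {l: pop.locus_parent_genotypes(l) for l in pop.calls}
                loci = [l for l in pop.calls if pop.truth.loc[l, ["group", "homoeologue"]].tolist() == [1, 1]]
                if len(loci) < 2:
                    continue
                est = estimate_rf(loci[0], loci[1], parents[loci[0]], parents[loci[1]],
                                  pop.calls[loci[0]], pop.calls[loci[1]])
                errs.append((est.r - true_r) ** 2)
            rmse[n] = np.sqrt(np.mean(errs))
        assert rmse[1000] < rmse[92]


class TestGrouping:
    def test_lod_transitivity(self):
        loci = ["A", "B", "C"]
        lod = np.array([[0, 10, 0], [10, 0, 9], [0, 9, 0]], dtype=float)
        assert group_loci(loci, lod, 8.0) == [["A", "B", "C"]]

    def test_all_below_threshold_gives_singletons(self):
        loci = ["A", "B", "C"]
        lod = np.full((3, 3), 5.0)
        np.fill_diagonal(lod, 0)
        assert sorted(map(len, group_loci(loci, lod, 8.0))) == [1, 1, 1]


class TestOrdering:
    def test_three_locus_additivity(self):
        loci = ["X", "Y", "Z"]
        r = np.array([[0.0, 0.05, 0.15], [0.05, 0.0, 0.10], [0.15, 0.10, 0.0]])
        lod = np.where(r > 0, 20.0, 0.0)
        out = order_group(loci, loci, r, lod)
        assert out["locus"].tolist() in (["X", "Y", "Z"], ["Z", "Y", "X"])
        # largest-r pair at the ends
        assert set(out["locus"].iloc[[0, -1]]) == {"X", "Z"}
        assert out["position"].is_monotonic_increasing

    def test_orientation_canonicalized(self):
        loci = ["B", "A", "C"]
        r = np.array([[0.0, 0.05, 0.05], [0.05, 0.0, 0.10], [0.05, 0.10, 0.0]])
        lod = np.where(r > 0, 20.0, 0.0)
        out = order_group(loci, loci, r, lod)
        # lexicographically smaller terminal locus first
        assert out["locus"].iloc[0] < out["locus"].iloc[-1]

    def test_simulated_group_order_recovery(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimConfig(rng_seed=seed, n_chromosome_pairs=1, markers_per_group=10,
                            population_sizes=(184, 184), dual_homoeolocus_probability=0.0,
                            joining_marker_fraction=0.0)
            pop = simulate_population(cfg, 0)
            parents = {l: pop.locus_parent_genotypes(l) for l in pop.calls}
            loci = informative_loci(parents, pop.calls)
            r, lod, _ = pairwise_linkage(loci, parents, pop.calls)
            groups = group_loci(loci, lod, 8.0)
            big = max(groups, key=len)
            out = order_group(big, loci, r, lod)
            truth_pos = pop.truth.loc[out["locus"], "position"].to_numpy()
            rho = abs(spearmanr(out["position"], truth_pos).statistic)
            hits += rho >= 0.95
        assert hits >= 0.9 * n_seeds

    def test_map_length_recovered_within_15_percent(self):
        lengths = []
        for seed in range(20):
            cfg = SimConfig(rng_seed=seed + 300, n_chromosome_pairs=1, markers_per_group=20,
                            population_sizes=(184, 184), dual_homoeolocus_probability=0.0,
                            joining_marker_fraction=0.0)
            pop = simulate_population(cfg, 0)
            parents = {l: pop.locus_parent_genotypes(l) for l in pop.calls}
            loci = informative_loci(parents, pop.calls)
            r, lod, _ = pairwise_linkage(loci, parents, pop.calls)
            big = max(group_loci(loci, lod, 8.0), key=len)
            out = order_group(big, loci, r, lod)
            lengths.append(out["position"].max())
        assert abs(np.mean(lengths) - 80.0) / 80.0 < 0.15


class TestConsensus:
    def test_identical_maps_merge_to_themselves(self):
        m = pd.DataFrame({"locus": list("abcd"), "group": 1,
                          "position": [0.0, 10.0, 20.0, 30.0]})
        merged, notes = build_parental_consensus(m, m)
        assert notes == []
        out = merged[0]
        joined = out[out["provenance"] == "joining"]
        assert joined["locus"].tolist() == list("abcd")
        assert np.allclose(joined["position"], [0, 10, 20, 30])

    def test_consistent_bridge_order_preserved(self):
        mat = pd.DataFrame({"locus": list("abcde"), "group": 1,
                            "position": [0.0, 5.0, 12.0, 20.0, 30.0]})
        pat = pd.DataFrame({"locus": ["a", "c", "e", "x", "y"], "group": 7,
                            "position": [0.0, 14.0, 33.0, 7.0, 25.0]})
        merged, _ = build_parental_consensus(mat, pat)
        out = merged[0]
        pos = out.set_index("locus")["position"]
        assert pos["a"] < pos["c"] < pos["e"]
        assert pos["b"] < pos["c"] and pos["d"] < pos["e"]

    def test_unbridged_groups_reported(self):
        mat = pd.DataFrame({"locus": ["a", "b"], "group": 1, "position": [0.0, 10.0]})
        pat = pd.DataFrame({"locus": ["x", "y"], "group": 2, "position": [0.0, 10.0]})
        merged, notes = build_parental_consensus(mat, pat)
        assert len(merged) == 2 and len(notes) == 2


class TestDistortionScan:
    def _scan_single(self, p1, p2, calls, **kw):
        parents = {"L": (p1, p2)}
        m = pd.DataFrame({"locus": ["L"], "position": [0.0]})
        return distortion_scan(m, parents, {"L": calls}, **kw)[0]

    def test_balanced_four_class_locus_not_distorted(self):
        calls = ([(120, 128)] * 46 + [(120, 132)] * 46 + [(124, 128)] * 46
                 + [(124, 132)] * 46)
        rec = self._scan_single((120, 124), (128, 132), calls)
        assert rec.chi_square == pytest.approx(0.0)
        assert rec.p_value == pytest.approx(1.0)
        assert not rec.distorted

    def test_one_to_one_locus_60_40(self):
        calls = [(100, 104)] * 60 + [(102, 104)] * 40
        rec = self._scan_single((100, 102), (104, 104), calls)
        assert rec.chi_square == pytest.approx(4.0)
        assert rec.p_value == pytest.approx(0.0455, abs=5e-4)
        assert rec.distorted

    def test_male_origin_sign_convention(self):
        # paternal-only informative locus with P ~= 0.01 -> signed value -2
        k = 0
        n = 184
        from scipy.stats import chi2 as chi2_dist

        # choose counts giving chi-square P close to 0.01
        dev = int(round(np.sqrt(chi2_dist.ppf(0.99, 1) * n) / 2))
        a = n // 2 + dev
        calls = [(100, 104)] * a + [(102, 104)] * (n - a)
        rec = self._scan_single((104, 104), (100, 102), calls)
        assert rec.parental_origin == "male"
        assert rec.signed_log10p == pytest.approx(math.log10(rec.p_value), abs=1e-9)
        assert rec.signed_log10p < -1.3

    def test_type_one_error_rate_near_nominal(self):
        """~5% of undistorted loci flagged at P<0.05, pooled over 50 seeds."""
        flags = []
        for seed in range(50):
            cfg = SimConfig(rng_seed=seed + 700, n_chromosome_pairs=1, markers_per_group=8,
                            population_sizes=(150, 150), null_allele_probability=0.0,
                            missing_data_rate=0.0, dual_homoeolocus_probability=0.0,
                            force_heterozygosity=True, joining_marker_fraction=0.0)
            pop = simulate_population(cfg, 0)
            parents = {l: pop.locus_parent_genotypes(l) for l in pop.calls}
            loci = informative_loci(parents, pop.calls)
            m = pd.DataFrame({"locus": loci,
                              "position": pop.truth.loc[loci, "position"].to_numpy()})
            m = m.sort_values("position").reset_index(drop=True)
            for rec in distortion_scan(m, parents, pop.calls):
                flags.append(rec.distorted)
        rate = np.mean(flags)
        tol = 3 * np.sqrt(0.05 * 0.95 / len(flags))
        assert abs(rate - 0.05) < tol + 0.01

    def test_incongruous_spike_marked_removable(self):
        parents = {f"L{i}": ((100, 102), (104, 104)) for i in range(3)}
        calls = {
            "L0": [(100, 104)] * 50 + [(102, 104)] * 50,
            "L1": [(100, 104)] * 90 + [(102, 104)] * 10,
            "L2": [(100, 104)] * 50 + [(102, 104)] * 50,
        }
        m = pd.DataFrame({"locus": ["L0", "L1", "L2"], "position": [0.0, 1.0, 2.0]})
        recs = distortion_scan(m, parents, calls)
        assert recs[1].distorted and recs[1].removable
        assert not recs[0].removable and not recs[2].removable


class TestJoinMapLocReader:
    def test_cp_codes_parse_and_classify(self):
        text = """; sample
loc1 <abxcd> ac ad bc bd --
loc2 <lmxll> lm ll lm ll lm
loc3 <hkxhk> hh hk kk hk hh
"""
        parents, calls, seg = read_joinmap_loc(io.StringIO(text))
        assert set(parents) == {"loc1", "loc2", "loc3"}
        t, classes = classify_segregation(*parents["loc1"])
        assert t == "abxcd" and len(classes) == 4
        assert calls["loc1"][4] is None
        t2, classes2 = classify_segregation(*parents["loc2"])
        assert t2 == "abxaa"
        t3, classes3 = classify_segregation(*parents["loc3"])
        assert t3 == "abxab"
        assert classes3[tuple(sorted(set(p for p in parents["loc3"][0])))] == 0.5
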