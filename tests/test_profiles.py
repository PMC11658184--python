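"""Positional histograms, misincorporation matrices, paired comparisons,
truncation association, tRF calling."""

import math

import numpy as np
import pandas as pd
import pytest

from trnacharge.align import AlignmentRecord, map_reads
from trnacharge.profiles import (
    call_5prime_trfs,
    compare_cca_cc,
    end_histogram,
    gene_position_counts,
    misincorporation_matrix,
    profiles_to_frame,
    trf_table,
    truncation_association,
)
from trnacharge.reference import ReferenceSet
from trnacharge.simulate import (
    GeneParams,
    ModSite,
    SimulationConfig,
    make_canonical_gene,
    simulate_library,
)
from trnacharge.tails import classify_tails

from .oracles import trf_calls_bruteforce


def _rec(gene, ref_start, ref_end, read_id="r", ops=None, n_sub=0, n_del=0):
    if ops is None:
        ops = (("M", ref_end - ref_start),)
    return AlignmentRecord(read_id=read_id, gene_id=gene.gene_id,
                           ref_start=ref_start, ref_end=ref_end,
                           ops=tuple(ops), score=0.0, n_sub=n_sub, n_del=n_del)


class TestEndHistogram:
    def test_full_length_reads_mass_at_label_1(self, canonical76):
        rs = ReferenceSet([canonical76])
        recs = [_rec(canonical76, 0, 76, read_id=f"r{i}") for i in range(20)]
        hist = end_histogram(recs, rs, "nuclear", "five_prime")
        s = hist[canonical76.gene_id].as_series()
        assert s["1"] == 1000.0 and s.sum() == 1000.0

    def test_per_thousand_normalization_across_genome(self, rng):
        a = make_canonical_gene("a", rng)
        b = make_canonical_gene("b", rng)
        rs = ReferenceSet([a, b])
        recs = [_rec(a, 33, 76, read_id=f"a{i}") for i in range(10)]
        recs += [_rec(b, 0, 76, read_id=f"b{i}") for i in range(990)]
        hist = end_histogram(recs, rs, "nuclear", "five_prime")
        assert hist["a"].as_series()["34"] == 10.0

    def test_mass_conservation_per_genome(self, pipeline_refset):
        cfg = SimulationConfig(seed=9, n_reads_per_gene=200, treatment="control",
                               default_params=GeneParams(theta=0.5))
        reads, _ = simulate_library(cfg, pipeline_refset)
        records, _ = map_reads(reads, pipeline_refset)
        hist = end_histogram(records, pipeline_refset, "nuclear", "five_prime")
        total = sum(p.values.sum() for p in hist.values())
        assert total == pytest.approx(1000.0, abs=1e-6)

    def test_empty_genome_undefined(self, canonical76):
        rs = ReferenceSet([canonical76])
        assert end_histogram([], rs, "plastid", "five_prime") == {}

    def test_three_prime_histogram_tracks_ref_end(self, canonical76):
        rs = ReferenceSet([canonical76])
        recs = [_rec(canonical76, 0, 75, read_id=f"r{i}") for i in range(5)]
        hist = end_histogram(recs, rs, "nuclear", "three_prime")
        assert hist[canonical76.gene_id].as_series()["75"] == 1000.0


class TestMisincorporationMatrix:
    def test_error_free_library_all_zero(self, pipeline_refset):
        cfg = SimulationConfig(seed=4, n_reads_per_gene=120, treatment="control",
                               extra_degradation=0.0)
        reads, _ = simulate_library(cfg, pipeline_refset)
        records, _ = map_reads(reads, pipeline_refset)
        mat = misincorporation_matrix(records, pipeline_refset, min_cov=50)
        vals = mat.to_numpy(dtype=float)
        assert np.nanmax(vals) == 0.0

    def test_cells_match_bruteforce_recount(self, canonical76):
        rs = ReferenceSet([canonical76])
        # hand-built reads: 30 clean, 12 substituted at position 25, 6 deleted
        recs = [_rec(canonical76, 0, 76, read_id=f"c{i}") for i in range(30)]
        recs += [_rec(canonical76, 0, 76, read_id=f"s{i}", n_sub=1,
                      ops=(("M", 25), ("X", "A"), ("M", 50))) for i in range(12)]
        recs += [_rec(canonical76, 0, 76, read_id=f"d{i}", n_del=1,
                      ops=(("M", 25), ("D", 1), ("M", 50))) for i in range(6)]
        mat = misincorporation_matrix(recs, rs, min_cov=10, level="gene")
        label = canonical76.sprinzl[25]
        assert mat.at[canonical76.gene_id, label] == pytest.approx(18 / 48)
        # brute-force per-column recount agrees cell by cell
        pc = gene_position_counts(recs, canonical76)
        for lab, cov, s, d in zip(pc.sprinzl, pc.coverage, pc["sub"], pc["del"]):
            got = mat.at[canonical76.gene_id, lab]
            if cov > 10:
                assert got == pytest.approx((s + d) / cov)
            else:
                assert math.isnan(got)

    def test_deleted_position_counts_as_covered(self, canonical76):
        recs = [_rec(canonical76, 0, 76, read_id=f"d{i}", n_del=1,
                     ops=(("M", 30), ("D", 1), ("M", 45))) for i in range(60)]
        pc = gene_position_counts(recs, canonical76)
        assert pc.coverage.iloc[30] == 60 and pc["del"].iloc[30] == 60

    def test_insertions_tallied_separately(self, canonical76):
        recs = [_rec(canonical76, 0, 76, read_id=f"i{i}",
                     ops=(("M", 30), ("I", "GG"), ("M", 46))) for i in range(60)]
        rs = ReferenceSet([canonical76])
        pc = gene_position_counts(recs, canonical76)
        assert pc.ins.iloc[29] == 60
        mat = misincorporation_matrix(recs, rs, min_cov=10, level="gene")
        assert mat.at[canonical76.gene_id, canonical76.sprinzl[29]] == 0.0

    def test_low_coverage_row_masked(self, canonical76):
        rs = ReferenceSet([canonical76])
        recs = [_rec(canonical76, 0, 76, read_id=f"r{i}") for i in range(40)]
        mat = misincorporation_matrix(recs, rs, min_cov=50, level="gene")
        assert mat.loc[canonical76.gene_id].isna().all()


class TestCompareCcaCc:
    @pytest.fixture
    def four_genes(self):
        from trnacharge.simulate import random_reference_set

        return random_reference_set(4, 31)

    def _library(self, refset, mods, seed=13, n=400):
        cfg = SimulationConfig(seed=seed, n_reads_per_gene=n, treatment="periodate",
                               default_params=GeneParams(theta=0.5, mod_sites=mods))
        reads, _ = simulate_library(cfg, refset)
        records, _ = map_reads(reads, refset)
        calls = classify_tails(records, refset)
        return records, calls

    def test_shared_modification_rates_correlate(self, four_genes):
        mods = (ModSite("26", sub_prob=0.4), ModSite("58", sub_prob=0.2))
        records, calls = self._library(four_genes, mods)
        cmp = compare_cca_cc(records, calls, four_genes, min_cov=50)
        assert cmp.n_sites >= 3
        assert cmp.pearson_r > 0.9
        assert cmp.t_p > 0.05

    def test_disjoint_coverage_is_undefined_with_diagnostic(self, canonical76):
        rs = ReferenceSet([canonical76])
        cmp = compare_cca_cc([], [], rs, min_cov=50)
        assert math.isnan(cmp.t_p) and cmp.diagnostic

    def test_class_specific_site_is_largest_difference(self, canonical76):
        rs = ReferenceSet([canonical76])
        # CCA reads clean; CC reads substituted at position 25
        recs = [_rec(canonical76, 0, 76, read_id=f"cca{i}") for i in range(100)]
        recs += [_rec(canonical76, 0, 75, read_id=f"cc{i}", n_sub=1,
                      ops=(("M", 25), ("X", "A"), ("M", 49))) for i in range(100)]
        calls = classify_tails(recs, rs)
        cmp = compare_cca_cc(recs, calls, rs, min_cov=50)
        diffs = (cmp.sites.rate_cc - cmp.sites.rate_cca).abs()
        top = cmp.sites.iloc[diffs.idxmax()]
        assert top.sprinzl == canonical76.sprinzl[25]


class TestTruncationAssociation:
    def test_independent_truncation_shows_no_difference(self, pipeline_refset):
        cfg = SimulationConfig(
            seed=21, n_reads_per_gene=1500, treatment="periodate",
            extra_degradation=0.0, size_min=20,
            default_params=GeneParams(theta=0.5, cca_intact_uncharged=1.0,
                                      mod_sites=(ModSite("37", stop_prob=0.4),)))
        reads, _ = simulate_library(cfg, pipeline_refset)
        records, _ = map_reads(reads, pipeline_refset)
        calls = classify_tails(records, pipeline_refset)
        assoc = truncation_association(records, calls, pipeline_refset, min_reads=100)
        nuclear = assoc.per_genome_tests.set_index("genome").loc["nuclear"]
        assert abs(nuclear.mean_diff) < 5.0
        assert nuclear.p > 0.01

    def test_single_gene_test_undefined_but_values_present(self, canonical76):
        rs = ReferenceSet([canonical76])
        recs = [_rec(canonical76, 0, 76, read_id=f"f{i}") for i in range(150)]
        recs += [_rec(canonical76, 40, 76, read_id=f"t{i}") for i in range(150)]
        calls = classify_tails(recs, rs)
        assoc = truncation_association(recs, calls, rs, min_reads=100)
        assert len(assoc.per_gene) == 1
        assert math.isnan(assoc.per_genome_tests.p.iloc[0])

    def test_underpowered_genes_dropped_and_counted(self, canonical76):
        rs = ReferenceSet([canonical76])
        recs = [_rec(canonical76, 0, 76, read_id=f"f{i}") for i in range(150)]
        recs += [_rec(canonical76, 40, 76, read_id=f"t{i}") for i in range(10)]
        calls = classify_tails(recs, rs)
        assoc = truncation_association(recs, calls, rs, min_reads=100)
        assert assoc.per_gene.empty and assoc.n_dropped == 1


class TestTRFCaller:
    def _recs_from_distances(self, gene, dist_counts):
        recs = []
        i = 0
        for dist, count in dist_counts.items():
            for _ in range(count):
                recs.append(_rec(gene, 0, len(gene.seq) - dist, read_id=f"r{i}"))
                i += 1
        return recs

    def test_all_full_length_reads_no_calls(self, canonical76):
        recs = self._recs_from_distances(canonical76, {0: 50})
        assert call_5prime_trfs(recs, canonical76) == []

    def test_ten_percent_at_one_breakpoint(self, canonical76):
        recs = self._recs_from_distances(canonical76, {0: 90, 20: 10})
        calls = call_5prime_trfs(recs, canonical76)
        assert len(calls) == 1 and calls[0].distance == 20
        assert calls[0].fraction == pytest.approx(0.10)

    def test_distance_threshold_is_strict(self, canonical76):
        recs = self._recs_from_distances(canonical76, {0: 80, 7: 20})
        assert call_5prime_trfs(recs, canonical76) == []
        recs = self._recs_from_distances(canonical76, {0: 80, 8: 20})
        assert len(call_5prime_trfs(recs, canonical76)) == 1

    def test_cluster_reported_at_3prime_most_member(self, canonical76):
        recs = self._recs_from_distances(canonical76, {0: 70, 20: 10, 22: 10, 30: 10})
        calls = call_5prime_trfs(recs, canonical76)
        assert [c.distance for c in calls] == [20, 30]
        assert calls[0].cluster_distances == (20, 22)
        assert calls[0].cluster_fraction == pytest.approx(0.20)

    def test_agrees_with_bruteforce_on_random_profiles(self, canonical76, rng):
        for t in range(150):
            n_pos = int(rng.integers(1, 8))
            dists = rng.choice(np.arange(0, 70), size=n_pos, replace=False)
            weights = rng.dirichlet(np.ones(n_pos) * 0.5)
            counts = {int(d): max(1, int(w * 400)) for d, w in zip(dists, weights)}
            n = sum(counts.values())
            recs = self._recs_from_distances(canonical76, counts)
            calls = call_5prime_trfs(recs, canonical76)
            got = sorted((c.distance, c.cluster_fraction) for c in calls)
            exp = trf_calls_bruteforce(counts, n)
            assert [g[0] for g in got] == [e[0] for e in exp], t
            for g, e in zip(got, exp):
                assert g[1] == pytest.approx(e[1])

    def test_table_reports_detectability_limit(self, canonical76):
        rs = ReferenceSet([canonical76])
        recs = self._recs_from_distances(canonical76, {0: 90, 20: 10})
        df = trf_table(recs, rs, size_min=35)
        assert (df.max_detectable_distance == 76 - 35).all()
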