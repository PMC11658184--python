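"""Merging, trimming, fit alignment, mapping, SAM round trip."""

import numpy as np
import pytest

from trnacharge.align import (
    AlignmentRecord,
    ScoringScheme,
    fit_align,
    map_read,
    map_reads,
    merge_pairs,
    min_score,
    parse_sam,
    revcomp,
    score_of,
    trim_adapter,
    write_sam,
)
from trnacharge.reference import ReferenceSet, TRNAGene
from trnacharge.simulate import (
    GeneParams,
    ModSite,
    SimulationConfig,
    simulate_library,
)

from .oracles import affine_fit_optimum, random_alignment_pair

SCHEME = ScoringScheme()


def _plain_gene(gene_id, seq, genome="nuclear"):
    return TRNAGene(gene_id, genome, "canonical" if seq.endswith("CCA") else "t_element",
                    "Ala", "AGC", seq, "encoded" if seq.endswith("CCA") else "absent",
                    (("body", 0, len(seq)),))


class TestMergePairs:
    def _pair(self, insert, rlen):
        r1 = insert[:rlen]
        r2 = revcomp(insert[-rlen:])
        return (r1, "I" * len(r1)), (r2, "I" * len(r2))

    def test_full_overlap_identical(self, rng):
        insert = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        r1, r2 = self._pair(insert, 60)
        merged, code = merge_pairs(r1, r2)
        assert code == "merged" and merged[0] == insert

    def test_partial_overlap_reconstructs_insert(self, rng):
        insert = "".join("ACGT"[i] for i in rng.integers(0, 4, 90))
        r1, r2 = self._pair(insert, 60)  # 30-nt overlap
        merged, code = merge_pairs(r1, r2)
        assert code == "merged" and merged[0] == insert

    def test_overlap_29_rejected(self, rng):
        insert = "".join("ACGT"[i] for i in rng.integers(0, 4, 91))
        r1, r2 = self._pair(insert, 60)  # 29-nt overlap
        merged, code = merge_pairs(r1, r2)
        # the true 29-nt overlap is below the floor; any accepted merge must
        # come from a spurious >=30-nt overlap, which for random sequence
        # exceeds the mismatch cap
        assert code != "merged" or merged[0] != insert

    def test_five_mismatches_rejected(self, rng):
        insert = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
        r1 = insert[:60]
        tail = list(insert[-60:])
        # corrupt 5 distinct positions inside the 40-nt overlap region of r2
        for p in (25, 28, 31, 34, 37):
            tail[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[tail[p]]
        r2 = revcomp("".join(tail))
        _, code = merge_pairs((r1, "I" * 60), (r2, "I" * 60))
        assert code == "too_many_mismatches"

    def test_four_mismatches_accepted(self, rng):
        insert = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
        r1 = insert[:60]
        tail = list(insert[-60:])
        for p in (25, 28, 31, 34):
            tail[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[tail[p]]
        r2 = revcomp("".join(tail))
        merged, code = merge_pairs((r1, "I" * 60), (r2, "I" * 60))
        assert code == "merged"
        # disagreements resolved toward r1 (equal qualities)
        assert merged[0] == insert

    def test_empty_read_distinct_code(self):
        _, code = merge_pairs(("", ""), ("ACGT", "IIII"))
        assert code == "empty_read"


class TestTrimAdapter:
    ADAPTER = "CTGACGTAGCATCGGAATTC"  # 20 nt

    def test_exact_adapter_removed(self, rng):
        insert = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
        out, code = trim_adapter(insert + self.ADAPTER, self.ADAPTER)
        assert code == "trimmed" and out == insert

    def test_one_mismatch_in_20nt_adapter_tolerated(self, rng):
        insert = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
        noisy = "A" + self.ADAPTER[1:] if self.ADAPTER[0] != "A" else "C" + self.ADAPTER[1:]
        out, code = trim_adapter(insert + noisy + "GG", self.ADAPTER)
        assert code == "trimmed" and out == insert

    def test_missing_adapter_rejected(self, rng):
        insert = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
        _, code = trim_adapter(insert, self.ADAPTER)
        assert code == "no_adapter"

    def test_read_shorter_than_adapter_rejected(self):
        _, code = trim_adapter("ACGT", self.ADAPTER)
        assert code == "too_short"


class TestMinScore:
    @pytest.mark.parametrize("length,expected", [(76, -53.9), (0, -0.7), (35, -25.2)])
    def test_linear_threshold(self, length, expected):
        assert min_score(length) == pytest.approx(expected)


class TestFitAlign:
    def test_exact_substring_scores_zero(self, rng):
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 76))
        gene = _plain_gene("g", ref)
        rec = fit_align(ref[18:58], gene, SCHEME)
        assert rec.score == 0 and (rec.ref_start, rec.ref_end) == (18, 58)
        assert rec.ops == (("M", 40),)

    def test_single_substitution_costs_five(self, rng):
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 76))
        gene = _plain_gene("g", ref)
        read = list(ref[18:58])
        read[20] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[20]]
        rec = fit_align("".join(read), gene, SCHEME)
        assert rec.score == -5 and rec.n_sub == 1

    def test_nontemplated_tail_clipped_free_past_terminus(self, rng):
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        gene = _plain_gene("t", ref)  # no CCA -> t_element
        rec = fit_align(ref[-40:] + "CA", gene, SCHEME)
        assert rec.score == 0 and rec.clip3 == "CA"
        assert rec.ref_end == 60

    def test_free_5prime_clip_absorbs_rt_additions(self, rng):
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 76))
        gene = _plain_gene("g", ref)
        rec = fit_align("GGTA" + ref[:40], gene, SCHEME)
        assert rec.score == 0 and len(rec.clip5) in (3, 4)  # a lucky 5' base may extend the match

    def test_deletion_read_aligns_with_gap(self, rng):
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 76))
        gene = _plain_gene("g", ref)
        read = ref[10:30] + ref[31:55]
        rec = fit_align(read, gene, SCHEME)
        assert rec.score == -8 and rec.n_del == 1

    def test_score_consistent_with_ops(self, rng):
        for t in range(40):
            read, ref = random_alignment_pair(rng)
            gene = _plain_gene("g", ref if not ref.endswith("CCA") else ref + "T")
            rec = fit_align(read, gene, SCHEME)
            if rec is None:
                continue
            assert score_of(rec.ops, SCHEME, len(gene.seq), rec.ref_end) == rec.score
            assert rec.read_consumed() == len(read)
            assert rec.ref_consumed() == rec.ref_end - rec.ref_start >= SCHEME.min_ref_cols

    def test_matches_bruteforce_optimum(self, rng):
        agree = 0
        for t in range(60):
            read, ref = random_alignment_pair(rng)
            gene = _plain_gene("g", ref)
            rec = fit_align(read, gene, SCHEME)
            exp = affine_fit_optimum(read, ref, SCHEME)
            got = None if rec is None else rec.score
            assert got == exp, (t, got, exp)
            agree += 1
        assert agree == 60


class TestMapRead:
    @pytest.fixture
    def refset(self, rng):
        seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 76)) for _ in range(4)]
        return ReferenceSet([_plain_gene(f"g{i}", s) for i, s in enumerate(seqs)])

    def test_unique_read_maps_unambiguously(self, refset):
        read = refset.genes[2].seq[5:55]
        rec = map_read(read, refset)
        assert rec.gene_id == "g2" and not rec.ambiguous

    def test_equal_scores_flag_ambiguity(self, rng):
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 76))
        other = base[:70] + revcomp(base[70:])  # differs only in the last 6 nt
        if other == base:
            other = base[:70] + "AAAAAA"
        rs = ReferenceSet([_plain_gene("a", base), _plain_gene("b", other)])
        rec = map_read(base[10:60], rs)
        assert rec.ambiguous and set(rec.tied_gene_ids) == {"a", "b"}

    def test_random_read_unmapped(self, rng, refset):
        read = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
        assert map_read(read, refset) is None

    def test_winner_independent_of_reference_order(self, rng, refset):
        read = list(refset.genes[1].seq[8:56])
        read[12] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[12]]
        read = "".join(read)
        rec1 = map_read(read, refset)
        shuffled = ReferenceSet(list(reversed(refset.genes)))
        rec2 = map_read(read, shuffled)
        assert rec1.gene_id == rec2.gene_id
        assert rec1.score == rec2.score
        assert rec1.ops == rec2.ops


class TestSamRoundTrip:
    def _mapped_library(self, pipeline_refset):
        cfg = SimulationConfig(
            seed=11, n_reads_per_gene=40, treatment="periodate",
            default_params=GeneParams(
                theta=0.5,
                mod_sites=(ModSite("26", del_prob=0.15, sub_prob=0.3),
                           ModSite("58", stop_prob=0.2))))
        reads, _ = simulate_library(cfg, pipeline_refset)
        records, _ = map_reads(reads, pipeline_refset)
        return records

    def test_roundtrip_preserves_downstream_fields(self, tmp_path, pipeline_refset):
        records = self._mapped_library(pipeline_refset)
        path = tmp_path / "x.sam"
        write_sam(records, pipeline_refset, path)
        back = parse_sam(path, pipeline_refset)
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert (a.read_id, a.gene_id, a.ref_start, a.ref_end) == \
                   (b.read_id, b.gene_id, b.ref_start, b.ref_end)
            assert a.ops == b.ops
            assert (a.n_sub, a.n_del, a.n_ins) == (b.n_sub, b.n_del, b.n_ins)
            assert a.ambiguous == b.ambiguous and a.tied_gene_ids == b.tied_gene_ids

    def test_sam_conventions(self, tmp_path, rng):
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 76))
        gene = _plain_gene("g", ref)
        rs = ReferenceSet([gene])
        full = fit_align(ref, gene, SCHEME, read_id="full")
        clipped = fit_align("TT" + ref[:40], gene, SCHEME, read_id="clipped")
        deleted = fit_align(ref[:30] + ref[31:], gene, SCHEME, read_id="deleted")
        path = tmp_path / "y.sam"
        write_sam([full, clipped, deleted], rs, path)
        lines = [l.split("\t") for l in path.read_text().splitlines()
                 if not l.startswith("@")]
        by_name = {f[0]: f for f in lines}
        assert by_name["full"][3] == "1" and by_name["full"][5] == "76M"
        assert by_name["clipped"][5].startswith("2S")
        assert "1D" in by_name["deleted"][5]
        assert "NM:i:1" in by_name["deleted"]

    def test_unknown_gene_is_hard_error(self, tmp_path, rng):
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 76))
        gene = _plain_gene("g", ref)
        rec = fit_align(ref[:40], gene, SCHEME)
        rs = ReferenceSet([_plain_gene("other", ref[::-1])])
        with pytest.raises(KeyError):
            write_sam([rec], rs, tmp_path / "z.sam")
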