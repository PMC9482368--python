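"""Tolerant mapping, consensus building and cyclic CDS extension."""

from collections import Counter

import pytest

import opsinpipe as op
from opsinpipe.extract import (
    ReadAlignment,
    TolerantMapParams,
    snp_partition,
    tolerant_map,
)
from opsinpipe.simulate import reverse_complement


def _mutate(seq: str, positions: dict[int, str]) -> str:
    out = list(seq)
    for pos, base in positions.items():
        out[pos] = base
    return "".join(out)


class TestTolerantMap:
    def test_exact_read_accepted_with_zero_mismatch(self, solo_reads):
        _, panel, _, pairs, _ = solo_reads
        ref = panel["gene1"].sequence
        alns = tolerant_map(pairs[:10], ref, TolerantMapParams())
        assert len(alns) == 20
        assert all(a.mismatch_pct == 0.0 for a in alns)

    def test_reverse_mate_strand_recorded(self, solo_reads):
        _, panel, _, pairs, _ = solo_reads
        alns = tolerant_map(pairs[:5], panel["gene1"].sequence, TolerantMapParams())
        strands = {a.read_id.rsplit("/", 1)[1]: a.strand for a in alns}
        assert strands == {"1": "+", "2": "-"}

    def test_read_over_mismatch_ceiling_rejected(self):
        ref = "ATG" + "ACGT" * 60 + "TAA"
        read = ref[10:60]
        # 45% of positions substituted: above the 40% ceiling
        bad = _mutate(read, {i: ("A" if read[i] != "A" else "C") for i in range(0, 45)})
        params = TolerantMapParams()
        pairs = [("p0", bad, reverse_complement(read))]
        alns = tolerant_map(pairs, ref, params)
        assert alns == []  # both-mates rule: rejected pair contributes nothing

    def test_pair_rejected_when_one_mate_has_no_seed(self, solo_reads):
        _, panel, _, pairs, _ = solo_reads
        ref = panel["gene1"].sequence
        pid, m1, _ = pairs[0]
        unrelated = "ACGTGCATTGCA" * 13  # no 14-mer shared with ref
        alns = tolerant_map([(pid, m1, unrelated[: len(m1)])], ref, TolerantMapParams())
        assert alns == []
        relaxed = TolerantMapParams(require_both_mates=False)
        alns = tolerant_map([(pid, m1, unrelated[: len(m1)])], ref, relaxed)
        assert [a.read_id for a in alns] == [f"{pid}/1"]

    def test_mismatched_mate_ids_rejected(self, tmp_path):
        (tmp_path / "a_R1.fastq").write_text("@x/1\nACGT\n+\nFFFF\n")
        (tmp_path / "a_R2.fastq").write_text("@y/2\nACGT\n+\nFFFF\n")
        with pytest.raises(ValueError, match="mismatched"):
            op.load_paired_fastq(tmp_path / "a_R1.fastq", tmp_path / "a_R2.fastq")


class TestBuildConsensus:
    def _aln(self, read_id, start, query, target):
        return ReadAlignment(
            read_id=read_id, gene_id="g", reference_start=start,
            reference_end=start + len(target.replace("-", "")), strand="+",
            mismatch_pct=0.0, gap_pct=0.0,
            query_aligned=query, target_aligned=target,
        )

    def test_identical_reads_reproduce_reference_region(self):
        ref = "AACCGGTTAACCGGTT"
        alns = [self._aln(f"r{i}", 4, ref[4:12], ref[4:12]) for i in range(3)]
        assert op.build_consensus(alns, len(ref)) == ref[4:12]

    def test_majority_vote_per_column(self):
        alns = [self._aln(f"a{i}", 0, "A", "G") for i in range(6)]
        alns += [self._aln(f"g{i}", 0, "G", "G") for i in range(4)]
        assert op.build_consensus(alns, 1) == "A"

    def test_tie_breaks_to_highest_base_in_fixed_order(self):
        alns = [self._aln("a", 0, "A", "C"), self._aln("g", 0, "G", "C")]
        assert op.build_consensus(alns, 1) == "G"

    def test_interior_zero_coverage_emits_n(self):
        alns = [self._aln("l", 0, "ACGTA", "ACGTA"), self._aln("r", 15, "CGTAC", "CGTAC")]
        consensus = op.build_consensus(alns, 20)
        assert consensus == "ACGTA" + "N" * 10 + "CGTAC"

    def test_empty_alignment_set_rejected(self):
        with pytest.raises(ValueError):
            op.build_consensus([], 10)


class TestSnpPartition:
    def test_pile_keeps_only_reference_consistent_pairs(self, family2):
        _, panel, _, pairs, truth = family2
        ref = panel["gene2"].sequence
        alns = tolerant_map(pairs, ref, TolerantMapParams(), "gene2")
        pile = snp_partition(alns, ref)
        pile_pairs = {a.read_id.rsplit("/", 1)[0] for a in pile}
        origins = Counter(truth.per_read_origin[p] for p in pile_pairs)
        assert origins["gene1"] == 0
        assert origins["gene2"] > 0

    def test_single_gene_reads_form_one_pile(self, solo_reads):
        _, panel, _, pairs, _ = solo_reads
        ref = panel["gene1"].sequence
        alns = tolerant_map(pairs, ref, TolerantMapParams(), "gene1")
        pile = snp_partition(alns, ref)
        assert len(pile) == len(alns)


class TestIterativeExtend:
    def test_complete_seed_returned_unchanged(self, solo_reads):
        _, panel, fam_truth, pairs, _ = solo_reads
        truth = fam_truth.true_sequences["gene1"]
        out = op.iterative_extend(pairs, truth, panel["gene1"])
        assert out.sequence == truth
        assert out.complete
        assert out.iterations_used == 0

    def test_central_seed_recovers_full_cds_exactly(self, solo_reads):
        _, panel, fam_truth, pairs, _ = solo_reads
        truth = fam_truth.true_sequences["gene1"]
        seed = truth[382:682]
        out = op.iterative_extend(pairs, seed, panel["gene1"])
        assert out.complete
        assert out.sequence == truth

    def test_coverage_gap_yields_partial(self, solo_reads):
        cfg, panel, fam_truth, pairs, _ = solo_reads
        truth = fam_truth.true_sequences["gene1"]
        ref = panel["gene1"].sequence
        # drop every pair whose fragment touches a 200 bp interior window
        window = (500, 700)
        kept = []
        for pid, m1, m2 in pairs:
            s1 = ref.find(m1)
            s2 = ref.find(reverse_complement(m2))
            spans = [(s1, s1 + len(m1)), (s2, s2 + len(m2))]
            if all(e <= window[0] or s >= window[1] for s, e in spans):
                kept.append((pid, m1, m2))
        out = op.iterative_extend(kept, truth[100:350], panel["gene1"])
        assert not out.complete
        assert len(out.sequence) < len(truth)

    def test_extension_monotone_and_exact_on_paralog_mixture(self, family2):
        _, panel, fam_truth, pairs, _ = family2
        truth = fam_truth.true_sequences["gene2"]
        seed = truth[300:650]
        out = op.iterative_extend(pairs, seed, panel["gene2"])
        assert out.complete
        assert out.sequence == truth  # paralog reads never pass 100% identity


class TestExtractGenes:
    def test_two_paralogs_recovered_byte_exact(self, family2):
        _, panel, fam_truth, pairs, _ = family2
        results = op.extract_genes(pairs, panel)
        assert sorted(r.gene_id for r in results) == ["gene1", "gene2"]
        for r in results:
            assert r.complete
            assert r.sequence == fam_truth.true_sequences[r.gene_id]

    def test_reads_from_one_gene_only(self, solo_reads):
        cfg, panel, fam_truth, pairs, _ = solo_reads
        two = op.ReferencePanel(
            [panel["gene1"], op.ReferenceOpsin("ghost", "RH2", "ATG" + "CAT" * 100 + "TAA")]
        )
        results = op.extract_genes(pairs, two)
        assert [r.gene_id for r in results] == ["gene1"]
        assert results[0].sequence == fam_truth.true_sequences["gene1"]

    def test_empty_input_warns_and_returns_nothing(self, toy_panel, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            assert op.extract_genes([], toy_panel) == []
        assert "no read pairs" in caplog.text
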