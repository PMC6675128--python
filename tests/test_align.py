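"""Aligner contracts: DP-oracle equivalence, primary selection, partitioning."""

from dataclasses import replace

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trfseq import align as al
from trfseq import reference as rf
from trfseq import simulate as sim

from dp_oracle import local_affine

TRNA = rf.TRNA_HIS_ID


def stub(read_id="r", ref_id=TRNA, start=0, end=18, score=30.0, seq=None, **kw):
    seq = seq if seq is not None else rf.TRNA_HIS_CORE[start:end]
    return al.AlignmentRecord(
        read_id=read_id,
        ref_id=ref_id,
        core_start=start,
        core_end=end,
        cigar=f"{len(seq)}M",
        mismatches=(),
        score=score,
        read_seq=seq,
        soft5=0,
        soft3=0,
        **kw,
    )


class TestAlignRead:
    def test_exact_match_in_padded_entry(self):
        ref = rf.build_padded_reference([("x", "ACGTACGTACGTACGTACGT")], 2)
        params = al.AlignParams(min_score=8)
        recs = al.align_read("ACGTACGTACGTACGTACGT", ref, params)
        (rec,) = recs
        assert (rec.core_start, rec.core_end) == (0, 20)
        assert rec.mismatches == () and rec.score == 40

    def test_full_length_trna_read_is_unique_best(self, ref):
        recs = al.select_primary(al.align_read(rf.TRNA_HIS_CORE, ref))
        assert len(recs) == 1
        rec = recs[0]
        assert rec.ref_id == TRNA
        assert (rec.core_start, rec.core_end) == (0, 76)
        assert rec.weight == 1.0

    def test_nontemplated_5p_t_is_clipped_not_shifted(self, ref):
        read = "T" + rf.TRNA_HIS_CORE[:30]
        (rec,) = [r for r in al.align_read(read, ref) if r.ref_id == TRNA]
        assert rec.core_start == 0 and rec.soft5 == 1
        assert rec.cigar == "1S30M"

    def test_short_read_rejected(self, ref):
        with pytest.raises(al.AlignmentError, match="too_short"):
            al.align_read("ACGTACGTACGT", ref)

    def test_empty_reference_rejected(self):
        empty = rf.PaddedReference(entries={}, pad_len=10)
        with pytest.raises(al.AlignmentError):
            al.align_read("ACGT" * 5, empty)


class TestOracleEquivalence:
    def test_matches_naive_dp_on_random_instances(self):
        """Scores/end coordinates equal a brute-force Gotoh DP (no pads)."""
        rng = np.random.default_rng(2019)
        params = al.AlignParams(min_score=4)
        for k in range(200):
            ref_seq = "".join(rng.choice(list("ACGT"), rng.integers(30, 61)))
            if k % 2:
                read = "".join(rng.choice(list("ACGT"), rng.integers(15, 41)))
            else:  # mutated substring: realistic, guaranteed-alignable
                lo = int(rng.integers(0, len(ref_seq) - 16))
                hi = int(rng.integers(lo + 15, min(lo + 40, len(ref_seq)) + 1))
                bases = list(ref_seq[lo:hi])
                for _ in range(int(rng.integers(0, 3))):
                    bases[rng.integers(len(bases))] = rng.choice(list("ACGT"))
                read = "".join(bases)
            ref = rf.build_padded_reference([("t", ref_seq)], 0)
            oracle_score, oracle_ends = local_affine(ref_seq, read)
            recs = al.align_read(read, ref, params)
            if not recs:
                assert oracle_score < params.min_score
                continue
            rec = recs[0]
            assert rec.score == oracle_score
            assert (rec.core_end, len(read) - rec.soft3) in oracle_ends
            assert rec.rescore(ref_seq, params) == rec.score


class TestSelectPrimary:
    def test_shared_maximum_gets_fractional_weight(self):
        recs = [stub(score=s, ref_id=r) for s, r in [(30, "a"), (30, "b"), (12, "c")]]
        ref = rf.build_padded_reference(
            [("a", "ACGT" * 5), ("b", "TTTT" * 5), ("c", "GGGG" * 5)]
        )
        out = al.select_primary(
            [replace(r, ref_id=rid) for r, rid in zip(recs, "abc")]
        )
        assert len(out) == 2
        assert all(r.is_primary and r.weight == 0.5 for r in out)

    def test_singleton(self):
        (out,) = al.select_primary([stub(score=30)])
        assert out.is_primary and out.weight == 1.0

    def test_empty(self):
        assert al.select_primary([]) == []

    def test_discriminating_base_resolves_trna_vs_decoy(self, ref):
        # 21-mer from the tRNA 3' end: A at the m1A site -> one mismatch vs
        # the decoy, so the tRNA wins by mismatch-vs-match score difference
        read = rf.TRNA_HIS_CORE[55:]
        out = al.select_primary(al.align_read(read, ref))
        assert [r.ref_id for r in out] == [TRNA]


class TestPartition:
    def test_boundary_at_50(self):
        recs = [stub(read_id=str(n), seq="A" * n) for n in (51, 50, 18)]
        long, short = al.partition_by_length(recs, 50)
        assert [r.read_len for r in long] == [51]
        assert sorted(r.read_len for r in short) == [18, 50]

    def test_empty(self):
        assert al.partition_by_length([], 50) == ([], [])

    @settings(derandomize=True, max_examples=30)
    @given(lengths=st.lists(st.integers(15, 90), max_size=40), threshold=st.integers(1, 90))
    def test_counts_conserved(self, lengths, threshold):
        recs = [stub(read_id=str(i), seq="A" * n) for i, n in enumerate(lengths)]
        long, short = al.partition_by_length(recs, threshold)
        assert len(long) + len(short) == len(recs)
        assert {r.read_id for r in long}.isdisjoint(r.read_id for r in short)


class TestLibraryAlignment:
    def test_noise_free_mock_aligns_perfectly(self, ref, clean_mock_lib):
        records, truth, rejected = clean_mock_lib
        assert not rejected
        assert len(records) == len(truth)
        assert all(r.ref_id == TRNA for r in records)
        assert all((r.core_start, r.core_end) == (0, 76) for r in records)
        assert all(r.mismatches == () for r in records)

    def test_cigar_consumes_read_and_score_rederives(self, ref, mock_lib):
        records, _, _ = mock_lib
        for r in records[:500]:
            consumed = sum(n for op, n in r.cigar_ops() if op in "SMI")
            assert consumed == r.read_len
            assert r.rescore(ref.core(r.ref_id)) == r.score

    def test_read_accounting(self, ref, mock_lib):
        records, truth, rejected = mock_lib
        assert len({r.read_id for r in records}) + len(rejected) == len(truth)


class TestIO:
    def test_tsv_round_trip(self, mock_lib, tmp_path):
        records = mock_lib[0][:50]
        path = tmp_path / "aln.tsv"
        al.write_tsv(records, path)
        assert al.read_tsv(path) == records

    def test_sam_fields(self, ref, mock_lib, tmp_path):
        records = mock_lib[0][:20]
        path = tmp_path / "aln.sam"
        al.write_sam(records, ref, path)
        with pysam.AlignmentFile(str(path), "r") as fh:
            assert fh.header["SQ"][0]["LN"] == 96  # padded length
            got = list(fh)
        assert len(got) == 20
        for a, r in zip(got, records):
            assert a.query_name == r.read_id
            assert a.reference_start == r.core_start + ref.pad_len
            assert a.get_tag("ZC") == r.core_start
            assert a.get_tag("ZW") == pytest.approx(r.weight)
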