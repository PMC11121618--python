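"""Reference/panel/variant I/O, window extraction and edit application."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from g4mm.genome_io import (
    GenomicInterval,
    GermlineFilterReport,
    SequenceWindow,
    Variant,
    VariantClass,
    VariantOrigin,
    apply_variants,
    extract_window,
    filter_germline,
    load_reference,
    merge_intervals,
    read_panel,
    read_variants,
    reverse_complement,
    write_panel,
)

from conftest import write_fasta


# ---------------------------------------------------------------------------
# FASTA


class TestLoadReference:
    def test_two_contigs_with_lengths(self, tmp_path):
        path = write_fasta(tmp_path / "r.fa", {"chr1": "ACGT", "chr2": "GGGG"})
        store = load_reference(path)
        assert {k: len(v) for k, v in store.items()} == {"chr1": 4, "chr2": 4}

    def test_lowercase_is_uppercased(self, tmp_path):
        path = write_fasta(tmp_path / "r.fa", {"chr1": "acgt"})
        assert load_reference(path)["chr1"] == "ACGT"

    def test_duplicate_contig_is_error(self, tmp_path):
        path = tmp_path / "r.fa"
        path.write_text(">chr1\nACGT\n>chr1\nTTTT\n")
        with pytest.raises(ValueError, match="duplicate contig"):
            load_reference(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_reference(tmp_path / "absent.fa")

    def test_empty_fasta(self, tmp_path):
        path = tmp_path / "r.fa"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            load_reference(path)

    def test_non_iupac_character_names_position(self, tmp_path):
        path = write_fasta(tmp_path / "r.fa", {"chrZ": "ACXT"})
        with pytest.raises(ValueError, match=r"chrZ:3"):
            load_reference(path)


# ---------------------------------------------------------------------------
# BED panel


class TestReadPanel:
    def test_overlap_merge(self, tmp_path):
        bed = tmp_path / "p.bed"
        bed.write_text("chr1\t10\t20\nchr1\t15\t30\n")
        panel = read_panel(bed)
        assert panel == [GenomicInterval("chr1", 10, 30)]
        assert sum(len(iv) for iv in panel) == 20

    def test_two_chroms_sorted(self, tmp_path):
        bed = tmp_path / "p.bed"
        bed.write_text("chr2\t0\t5\nchr1\t3\t9\n")
        panel = read_panel(bed)
        assert [iv.chrom for iv in panel] == ["chr1", "chr2"]

    def test_inverted_row_reports_line(self, tmp_path):
        bed = tmp_path / "p.bed"
        bed.write_text("chr1\t0\t5\nchr1\t20\t10\n")
        with pytest.raises(ValueError, match=":2"):
            read_panel(bed)

    def test_adjacent_intervals_merge(self, tmp_path):
        bed = tmp_path / "p.bed"
        bed.write_text("chr1\t0\t10\nchr1\t10\t20\n")
        assert read_panel(bed) == [GenomicInterval("chr1", 0, 20)]

    def test_write_read_round_trip_idempotent(self, tmp_path):
        bed = tmp_path / "p.bed"
        bed.write_text("chr1\t5\t9\nchr1\t0\t6\nchr2\t2\t4\n")
        panel = read_panel(bed)
        out = tmp_path / "merged.bed"
        write_panel(panel, out)
        assert read_panel(out) == panel

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 50), st.integers(1, 20)),
            min_size=1,
            max_size=12,
        )
    )
    def test_merge_idempotent_and_disjoint(self, raw):
        intervals = [GenomicInterval("c", s, s + w) for s, w in raw]
        merged = merge_intervals(intervals)
        assert merge_intervals(merged) == merged
        for a, b in zip(merged, merged[1:]):
            assert a.end < b.start  # strictly disjoint, non-adjacent


# ---------------------------------------------------------------------------
# VCF

VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000>
##INFO=<ID=AF,Number=A,Type=Float,Description="pop AF">
##INFO=<ID=CSQ,Number=.,Type=String,Description="consequence">
##FILTER=<ID=LowQual,Description="low">
##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
chr1\t101\trs1\tA\tG\t.\tPASS\tAF=0.25;CSQ=5_prime_UTR_variant\tGT:DP:AD\t0/1:20:12,8
chr1\t150\t.\tA\tG,T\t.\tPASS\tAF=0.1,0.2\tGT:DP:AD\t1/2:30:10,12,8
chr1\t200\t.\tC\tT\t.\tLowQual\t.\tGT:DP:AD\t0/1:9:5,4
"""


class TestReadVariants:
    @pytest.fixture
    def vcf_path(self, tmp_path):
        path = tmp_path / "s1.vcf"
        path.write_text(VCF_TEXT)
        return path

    def test_snv_fields(self, vcf_path):
        variants = read_variants(vcf_path, "S1", VariantOrigin.GERMLINE)
        v = variants[0]
        assert (v.chrom, v.pos, v.ref, v.alt) == ("chr1", 101, "A", "G")
        assert v.vclass is VariantClass.SNV
        assert v.dp == 20 and v.ad_alt == 8
        assert v.af_pop == pytest.approx(0.25)
        assert v.consequence == "5_prime_UTR_variant"
        assert v.rsid == "rs1"

    def test_multiallelic_split(self, vcf_path):
        variants = read_variants(vcf_path, "S1", VariantOrigin.GERMLINE)
        alts = [(v.pos, v.alt) for v in variants if v.pos == 150]
        assert alts == [(150, "G"), (150, "T")]
        by_alt = {v.alt: v for v in variants if v.pos == 150}
        assert by_alt["G"].ad_alt == 12 and by_alt["T"].ad_alt == 8
        assert by_alt["G"].af_pop == pytest.approx(0.1)
        assert by_alt["T"].af_pop == pytest.approx(0.2)

    def test_nonpass_excluded_by_default(self, vcf_path):
        variants = read_variants(vcf_path, "S1", VariantOrigin.GERMLINE)
        assert all(v.pos != 200 for v in variants)

    def test_keep_nonpass(self, vcf_path):
        variants = read_variants(vcf_path, "S1", VariantOrigin.GERMLINE, keep_nonpass=True)
        assert any(v.pos == 200 for v in variants)


class TestFilterGermline:
    @pytest.mark.parametrize(
        "dp,ad,kept",
        [(11, 6, True), (10, 6, False), (11, 5, False), (100, 6, True)],
    )
    def test_strict_thresholds(self, dp, ad, kept):
        v = Variant("chr1", 1, "A", "G", dp=dp, ad_alt=ad)
        out, report = filter_germline([v])
        assert (len(out) == 1) is kept
        assert report.total == 1

    def test_missing_depth_is_unscored(self):
        v = Variant("chr1", 1, "A", "G", dp=None, ad_alt=6)
        out, report = filter_germline([v])
        assert out == [] and report.unscored == 1 and report.dropped == 0

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_germline([], min_dp=-1)


# ---------------------------------------------------------------------------
# Windows


def _long_reference(n=1000, seed=5):
    rng = np.random.default_rng(seed)
    return {"chr1": "".join(rng.choice(list("ACGT"), size=n))}


class TestExtractWindow:
    def test_snv_interval_and_length(self):
        ref = _long_reference()
        v = Variant("chr1", 100, ref["chr1"][99], "A" if ref["chr1"][99] != "A" else "C")
        w = extract_window(ref, v, flank=70)
        assert (w.interval.start, w.interval.end) == (29, 170)
        assert len(w.seq) == 141 and w.clipped_left == w.clipped_right == 0

    def test_left_clipping(self):
        ref = _long_reference()
        v = Variant("chr1", 10, ref["chr1"][9], "A" if ref["chr1"][9] != "A" else "C")
        w = extract_window(ref, v, flank=70)
        assert w.clipped_left == 61 and len(w.seq) == 80

    def test_deletion_anchor_span(self):
        ref = _long_reference()
        anchor = ref["chr1"][99:102]
        v = Variant("chr1", 100, anchor, anchor[0])
        w = extract_window(ref, v, flank=70)
        assert (w.interval.start, w.interval.end) == (29, 172)
        assert len(w.seq) == 143

    def test_anchor_base_matches_ref(self, rng):
        ref = _long_reference()
        for pos in rng.integers(80, 900, size=25):
            base = ref["chr1"][pos - 1]
            v = Variant("chr1", int(pos), base, "A" if base != "A" else "C")
            w = extract_window(ref, v)
            assert w.seq[w.flank] == base

    def test_missing_contig(self):
        with pytest.raises(KeyError):
            extract_window({"chr1": "ACGT" * 100}, Variant("chrX", 10, "A", "C"))

    def test_reference_mismatch(self):
        ref = {"chr1": "A" * 200}
        with pytest.raises(ValueError, match="mismatch"):
            extract_window(ref, Variant("chr1", 100, "C", "T"))


def _window(seq, start=0, chrom="chr1", applied=()):
    return SequenceWindow(
        interval=GenomicInterval(chrom, start, start + len(seq)),
        seq=seq,
        flank=2,
        applied_edits=tuple(applied),
    )


class TestApplyVariants:
    def test_snv_splice(self):
        w = apply_variants(_window("AAAAA"), [Variant("chr1", 3, "A", "G")])
        assert w.seq == "AAGAA"

    def test_deletion_splice(self):
        w = apply_variants(_window("AAAAA"), [Variant("chr1", 2, "AA", "A")])
        assert w.seq == "AAAA"

    def test_two_edits_same_base_error(self):
        with pytest.raises(ValueError, match="overlapping"):
            apply_variants(
                _window("AAAAA"),
                [Variant("chr1", 3, "A", "G"), Variant("chr1", 3, "A", "T")],
            )

    def test_edit_outside_interval_skipped(self):
        w = apply_variants(_window("AAAAA"), [Variant("chr1", 99, "A", "G")])
        assert w.seq == "AAAAA" and len(w.skipped_edits) == 1

    def test_zero_edits_identity(self):
        w = _window("ACGTA")
        assert apply_variants(w, []).seq == w.seq

    def test_ref_mismatch_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            apply_variants(_window("AAAAA"), [Variant("chr1", 3, "C", "G")])

    def test_insertion_then_reverse_deletion_round_trip(self, rng):
        """Inserting then deleting the same bases restores the sequence."""
        for _ in range(50):
            n = int(rng.integers(10, 40))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            pos = int(rng.integers(1, n))
            ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
            w0 = _window(seq)
            w1 = apply_variants(w0, [Variant("chr1", pos, seq[pos - 1], seq[pos - 1] + ins)])
            # the inverse deletion addresses the edited haplotype, so apply it
            # to a fresh window over that sequence
            w2 = apply_variants(
                _window(w1.seq), [Variant("chr1", pos, seq[pos - 1] + ins, seq[pos - 1])]
            )
            assert w2.seq == seq

    def test_cross_batch_coordinate_shift(self):
        """A later edit is located correctly after an earlier indel."""
        # reference coords: pos 2 deletion (AA->A), then SNV at pos 5
        w = _window("AACGT")
        w = apply_variants(w, [Variant("chr1", 1, "AA", "A")])
        assert w.seq == "ACGT"
        w = apply_variants(w, [Variant("chr1", 5, "T", "G")])
        assert w.seq == "ACGG"

    def test_multiple_edits_right_to_left(self):
        w = apply_variants(
            _window("AAAAA"),
            [Variant("chr1", 1, "A", "T"), Variant("chr1", 4, "AA", "A")],
        )
        assert w.seq == "TAAA"


def test_variant_class_derivation():
    assert Variant("c", 1, "A", "G").vclass is VariantClass.SNV
    assert Variant("c", 1, "AT", "GC").vclass is VariantClass.MNV
    assert Variant("c", 1, "A", "AG").vclass is VariantClass.INS
    assert Variant("c", 1, "AG", "A").vclass is VariantClass.DEL
    with pytest.raises(ValueError):
        Variant("c", 1, "A", "A")


def test_reverse_complement():
    assert reverse_complement("GGGCAT") == "ATGCCC"
    assert reverse_complement(reverse_complement("ACGTN")) == "ACGTN"
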