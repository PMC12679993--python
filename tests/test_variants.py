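"""Variant parsing, application, and frameshift classification."""

import numpy as np
import pytest

from fsneo.sequence import Transcript
from fsneo.variants import (
    CodingVariant,
    FrameshiftClass,
    VariantClass,
    apply_variant,
    classify_frameshift,
    parse_hgvs_c,
    read_maf,
    read_vcf_projected,
)

MAF_HEADER = (
    "Hugo_Symbol\tTranscript_ID\tTumor_Sample_Barcode\tVariant_Classification\t"
    "Variant_Type\tHGVSc\tReference_Allele\tTumor_Seq_Allele2\n"
)


def _mk(pos, ref, alt, vclass, tid="T1", patient="p1"):
    return CodingVariant(patient, tid, pos, ref, alt, vclass)


class TestHgvsParsing:
    @pytest.mark.parametrize(
        "hgvs,expected",
        [
            ("c.331delG", (331, "G", "", VariantClass.DELETION)),
            ("c.3_4insAA", (3, "", "AA", VariantClass.INSERTION)),
            ("c.76A>T", (76, "A", "T", VariantClass.SNV)),
            ("c.10_12delACG", (10, "ACG", "", VariantClass.DELETION)),
            ("c.10_12del", (10, "NNN", "", VariantClass.DELETION)),
            ("c.5_7delinsTT", (5, "NNN", "TT", VariantClass.DELINS)),
            ("c.8dupT", (8, "", "T", VariantClass.INSERTION)),
        ],
    )
    def test_supported_forms(self, hgvs, expected):
        assert parse_hgvs_c(hgvs) == expected

    @pytest.mark.parametrize("hgvs", ["c.-12A>T", "c.88+2T>C", "p.G110fs", "", "c.10_12delAC"])
    def test_unsupported_forms_return_none(self, hgvs):
        assert parse_hgvs_c(hgvs) is None


class TestReadMaf:
    def test_rows_parsed_and_skips_counted(self, tmp_path):
        rows = [
            "g\tT1\tp1\tFrame_Shift_Del\tDEL\tc.331delG\tG\t-",
            "g\tT1\tp1\tFrame_Shift_Ins\tINS\tc.3_4insAA\t-\tAA",
            "g\tT1\tp2\tMissense_Mutation\tSNP\tc.7A>C\tA\tC",
            "g\tT1\tp2\tSplice_Site\tSNP\t\t-\t-",  # no HGVSc, no CDS_position
            "g\tT1\tp2\tIntron\tSNP\tc.88+2T>C\t-\t-",  # unsupported form
        ]
        maf = tmp_path / "m.maf"
        maf.write_text(MAF_HEADER + "\n".join(rows) + "\n")
        variants, report = read_maf(maf)
        assert len(variants) == 3
        assert len(report) == 2
        assert set(report["reason"]) == {"no_coding_annotation"}
        assert variants[0] == _mk(331, "G", "", VariantClass.DELETION)

    def test_comment_lines_tolerated(self, tmp_path):
        maf = tmp_path / "m.maf"
        maf.write_text("#version 2.4\n" + MAF_HEADER +
                       "g\tT1\tp1\tMissense_Mutation\tSNP\tc.7A>C\tA\tC\n")
        variants, _ = read_maf(maf)
        assert len(variants) == 1

    def test_missing_columns_hard_error(self, tmp_path):
        maf = tmp_path / "m.maf"
        maf.write_text("Hugo_Symbol\tHGVSc\ngene\tc.7A>C\n")
        with pytest.raises(ValueError, match="missing required columns"):
            read_maf(maf)

    def test_coordinate_columns_fallback(self, tmp_path):
        header = (
            "Transcript_ID\tTumor_Sample_Barcode\tVariant_Classification\t"
            "Variant_Type\tCDS_position\tReference_Allele\tTumor_Seq_Allele2\n"
        )
        maf = tmp_path / "m.maf"
        maf.write_text(header + "T1\tp1\tMissense_Mutation\tSNP\t7\tA\tC\n")
        variants, _ = read_maf(maf)
        assert variants == [_mk(7, "A", "C", VariantClass.SNV)]


class TestClassifyFrameshift:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("", "AA", FrameshiftClass.TYPE1),  # +2 nt
            ("", "A", FrameshiftClass.TYPE2),  # +1 nt
            ("ACG", "", FrameshiftClass.IN_FRAME),  # -3 nt
            ("A", "", FrameshiftClass.TYPE1),  # -1 nt reads the same frame as +2
            ("AC", "", FrameshiftClass.TYPE2),
            ("A", "G", FrameshiftClass.IN_FRAME),  # SNV
        ],
    )
    def test_examples(self, ref, alt, expected):
        vclass = (
            VariantClass.SNV if ref and alt and len(ref) == len(alt) == 1
            else VariantClass.INSERTION if not ref
            else VariantClass.DELETION
        )
        assert classify_frameshift(_mk(5, ref, alt, vclass)) == expected

    def test_law_on_random_indels(self, rng):
        # class depends only on allele lengths: (len(alt)-len(ref)) mod 3
        mapping = {0: FrameshiftClass.IN_FRAME, 1: FrameshiftClass.TYPE2,
                   2: FrameshiftClass.TYPE1}
        for _ in range(1000):
            nref = int(rng.integers(0, 7))
            nalt = int(rng.integers(0, 7))
            if nref == 0 and nalt == 0:
                continue
            ref = "".join(rng.choice(list("ACGT"), size=nref))
            alt = "".join(rng.choice(list("ACGT"), size=nalt))
            vclass = VariantClass.DELINS if ref and alt else (
                VariantClass.DELETION if ref else VariantClass.INSERTION)
            v = _mk(int(rng.integers(1, 500)), ref, alt, vclass)
            assert classify_frameshift(v) == mapping[(nalt - nref) % 3]

    def test_minus_one_deletion_frame_equals_plus_two_insertion(self, rng):
        # exhaustive frame comparison: downstream of the affected codon, a
        # 1-nt deletion and a 2-nt insertion at the same site read the same frame
        for _ in range(50):
            cds = "ATG" + "".join(rng.choice(list("ACGT"), size=60))
            t = Transcript("t", cds + "TAA", three_prime_flank="")
            pos = int(rng.integers(4, 30))
            del_seq, _ = apply_variant(t, _mk(pos, cds[pos - 1], "", VariantClass.DELETION, tid="t"))
            ins_seq, _ = apply_variant(t, _mk(pos, "", "GG", VariantClass.INSERTION, tid="t"))
            # alignment: deletion removes 1 base, insertion adds 2 after pos
            assert del_seq[pos:] == ins_seq[pos + 3 :]


class TestApplyVariant:
    def test_insertion_example(self):
        t = Transcript("t", "ATGGAATGA")
        seq, codon = apply_variant(t, _mk(3, "", "T", VariantClass.INSERTION, tid="t"))
        assert seq == "ATGTGAATGA" and codon == 2

    def test_deletion_example(self):
        t = Transcript("t", "ATGGAAGAATGA")
        seq, codon = apply_variant(t, _mk(4, "G", "", VariantClass.DELETION, tid="t"))
        assert seq == "ATGAAGAATGA" and codon == 2

    def test_ref_mismatch_names_locus(self):
        t = Transcript("t", "ATGGAATGA")
        with pytest.raises(ValueError, match="c.4"):
            apply_variant(t, _mk(4, "C", "", VariantClass.DELETION, tid="t"))

    def test_length_law_fuzz(self, rng):
        for _ in range(50):
            n_codons = int(rng.integers(4, 40))
            cds = "ATG" + "".join(rng.choice(list("ACGT"), size=3 * n_codons))
            flank = "".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 30))))
            t = Transcript("t", cds, three_prime_flank=flank)
            pos = int(rng.integers(1, len(cds)))
            if rng.random() < 0.5:
                alt = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
                v = _mk(pos, "", alt, VariantClass.INSERTION, tid="t")
            else:
                size = min(int(rng.integers(1, 4)), len(cds) - pos + 1)
                v = _mk(pos, cds[pos - 1 : pos - 1 + size], "", VariantClass.DELETION, tid="t")
            seq, _ = apply_variant(t, v)
            assert len(seq) == len(cds) + len(flank) + len(v.alt_allele) - len(v.ref_allele)
            # naive splice oracle
            if v.variant_class is VariantClass.INSERTION:
                assert seq == cds[:pos] + v.alt_allele + cds[pos:] + flank
            else:
                assert seq == cds[: pos - 1] + cds[pos - 1 + len(v.ref_allele):] + flank

    def test_apply_then_revert_restores_sequence(self):
        # SNV revert: swap ref/alt at the same position
        t = Transcript("t", "ATGGAAGAATGA", three_prime_flank="CC")
        mutated, _ = apply_variant(t, _mk(4, "G", "C", VariantClass.SNV, tid="t"))
        t_mut = Transcript("t", mutated[: len(t.cds)], three_prime_flank="CC")
        restored, _ = apply_variant(t_mut, _mk(4, "C", "G", VariantClass.SNV, tid="t"))
        assert restored == t.cds + "CC"
        # pure indel revert: delete a codon, re-insert it after the
        # preceding position (the insertion convention is "after cds_pos")
        mutated, _ = apply_variant(t, _mk(4, "GAA", "", VariantClass.DELETION, tid="t"))
        t_del = Transcript("t", mutated[: len(t.cds) - 3], three_prime_flank="CC")
        restored, _ = apply_variant(t_del, _mk(3, "", "GAA", VariantClass.INSERTION, tid="t"))
        assert restored == t.cds + "CC"


class TestVcfProjection:
    def _fixture(self, tmp_path, rng, strand="+"):
        contig = "".join(rng.choice(list("ACGT"), size=60))
        (tmp_path / "g.fa").write_text(f">chr1\n{contig}\n")
        lines = ["##gff-version 3"]
        if strand == "+":
            lines.append("chr1\tsrc\tCDS\t10\t39\t.\t+\t0\tID=c1;Parent=tx1")
        else:
            lines.append("chr1\tsrc\tCDS\t10\t39\t.\t-\t0\tID=c1;Parent=tx1")
        (tmp_path / "m.gff3").write_text("\n".join(lines) + "\n")
        from fsneo.sequence import load_transcripts

        tx = load_transcripts(tmp_path / "g.fa", gff3_path=tmp_path / "m.gff3")
        return contig, tx

    def _write_vcf(self, tmp_path, rows):
        body = "\n".join(rows)
        (tmp_path / "v.vcf").write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chr1,length=60>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n" + body + "\n"
        )
        return tmp_path / "v.vcf"

    def test_plus_strand_snv_identity_mapping(self, tmp_path, rng):
        contig, tx = self._fixture(tmp_path, rng, "+")
        g = 19  # CDS base 10
        ref = contig[g - 1]
        alt = "A" if ref != "A" else "C"
        vcf = self._write_vcf(tmp_path, [f"chr1\t{g}\t.\t{ref}\t{alt}\t.\tPASS\t."])
        variants, _ = read_vcf_projected(vcf, tx, tmp_path / "m.gff3", patient_id="p")
        assert variants[0].cds_pos == 10
        assert (variants[0].ref_allele, variants[0].alt_allele) == (ref, alt)

    def test_minus_strand_snv_reflected_and_complemented(self, tmp_path, rng):
        contig, tx = self._fixture(tmp_path, rng, "-")
        g = 19
        ref = contig[g - 1]
        alt = "A" if ref != "A" else "C"
        vcf = self._write_vcf(tmp_path, [f"chr1\t{g}\t.\t{ref}\t{alt}\t.\tPASS\t."])
        variants, _ = read_vcf_projected(vcf, tx, tmp_path / "m.gff3", patient_id="p")
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        v = variants[0]
        assert v.cds_pos == 39 - g + 1  # reflected within the 30-nt CDS
        assert v.ref_allele == comp[ref] and v.alt_allele == comp[alt]
        assert tx["tx1"].cds[v.cds_pos - 1] == v.ref_allele

    def test_anchored_deletion_normalized(self, tmp_path, rng):
        contig, tx = self._fixture(tmp_path, rng, "+")
        g = 19
        ref2 = contig[g - 1 : g + 1]
        vcf = self._write_vcf(tmp_path, [f"chr1\t{g}\t.\t{ref2}\t{ref2[0]}\t.\tPASS\t."])
        variants, _ = read_vcf_projected(vcf, tx, tmp_path / "m.gff3", patient_id="p")
        v = variants[0]
        assert v.variant_class is VariantClass.DELETION
        assert v.cds_pos == 11 and v.ref_allele == ref2[1] and v.alt_allele == ""

    def test_unknown_contig_skipped_with_reason(self, tmp_path, rng):
        _, tx = self._fixture(tmp_path, rng, "+")
        vcf = self._write_vcf(tmp_path, ["chr1\t19\t.\tA\tC\t.\tPASS\t."])
        (tmp_path / "v2.vcf").write_text(
            (tmp_path / "v.vcf").read_text().replace("chr1\t19", "chr9\t19")
        )
        variants, report = read_vcf_projected(
            tmp_path / "v2.vcf", tx, tmp_path / "m.gff3", patient_id="p"
        )
        assert variants == [] or all(v.transcript_id != "tx1" for v in variants)
        assert "contig_not_in_gff3" in set(report["reason"])

    def test_maf_and_vcf_encode_same_variant(self, tmp_path, rng):
        # the same SNV written both ways yields identical CodingVariants
        contig, tx = self._fixture(tmp_path, rng, "+")
        g = 19
        ref = contig[g - 1]
        alt = "A" if ref != "A" else "C"
        vcf = self._write_vcf(tmp_path, [f"chr1\t{g}\t.\t{ref}\t{alt}\t.\tPASS\t."])
        from_vcf, _ = read_vcf_projected(vcf, tx, tmp_path / "m.gff3", patient_id="p1")
        maf = tmp_path / "m.maf"
        maf.write_text(
            MAF_HEADER
            + f"g\ttx1\tp1\tMissense_Mutation\tSNP\tc.10{ref}>{alt}\t{ref}\t{alt}\n"
        )
        from_maf, _ = read_maf(maf)
        assert from_vcf == from_maf
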