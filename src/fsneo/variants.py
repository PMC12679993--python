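"""Somatic coding variants: MAF/VCF ingestion, application, frameshift typing.

A variant lives in 1-based CDS coordinates.  For insertions ``cds_pos`` is
the position AFTER which the alternate sequence is inserted (HGVS
``c.N_N+1ins``, MAF Start=End=N); for deletions, SNVs and delins it is the
first altered position.

Frameshift nomenclature: a net coding-length change congruent to 2 (mod 3)
is a *type 1* frameshift (e.g. a +2-nt insertion or a −1-nt deletion); a
change congruent to 1 (mod 3) is *type 2*.  The two types put downstream
translation into the two possible non-native reading frames.
"""

from __future__ import annotations

import enum
import math
import re
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .sequence import Transcript

logger = logging.getLogger(__name__)


class VariantClass(str, enum.Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"
    DELINS = "delins"


class FrameshiftClass(str, enum.Enum):
    IN_FRAME = "in_frame"
    TYPE1 = "type1"  # net length change ≡ 2 (mod 3), e.g. +2 nt
    TYPE2 = "type2"  # net length change ≡ 1 (mod 3), e.g. +1 nt


@dataclass(frozen=True)
class CodingVariant:
    """One somatic variant in CDS coordinates with patient attribution."""

    patient_id: str
    transcript_id: str
    cds_pos: int
    ref_allele: str
    alt_allele: str
    variant_class: VariantClass

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.cds_pos < 1:
            raise ValueError(f"cds_pos must be positive, got {self.cds_pos}")
        if not self.ref_allele and not self.alt_allele:
            raise ValueError("ref and alt alleles cannot both be empty")

    @property
    def net_length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)


def classify_frameshift(v: CodingVariant) -> FrameshiftClass:
    """Frameshift type from allele lengths alone.

    shift = (len(alt) − len(ref)) mod 3 → 0: in frame, 1: type 2, 2: type 1.
    """
    shift = v.net_length_change % 3
    if shift == 0:
        return FrameshiftClass.IN_FRAME
    return FrameshiftClass.TYPE2 if shift == 1 else FrameshiftClass.TYPE1


def _refs_compatible(observed: str, expected: str) -> bool:
    # 'N' acts as a wildcard on either side (MAF rows without an explicit
    # deleted sequence are carried as N-placeholders).
    if len(observed) != len(expected):
        return False
    return all(o == e or o == "N" or e == "N" for o, e in zip(observed, expected))


def apply_variant(t: Transcript, v: CodingVariant) -> tuple[str, int]:
    """Apply ``v`` to ``t`` and return (mutated sequence + 3' flank, first affected codon).

    The first affected codon index (1-based, in the mutated sequence's
    frame anchored at the CDS start) is ``ceil(p*/3)`` with ``p* = cds_pos+1``
    for insertions and ``p* = cds_pos`` otherwise.  A reference-allele
    mismatch raises — it almost always means a coordinate-convention bug
    upstream, so the message names transcript, position and both alleles.
    """
    cds = t.cds
    if v.variant_class is VariantClass.INSERTION:
        if v.cds_pos > len(cds):
            raise ValueError(
                f"{t.transcript_id}: insertion after position {v.cds_pos} "
                f"outside CDS of length {len(cds)}"
            )
        mutated = cds[: v.cds_pos] + v.alt_allele + cds[v.cds_pos :]
        p_star = v.cds_pos + 1
    else:
        end = v.cds_pos + len(v.ref_allele) - 1
        if end > len(cds):
            raise ValueError(
                f"{t.transcript_id}: variant span {v.cds_pos}-{end} outside "
                f"CDS of length {len(cds)}"
            )
        observed = cds[v.cds_pos - 1 : end]
        if not _refs_compatible(observed, v.ref_allele):
            raise ValueError(
                f"{t.transcript_id}: reference mismatch at c.{v.cds_pos}: "
                f"expected {v.ref_allele!r}, CDS has {observed!r}"
            )
        mutated = cds[: v.cds_pos - 1] + v.alt_allele + cds[end:]
        p_star = v.cds_pos
    first_codon = math.ceil(p_star / 3)
    return mutated + t.three_prime_flank, first_codon


# --- HGVS c. parsing -------------------------------------------------------

_HGVS_PATTERNS = [
    ("snv", re.compile(r"^c\.(\d+)([ACGTN])>([ACGTN])$")),
    ("delins", re.compile(r"^c\.(\d+)(?:_(\d+))?delins([ACGTN]+)$")),
    ("del", re.compile(r"^c\.(\d+)(?:_(\d+))?del([ACGTN]*)$")),
    ("ins", re.compile(r"^c\.(\d+)(?:_(\d+))?ins([ACGTN]+)$")),
    ("dup", re.compile(r"^c\.(\d+)(?:_(\d+))?dup([ACGTN]*)$")),
]


def parse_hgvs_c(hgvs: str) -> tuple[int, str, str, VariantClass] | None:
    """Parse a coding-DNA HGVS string into (cds_pos, ref, alt, class).

    Supported forms: c.NX>Y, c.NdelX / c.N_Mdel[SEQ], c.N_N+1insSEQ,
    c.N[_M]delinsSEQ, c.N[_M]dup[SEQ].  UTR/intronic positions (``c.-``,
    ``c.*``, offsets with ``+``/``-``) and anything else return None.
    """
    hgvs = hgvs.strip()
    for kind, pat in _HGVS_PATTERNS:
        m = pat.match(hgvs)
        if not m:
            continue
        if kind == "snv":
            pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
            return pos, ref, alt, VariantClass.SNV
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        seq = m.group(3) or ""
        if kind == "del":
            ref = seq if seq else "N" * (end - start + 1)
            if len(ref) != end - start + 1:
                return None
            return start, ref, "", VariantClass.DELETION
        if kind == "ins":
            # c.N_N+1insSEQ inserts after N
            return start, "", seq, VariantClass.INSERTION
        if kind == "delins":
            ref = "N" * (end - start + 1)
            return start, ref, seq, VariantClass.DELINS
        if kind == "dup":
            dup = seq if seq else "N" * (end - start + 1)
            if len(dup) != end - start + 1:
                return None
            # duplication == insertion of the duplicated run after its end
            return end, "", dup, VariantClass.INSERTION
    return None


MAF_BASE_COLUMNS = ["Tumor_Sample_Barcode", "Variant_Classification", "Variant_Type"]


def read_maf(maf_path: str | Path) -> tuple[list[CodingVariant], pd.DataFrame]:
    """Read a TCGA-dialect MAF into CodingVariants.

    Requires ``Tumor_Sample_Barcode``, ``Variant_Classification``,
    ``Variant_Type`` and either (``Transcript_ID`` + ``HGVSc``) or
    (``Transcript_ID`` + ``CDS_position`` + ``Reference_Allele`` +
    ``Tumor_Seq_Allele2``).  Rows without a parsable coding annotation are
    skipped and tallied in the returned parse report (row_index, reason).
    """
    maf = pd.read_csv(maf_path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in MAF_BASE_COLUMNS + ["Transcript_ID"] if c not in maf.columns]
    has_hgvs = "HGVSc" in maf.columns
    has_coords = {"CDS_position", "Reference_Allele", "Tumor_Seq_Allele2"}.issubset(
        maf.columns
    )
    if missing or not (has_hgvs or has_coords):
        needed = missing + ([] if (has_hgvs or has_coords) else ["HGVSc or CDS_position+alleles"])
        raise ValueError(f"MAF is missing required columns: {needed}")

    variants: list[CodingVariant] = []
    skipped: list[tuple[int, str]] = []
    for idx, row in maf.iterrows():
        parsed = None
        if has_hgvs and row.get("HGVSc", ""):
            parsed = parse_hgvs_c(row["HGVSc"])
        if parsed is None and has_coords and row.get("CDS_position", ""):
            parsed = _parse_maf_coords(row)
        if parsed is None:
            skipped.append((int(idx), "no_coding_annotation"))
            continue
        pos, ref, alt, vclass = parsed
        try:
            variants.append(
                CodingVariant(
                    patient_id=row["Tumor_Sample_Barcode"],
                    transcript_id=row["Transcript_ID"],
                    cds_pos=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    variant_class=vclass,
                )
            )
        except ValueError as exc:
            logger.warning("MAF row %d malformed: %s", idx, exc)
            skipped.append((int(idx), "malformed"))
    report = pd.DataFrame(skipped, columns=["row_index", "reason"])
    return variants, report


def _parse_maf_coords(row: pd.Series) -> tuple[int, str, str, VariantClass] | None:
    try:
        pos = int(str(row["CDS_position"]).split("/")[0])
    except ValueError:
        return None
    ref = row["Reference_Allele"].replace("-", "")
    alt = row["Tumor_Seq_Allele2"].replace("-", "")
    if not ref and not alt:
        return None
    if not ref:
        vclass = VariantClass.INSERTION
    elif not alt:
        vclass = VariantClass.DELETION
    elif len(ref) == 1 and len(alt) == 1:
        vclass = VariantClass.SNV
    else:
        vclass = VariantClass.DELINS
    return pos, ref, alt, vclass


# --- VCF projection --------------------------------------------------------


def _cds_intervals(gff3_path: str | Path) -> dict[str, list]:
    """Per-transcript CDS features ordered 5'->3' along the transcript."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    groups: dict[str, list] = {}
    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent") or feat.attributes.get("transcript_id")
        if parents:
            groups.setdefault(parents[0], []).append(feat)
    for tid, feats in groups.items():
        feats.sort(key=lambda f: f.start, reverse=(feats[0].strand == "-"))
    return groups


def _genomic_to_cds(feats: list, gpos: int) -> int | None:
    """Map a genomic position to a 1-based CDS coordinate, or None if outside."""
    offset = 0
    for f in feats:
        if f.start <= gpos <= f.end:
            if f.strand == "-":
                return offset + (f.end - gpos + 1)
            return offset + (gpos - f.start + 1)
        offset += f.end - f.start + 1
    return None


def read_vcf_projected(
    vcf_path: str | Path,
    transcripts: dict[str, Transcript],
    gff3_path: str | Path,
    patient_id: str | None = None,
) -> tuple[list[CodingVariant], pd.DataFrame]:
    """Project VCF records onto transcript CDS coordinates.

    Anchored alleles are normalized by stripping the shared leading base.
    Minus-strand transcripts get reverse-complemented alleles and reflected
    positions.  Records not fully inside a CDS are skipped with a reason
    code.  The sample name is used as patient_id unless overridden.
    """
    from cyvcf2 import VCF

    groups = _cds_intervals(gff3_path)
    vcf = VCF(str(vcf_path))
    default_patient = patient_id or (vcf.samples[0] if vcf.samples else "unknown")
    variants: list[CodingVariant] = []
    skipped: list[tuple[str, str]] = []

    for rec in vcf:
        if not rec.ALT:
            skipped.append((f"{rec.CHROM}:{rec.POS}", "no_alt"))
            continue
        ref, alt, pos = rec.REF.upper(), str(rec.ALT[0]).upper(), rec.POS
        # strip shared leading anchor base (VCF indel convention)
        while ref and alt and ref[0] == alt[0]:
            ref, alt, pos = ref[1:], alt[1:], pos + 1
        hit = False
        for tid, feats in groups.items():
            if feats[0].seqid != rec.CHROM or tid not in transcripts:
                continue
            projected = _project_alleles(feats, pos, ref, alt)
            if projected is None:
                continue
            cds_pos, p_ref, p_alt, vclass = projected
            variants.append(
                CodingVariant(
                    patient_id=default_patient,
                    transcript_id=tid,
                    cds_pos=cds_pos,
                    ref_allele=p_ref,
                    alt_allele=p_alt,
                    variant_class=vclass,
                )
            )
            hit = True
        if not hit:
            known_contigs = {f[0].seqid for f in groups.values()}
            reason = "contig_not_in_gff3" if rec.CHROM not in known_contigs else "outside_cds"
            if reason == "contig_not_in_gff3":
                logger.warning("VCF contig %s absent from GFF3", rec.CHROM)
            skipped.append((f"{rec.CHROM}:{rec.POS}", reason))
    report = pd.DataFrame(skipped, columns=["record", "reason"])
    return variants, report


def _project_alleles(
    feats: list, gpos: int, ref: str, alt: str
) -> tuple[int, str, str, VariantClass] | None:
    minus = feats[0].strand == "-"
    if ref:  # deletion / SNV / delins: whole ref span must lie inside the CDS
        start_c = _genomic_to_cds(feats, gpos)
        end_c = _genomic_to_cds(feats, gpos + len(ref) - 1)
        if start_c is None or end_c is None:
            return None
        cds_pos = min(start_c, end_c)
        if abs(end_c - start_c) != len(ref) - 1:
            return None  # span crosses an intron; not representable in CDS space
        p_ref = str(Seq(ref).reverse_complement()) if minus else ref
        p_alt = str(Seq(alt).reverse_complement()) if minus else alt
        if not p_alt:
            vclass = VariantClass.DELETION
        elif len(p_ref) == 1 and len(p_alt) == 1:
            vclass = VariantClass.SNV
        else:
            vclass = VariantClass.DELINS
        return cds_pos, p_ref, p_alt, vclass
    # pure insertion between gpos-1 and gpos after anchor stripping:
    # anchor the CDS position to the base 5' of the insertion point
    left_g = gpos - 1
    left_c = _genomic_to_cds(feats, left_g if not minus else gpos)
    if left_c is None:
        return None
    p_alt = str(Seq(alt).reverse_complement()) if minus else alt
    return left_c, "", p_alt, VariantClass.INSERTION
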