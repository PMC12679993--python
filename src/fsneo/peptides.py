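"""Functional-peptide extraction.

A *functional peptide* (FP) is the amino-acid run translated in the shifted
reading frame from a frameshift mutation site to the aberrantly generated
stop codon.  Its length drives the chance that a single chain carries both
MHC class I and class II epitopes, which is what makes long FPs
immunologically interesting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .sequence import Transcript, translate
from .variants import CodingVariant, FrameshiftClass, apply_variant, classify_frameshift

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FunctionalPeptide:
    """Shifted-frame peptide from the mutation site to the premature stop.

    ``stop_found`` is False for stop-lost read-through: the shifted frame
    exhausted the CDS plus 3' flank without hitting a stop codon.  Such
    peptides are retained (with their observed length) rather than dropped,
    so that length statistics never silently lose the longest candidates.
    """

    patient_id: str
    transcript_id: str
    variant: CodingVariant
    fs_class: FrameshiftClass
    sequence: str
    stop_found: bool
    start_codon_index: int

    @property
    def length_aa(self) -> int:
        return len(self.sequence)


def extract_functional_peptide(
    t: Transcript,
    v: CodingVariant,
    start_at_first_changed_aa: bool = False,
) -> FunctionalPeptide | None:
    """Extract the functional peptide for one frameshift variant.

    Returns None for in-frame variants (including SNVs).  Translation starts
    at the first codon containing altered nucleotides — anchored to the
    mutated CDS start, so the shifted frame is exactly what a ribosome
    initiating at the native AUG would read — and runs to the first stop
    codon or the end of CDS+flank.  If the first affected codon is itself a
    stop, the peptide is empty (length 0).

    With ``start_at_first_changed_aa`` the peptide is instead trimmed to
    begin at the first residue that differs from the native protein, which
    matters when the first affected codon still encodes the wild-type
    residue.
    """
    fs_class = classify_frameshift(v)
    if fs_class is FrameshiftClass.IN_FRAME:
        return None
    mutated, first_codon = apply_variant(t, v)
    tail = mutated[(first_codon - 1) * 3 :]
    if not tail:
        sequence, stop_found = "", False
    else:
        sequence, stop_found = translate(tail)
    start_codon = first_codon
    if start_at_first_changed_aa and sequence:
        native = t.protein()
        offset = 0
        for i, aa in enumerate(sequence):
            native_idx = first_codon - 1 + i
            if native_idx >= len(native) or native[native_idx] != aa:
                break
            offset = i + 1
        sequence = sequence[offset:]
        start_codon = first_codon + offset
    return FunctionalPeptide(
        patient_id=v.patient_id,
        transcript_id=v.transcript_id,
        variant=v,
        fs_class=fs_class,
        sequence=sequence,
        stop_found=stop_found,
        start_codon_index=start_codon,
    )


def extract_all(
    transcripts: dict[str, Transcript],
    variants: list[CodingVariant],
    start_at_first_changed_aa: bool = False,
) -> tuple[list[FunctionalPeptide], pd.DataFrame]:
    """Extract FPs for every frameshift variant; skip the rest with reasons.

    Output order is deterministic: (patient_id, transcript_id, cds_pos).
    The skip report tallies in-frame variants, SNVs and unknown transcripts.
    """
    peptides: list[FunctionalPeptide] = []
    skipped: list[dict] = []
    for v in sorted(variants, key=lambda v: (v.patient_id, v.transcript_id, v.cds_pos)):
        t = transcripts.get(v.transcript_id)
        if t is None:
            logger.warning("variant references unknown transcript %s", v.transcript_id)
            skipped.append(_skip(v, "unknown_transcript"))
            continue
        if classify_frameshift(v) is FrameshiftClass.IN_FRAME:
            reason = "snv" if v.variant_class.value == "SNV" else "in_frame_indel"
            skipped.append(_skip(v, reason))
            continue
        try:
            fp = extract_functional_peptide(t, v, start_at_first_changed_aa)
        except ValueError as exc:
            logger.warning("skipping variant: %s", exc)
            skipped.append(_skip(v, "ref_mismatch"))
            continue
        assert fp is not None
        peptides.append(fp)
    report = pd.DataFrame(
        skipped, columns=["patient_id", "transcript_id", "cds_pos", "reason"]
    )
    return peptides, report


def _skip(v: CodingVariant, reason: str) -> dict:
    return {
        "patient_id": v.patient_id,
        "transcript_id": v.transcript_id,
        "cds_pos": v.cds_pos,
        "reason": reason,
    }


def peptides_to_frame(
    peptides: list[FunctionalPeptide], transcripts: dict[str, Transcript] | None = None
) -> pd.DataFrame:
    """Tabulate FPs for TSV export."""
    rows = []
    for fp in peptides:
        gene = ""
        if transcripts and fp.transcript_id in transcripts:
            gene = transcripts[fp.transcript_id].gene_symbol
        rows.append(
            {
                "patient_id": fp.patient_id,
                "transcript_id": fp.transcript_id,
                "gene": gene,
                "cds_pos": fp.variant.cds_pos,
                "ref": fp.variant.ref_allele,
                "alt": fp.variant.alt_allele,
                "fs_type": fp.fs_class.value,
                "fp_length_aa": fp.length_aa,
                "stop_found": fp.stop_found,
                "fp_sequence": fp.sequence,
            }
        )
    columns = [
        "patient_id", "transcript_id", "gene", "cds_pos", "ref", "alt",
        "fs_type", "fp_length_aa", "stop_found", "fp_sequence",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_peptides_fasta(peptides: list[FunctionalPeptide], path: str | Path) -> None:
    """FASTA export (IDs patient|transcript|c.pos) for external predictors."""
    with open(path, "w") as fh:
        for fp in peptides:
            if not fp.sequence:
                continue
            fh.write(f">{fp.patient_id}|{fp.transcript_id}|c.{fp.variant.cds_pos}\n")
            fh.write(fp.sequence + "\n")
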