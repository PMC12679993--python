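"""Transcript container, standard-format readers, and codon translation.

Coding sequences (CDS) are held sense-strand, 5'->3', starting at the
annotated start codon.  Coordinates everywhere in this package are 1-based
on the CDS (position 1 = first base of the start codon), matching HGVS
"c." positions as annotated in MAF files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

#: The three termination codons of the standard genetic code.
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def _build_codon_table() -> dict[str, str]:
    table = dict(_BioCodonTable.unambiguous_dna_by_id[1].forward_table)
    assert len(table) == 61 and not (set(table) & STOP_CODONS)
    return table


#: Standard genetic code: 61 sense codons -> single-letter amino acids.
CODON_TABLE: dict[str, str] = _build_codon_table()


def translate(nt: str, table: dict[str, str] | None = None) -> tuple[str, bool]:
    """Translate ``nt`` in frame 0 until the first stop codon.

    Codons are read 5'->3'.  The stop codon is not included in the returned
    amino-acid string; a trailing incomplete codon (<3 nt) is ignored.  Any
    codon containing ``N`` translates to ``'X'`` and never terminates —
    ambiguity must not fabricate a premature stop.

    Returns
    -------
    (aa, stop_found)
        ``aa`` is the translated peptide, ``stop_found`` is True when a stop
        codon terminated translation (False when the sequence ran out).
    """
    if not nt:
        raise ValueError("cannot translate an empty sequence")
    table = table if table is not None else CODON_TABLE
    nt = nt.upper()
    aa: list[str] = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if codon in STOP_CODONS:
            return "".join(aa), True
        if "N" in codon:
            aa.append("X")
        else:
            aa.append(table[codon])
    return "".join(aa), False


@dataclass
class Transcript:
    """One spliced coding sequence with optional 3' flank and expression.

    ``three_prime_flank`` carries downstream (3'UTR) sequence used when a
    frameshift reads through the native stop codon.  ``expression_fpkm`` is
    FPKM (fragments per kb of transcript per million mapped reads) when an
    expression table was joined, else ``None``.
    """

    transcript_id: str
    cds: str
    gene_symbol: str = ""
    three_prime_flank: str = ""
    expression_fpkm: float | None = None

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()
        self.three_prime_flank = self.three_prime_flank.upper()
        if len(self.cds) < 3:
            raise ValueError(
                f"{self.transcript_id}: CDS shorter than one codon ({len(self.cds)} nt)"
            )
        if len(self.cds) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {len(self.cds)} not divisible by 3"
            )
        bad = set(self.cds) - VALID_BASES
        if bad:
            raise ValueError(f"{self.transcript_id}: invalid bases {sorted(bad)}")
        if self.expression_fpkm is not None and self.expression_fpkm < 0:
            raise ValueError(f"{self.transcript_id}: negative FPKM")

    @property
    def full_sequence(self) -> str:
        """CDS plus 3' flank — the substrate for stop-lost read-through."""
        return self.cds + self.three_prime_flank

    def protein(self) -> str:
        """Native-frame protein (stop excluded)."""
        return translate(self.cds)[0]


def _read_expression(expression_path: str | Path) -> dict[str, float]:
    tab = pd.read_csv(expression_path, sep="\t")
    required = {"transcript_id", "fpkm"}
    if not required.issubset(tab.columns):
        raise ValueError(
            f"expression table must have columns {sorted(required)}, got {list(tab.columns)}"
        )
    return dict(zip(tab["transcript_id"].astype(str), tab["fpkm"].astype(float)))


def _assemble_from_gff3(
    gff3_path: str | Path, contigs: dict[str, str]
) -> Iterable[tuple[str, str, str]]:
    """Yield (transcript_id, gene_symbol, cds) assembled from GFF3 CDS features.

    CDS features are grouped by their Parent (falling back to a
    ``transcript_id`` attribute), ordered 5'->3' along the transcript, and
    minus-strand features are reverse-complemented.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    groups: dict[str, list] = {}
    genes: dict[str, str] = {}
    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent") or feat.attributes.get("transcript_id")
        if not parents:
            raise ValueError(f"CDS feature at {feat.seqid}:{feat.start} has no Parent")
        tid = parents[0]
        groups.setdefault(tid, []).append(feat)
        gene = feat.attributes.get("gene") or feat.attributes.get("gene_id")
        if gene:
            genes[tid] = gene[0]
    for tid, feats in groups.items():
        strand = feats[0].strand
        # transcript 5'->3': genomic ascending on +, descending on -
        feats.sort(key=lambda f: f.start, reverse=(strand == "-"))
        parts = []
        for f in feats:
            if f.seqid not in contigs:
                raise ValueError(
                    f"CDS feature for {tid} references missing sequence {f.seqid!r}"
                )
            seg = contigs[f.seqid][f.start - 1 : f.end]  # GFF3 1-based inclusive
            if strand == "-":
                seg = str(Seq(seg).reverse_complement())
            parts.append(seg)
        yield tid, genes.get(tid, ""), "".join(parts)


def load_transcripts(
    fasta_path: str | Path,
    gff3_path: str | Path | None = None,
    expression_path: str | Path | None = None,
    flank_map: dict[str, str] | None = None,
) -> dict[str, Transcript]:
    """Load transcripts from FASTA (optionally assembling CDS from GFF3).

    Without a GFF3, each FASTA record is taken as an already-spliced
    sense-strand CDS.  With a GFF3, the FASTA holds contigs and each
    transcript's CDS is stitched from its CDS features (minus-strand
    features reverse-complemented).  Expression values are joined by
    ``transcript_id``.  Records whose length is not divisible by 3 are
    skipped with a warning; duplicate IDs are rejected.

    FASTA description lines may carry ``gene=SYMBOL`` and ``flank=SEQ``
    key=value tags (the flank tag is how the synthetic generator round-trips
    3' flanks through plain FASTA).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    expression = _read_expression(expression_path) if expression_path else {}
    flank_map = flank_map or {}
    transcripts: dict[str, Transcript] = {}

    if gff3_path is not None:
        contigs = {r.id: str(r.seq).upper() for r in records}
        entries = _assemble_from_gff3(gff3_path, contigs)
        for tid, gene, cds in entries:
            _add_transcript(transcripts, tid, gene, cds, flank_map.get(tid, ""), expression)
    else:
        for rec in records:
            gene, flank = _parse_description(rec.description)
            flank = flank_map.get(rec.id, flank)
            _add_transcript(transcripts, rec.id, gene, str(rec.seq), flank, expression)
    return transcripts


def _parse_description(description: str) -> tuple[str, str]:
    gene, flank = "", ""
    for token in description.split()[1:]:
        if token.startswith("gene="):
            gene = token[5:]
        elif token.startswith("flank="):
            flank = token[6:]
    return gene, flank


def _add_transcript(
    transcripts: dict[str, Transcript],
    tid: str,
    gene: str,
    cds: str,
    flank: str,
    expression: dict[str, float],
) -> None:
    if tid in transcripts:
        raise ValueError(f"duplicate transcript_id {tid!r}")
    try:
        t = Transcript(
            transcript_id=tid,
            cds=cds,
            gene_symbol=gene,
            three_prime_flank=flank,
            expression_fpkm=expression.get(tid),
        )
    except ValueError as exc:
        logger.warning("skipping %s: %s", tid, exc)
        warnings.warn(f"skipping transcript {tid}: {exc}", stacklevel=2)
        return
    transcripts[tid] = t
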