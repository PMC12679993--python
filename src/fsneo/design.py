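"""In-silico frameshift knock-in design.

For every candidate insertion site along a CDS, simulate a 2-nt insertion
(type 1 frameshift, FS1) and a 1-nt insertion (type 2 frameshift, FS2),
extract both functional peptides, and rank sites by the absolute length
difference |len(FS1) − len(FS2)|.  A large difference lets the two knock-in
lines act as a matched pair: one long, potentially antigenic peptide versus
one short control from the same locus.  Target transcripts are restricted
to the most highly expressed fraction (top 1% by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peptides import extract_functional_peptide
from .sequence import Transcript
from .variants import CodingVariant, VariantClass


@dataclass(frozen=True)
class DesignCandidate:
    """One insertion site with both frameshift peptide lengths."""

    transcript_id: str
    site: int  # insertion after this 1-based CDS position
    len_fs1: int  # AA from the 2-nt insertion
    len_fs2: int  # AA from the 1-nt insertion
    fs1_stop_found: bool
    fs2_stop_found: bool
    expression_percentile: float = float("nan")

    @property
    def diff(self) -> int:
        return abs(self.len_fs1 - self.len_fs2)


def _insertion(t: Transcript, site: int, bases: str) -> CodingVariant:
    return CodingVariant(
        patient_id="design",
        transcript_id=t.transcript_id,
        cds_pos=site,
        ref_allele="",
        alt_allele=bases,
        variant_class=VariantClass.INSERTION,
    )


def scan_sites(
    t: Transcript,
    insert_base: str = "A",
    site_range: tuple[int, int] | None = None,
    codon_boundaries_only: bool = False,
) -> list[DesignCandidate]:
    """Evaluate every insertion site and rank by |FS1 − FS2| length difference.

    FS1 inserts ``insert_base*2`` after the site, FS2 inserts
    ``insert_base*1``.  The default scan covers every CDS position (the
    last position is excluded so the insertion stays upstream of sequence
    end); ``codon_boundaries_only`` restricts to positions that are
    multiples of 3.  Results are ordered by diff descending, then site
    ascending — a pure function of the CDS+flank sequence.
    """
    if len(insert_base) != 1 or insert_base not in "ACGT":
        raise ValueError(f"insert_base must be one of A/C/G/T, got {insert_base!r}")
    lo, hi = site_range if site_range else (1, len(t.cds) - 1)
    lo, hi = max(1, lo), min(len(t.cds) - 1, hi)
    candidates: list[DesignCandidate] = []
    for site in range(lo, hi + 1):
        if codon_boundaries_only and site % 3 != 0:
            continue
        fp1 = extract_functional_peptide(t, _insertion(t, site, insert_base * 2))
        fp2 = extract_functional_peptide(t, _insertion(t, site, insert_base))
        assert fp1 is not None and fp2 is not None
        candidates.append(
            DesignCandidate(
                transcript_id=t.transcript_id,
                site=site,
                len_fs1=fp1.length_aa,
                len_fs2=fp2.length_aa,
                fs1_stop_found=fp1.stop_found,
                fs2_stop_found=fp2.stop_found,
            )
        )
    candidates.sort(key=lambda c: (-c.diff, c.site))
    return candidates


def select_targets(
    candidates: list[DesignCandidate],
    transcripts: dict[str, Transcript],
    expression_quantile: float = 0.99,
) -> list[DesignCandidate]:
    """Keep candidates on highly expressed transcripts, re-ranked by diff.

    The cut is the given quantile (default 0.99 = top 1%) of the FPKM
    distribution over all supplied transcripts with expression values;
    candidates whose transcript sits at or above the cut survive.
    """
    fpkms = {
        tid: t.expression_fpkm
        for tid, t in transcripts.items()
        if t.expression_fpkm is not None
    }
    if not fpkms:
        raise ValueError("no transcript has an expression value; cannot filter")
    values = np.array(list(fpkms.values()), dtype=float)
    cut = float(np.quantile(values, expression_quantile)) if expression_quantile > 0 else -np.inf
    out: list[DesignCandidate] = []
    for c in candidates:
        fpkm = fpkms.get(c.transcript_id)
        if fpkm is None or fpkm < cut:
            continue
        pct = 100.0 * (values <= fpkm).mean()
        out.append(
            DesignCandidate(
                transcript_id=c.transcript_id,
                site=c.site,
                len_fs1=c.len_fs1,
                len_fs2=c.len_fs2,
                fs1_stop_found=c.fs1_stop_found,
                fs2_stop_found=c.fs2_stop_found,
                expression_percentile=pct,
            )
        )
    out.sort(key=lambda c: (-c.diff, c.transcript_id, c.site))
    return out


def candidates_to_frame(candidates: list[DesignCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": c.transcript_id,
                "site": c.site,
                "len_fs1": c.len_fs1,
                "len_fs2": c.len_fs2,
                "diff": c.diff,
                "fs1_stop_found": c.fs1_stop_found,
                "fs2_stop_found": c.fs2_stop_found,
                "expression_percentile": c.expression_percentile,
            }
            for c in candidates
        ]
    )
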