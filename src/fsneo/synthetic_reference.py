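"""Synthetic stand-in reference transcripts (clearly not real gene sequences).

This module fabricates coding sequences engineered so that a designated
single-base deletion produces a frameshift functional peptide of an exact
target length.  It exists to exercise the deletion → premature-stop
extraction path on a realistically sized transcript when no real reference
sequence is bundled: every sequence produced here is SYNTHETIC and shares
nothing with any real gene beyond length scale and the designed variant
geometry.
"""

from __future__ import annotations

import numpy as np

from .peptides import extract_functional_peptide
from .sequence import STOP_CODONS, Transcript
from .variants import CodingVariant, VariantClass


def synthetic_deletion_reference(
    cds_pos: int = 331,
    target_fp_length: int = 216,
    deleted_base: str = "G",
    cds_length: int = 1500,
    flank_length: int = 300,
    seed: int = 0,
    transcript_id: str = "SYNTH_DEL_REF",
) -> tuple[Transcript, CodingVariant]:
    """Build a synthetic CDS where deleting one base yields an exact FP length.

    The construction starts from uniform random sequence, pins
    ``deleted_base`` at ``cds_pos``, and then edits the post-deletion
    shifted frame so its first stop codon falls exactly
    ``target_fp_length`` codons after the first affected codon.  Returns
    the transcript and the single-base deletion variant; extraction on the
    pair is verified before returning.
    """
    if not 1 <= cds_pos <= cds_length:
        raise ValueError("cds_pos outside CDS")
    rng = np.random.default_rng(seed)
    cds = list("ATG" + "".join(rng.choice(list("ACGT"), size=cds_length - 3)))
    if cds_pos <= 3:
        raise ValueError("deletion inside the start codon is not supported")
    cds[cds_pos - 1] = deleted_base
    flank = "".join(rng.choice(list("ACGT"), size=flank_length))

    mutated = cds[: cds_pos - 1] + cds[cds_pos:] + list(flank)
    first_codon = (cds_pos + 2) // 3  # ceil(cds_pos / 3)
    needed = 3 * (first_codon + target_fp_length)
    if len(mutated) < needed:
        raise ValueError(
            f"target {target_fp_length} AA infeasible: capacity "
            f"{len(mutated) // 3 - first_codon} codons after the mutation site"
        )
    for j in range(first_codon, first_codon + target_fp_length):
        base0 = (j - 1) * 3
        if "".join(mutated[base0 : base0 + 3]) in STOP_CODONS:
            mutated[base0 + 1] = "C"  # any stop becomes a sense codon
    base0 = (first_codon + target_fp_length - 1) * 3
    mutated[base0 : base0 + 3] = "TAA"

    # undo the deletion to recover the wild-type CDS + flank
    restored = mutated[: cds_pos - 1] + [deleted_base] + mutated[cds_pos - 1 :]
    new_cds = "".join(restored[:cds_length])
    new_flank = "".join(restored[cds_length:])
    t = Transcript(
        transcript_id=transcript_id,
        cds=new_cds,
        gene_symbol="SYNTH",
        three_prime_flank=new_flank,
    )
    v = CodingVariant(
        patient_id="synthetic",
        transcript_id=transcript_id,
        cds_pos=cds_pos,
        ref_allele=deleted_base,
        alt_allele="",
        variant_class=VariantClass.DELETION,
    )
    fp = extract_functional_peptide(t, v)
    assert fp is not None and fp.length_aa == target_fp_length
    return t, v
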