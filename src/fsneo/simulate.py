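"""Synthetic transcriptome / somatic-cohort / survival generator.

Generates matched fixtures with the statistical structure the analysis
assumes: a transcriptome of coding sequences, per-patient somatic SNV and
InDel calls written as a TCGA-dialect MAF, and survival times whose hazard
depends on whether the patient's maximal functional-peptide length exceeds
the long-FP threshold.  Every output is a pure function of the config and
seed.

Two sequence models are offered for the frameshift-length distribution:

* ``uniform_sequence`` (default) — CDS interiors are i.i.d. uniform
  nucleotides, so each shifted-frame codon is an independent uniform
  triplet and the functional-peptide length is geometric with per-codon
  stop probability 3/64.  This is the model under which the analytic
  length law P(L >= n) = (61/64)^n holds exactly.
* ``implanted`` — frameshifts are knocked in with exact target lengths
  (see :func:`implant_frameshift`), giving ground-truth control over the
  long-FP share for survival power studies.

Note that a "clean" ORF without internal in-frame stop codons is *not*
neutral for shifted frames: conditioning frame 0 on the 61 sense codons
raises the shifted-frame per-codon stop probability to 192/61^2 ~ 0.0516,
measurably above 3/64 ~ 0.0469.  ``generate_transcriptome`` therefore
exposes ``clean_orf``; cohort generation under ``uniform_sequence`` uses
unconstrained interiors so the geometric law survives end to end.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .peptides import FunctionalPeptide, extract_functional_peptide
from .sequence import STOP_CODONS, Transcript
from .variants import CodingVariant, FrameshiftClass, VariantClass, classify_frameshift

BASES = np.array(list("ACGT"))

_SENSE_CODONS = sorted(
    {"".join(c) for c in __import__("itertools").product("ACGT", repeat=3)} - STOP_CODONS
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror a desk-scale version of a colorectal-cancer WES cohort:
    InDels make up 12% of somatic calls, mutation counts are
    negative-binomial across patients, expression is log-normal, and
    survival is exponential with the long-FP group's hazard scaled by
    ``hazard_ratio``.
    """

    seed: int = 0
    n_transcripts: int = 60
    cds_length_range: tuple[int, int] = (300, 1500)  # nt, rounded to codons
    flank_length: int = 300  # 3'UTR nt available for stop-lost read-through
    n_patients: int = 100
    mutations_mean: float = 20.0  # negative-binomial mean per patient
    mutations_dispersion: float = 5.0  # NB size parameter r
    indel_fraction: float = 0.12
    indel_length_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.55, 2: 0.30, 3: 0.15}
    )
    fp_length_model: str = "uniform_sequence"  # or "implanted"
    implant_long_fraction: float = 0.25  # implanted mode: share of patients given a long FP
    implant_long_range: tuple[int, int] = (130, 240)
    implant_short_range: tuple[int, int] = (5, 100)
    fp_threshold_aa: int = 120
    baseline_hazard: float = 1.0 / 40.0  # per month
    hazard_ratio: float = 0.5  # long-FP hazard relative to short-FP
    censoring_fraction: float = 0.30
    capture_mb: float = 38.0  # exome capture size for TMB per Mb

    def __post_init__(self) -> None:
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise ValueError("indel_fraction must be a probability")
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ValueError("censoring_fraction must be in [0, 1)")
        if self.fp_length_model not in ("uniform_sequence", "implanted"):
            raise ValueError(f"unknown fp_length_model {self.fp_length_model!r}")
        total = sum(self.indel_length_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("indel_length_probs must sum to 1")


# --- transcriptome ---------------------------------------------------------


def _random_cds(rng: np.random.Generator, n_codons: int, clean_orf: bool) -> str:
    if clean_orf:
        body = "".join(
            rng.choice(_SENSE_CODONS) for _ in range(n_codons - 2)
        )
    else:
        body = "".join(rng.choice(BASES, size=3 * (n_codons - 2)))
    stop = str(rng.choice(sorted(STOP_CODONS)))
    return "ATG" + body + stop


def generate_transcriptome(
    cfg: SimConfig, rng: np.random.Generator | None = None, clean_orf: bool = True
) -> dict[str, Transcript]:
    """Generate CDS + 3' flank + log-normal FPKM per transcript.

    With ``clean_orf`` (default) every CDS begins ATG, ends with a stop and
    has no internal in-frame stop; with ``clean_orf=False`` interiors are
    i.i.d. uniform nucleotides (internal stops possible), the model under
    which shifted-frame codons are unbiased uniform triplets.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    lo, hi = cfg.cds_length_range
    transcripts: dict[str, Transcript] = {}
    for i in range(cfg.n_transcripts):
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        n_codons = max(n_codons, 4)
        cds = _random_cds(rng, n_codons, clean_orf)
        flank = "".join(rng.choice(BASES, size=cfg.flank_length))
        fpkm = float(np.exp(rng.normal(1.0, 1.5)))
        tid = f"TX{i:04d}"
        transcripts[tid] = Transcript(
            transcript_id=tid,
            cds=cds,
            gene_symbol=f"GENE{i:04d}",
            three_prime_flank=flank,
            expression_fpkm=fpkm,
        )
    return transcripts


def write_transcriptome(transcripts: dict[str, Transcript], outdir: Path) -> tuple[Path, Path]:
    """Write FASTA (with gene=/flank= tags) and expression TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "transcripts.fa"
    with open(fasta, "w") as fh:
        for t in transcripts.values():
            tags = f" gene={t.gene_symbol}" if t.gene_symbol else ""
            if t.three_prime_flank:
                tags += f" flank={t.three_prime_flank}"
            fh.write(f">{t.transcript_id}{tags}\n{t.cds}\n")
    expr = outdir / "expression.tsv"
    rows = [
        {"transcript_id": t.transcript_id, "fpkm": t.expression_fpkm}
        for t in transcripts.values()
        if t.expression_fpkm is not None
    ]
    pd.DataFrame(rows).to_csv(expr, sep="\t", index=False, float_format="%.6f")
    return fasta, expr


# --- exact-length frameshift implantation ----------------------------------


def implant_frameshift(
    t: Transcript,
    target_fp_length: int,
    fs_type: FrameshiftClass,
    insert_base: str = "A",
) -> tuple[CodingVariant, Transcript]:
    """Edit ``t`` minimally so a knocked-in insertion yields an exact FP length.

    The insertion (``insert_base`` x2 for type 1, x1 for type 2) is placed
    after CDS position 4.  Downstream bases are edited only where the
    shifted frame would otherwise stop early (middle base flipped to C) or
    where the terminal stop must be written; the native frame is preserved
    wherever possible.  Extraction on the returned transcript/variant pair
    reproduces ``target_fp_length`` exactly — asserted before returning.
    """
    if fs_type is FrameshiftClass.IN_FRAME:
        raise ValueError("cannot implant an in-frame event")
    if target_fp_length < 0:
        raise ValueError("target length must be >= 0")
    ins = insert_base * (2 if fs_type is FrameshiftClass.TYPE1 else 1)
    site = 4
    if len(t.cds) < 6:
        raise ValueError(f"{t.transcript_id}: CDS too short to implant")
    mutated = list(t.cds[:site] + ins + t.cds[site:] + t.three_prime_flank)
    # capacity: shifted frame starts at codon 2, needs target sense codons + stop
    needed = 3 * (2 + target_fp_length)
    if len(mutated) < needed:
        raise ValueError(
            f"{t.transcript_id}: target {target_fp_length} AA infeasible "
            f"(capacity {len(mutated) // 3 - 2} codons)"
        )
    fixed = set(range(site, site + len(ins)))  # inserted bases define the variant

    def codon(j: int) -> str:  # 1-based codon index in the mutated sequence
        return "".join(mutated[(j - 1) * 3 : (j - 1) * 3 + 3])

    first_codon = 2  # ceil((site+1)/3) with site=4
    for j in range(first_codon, first_codon + target_fp_length):
        if codon(j) in STOP_CODONS:
            base0 = (j - 1) * 3
            # flipping the middle base to C turns any stop into a sense codon
            edit = base0 + 1 if base0 + 1 not in fixed else base0
            mutated[edit] = "C"
    stop_at = first_codon + target_fp_length
    base0 = (stop_at - 1) * 3
    for offset, want in enumerate("TAA"):
        idx = base0 + offset
        if idx in fixed:
            if mutated[idx] != want:
                raise ValueError(
                    f"{t.transcript_id}: cannot write stop codon over inserted bases"
                )
        else:
            mutated[idx] = want

    seq = "".join(mutated)
    new_cds = seq[:site] + seq[site + len(ins) : len(t.cds) + len(ins)]
    new_flank = seq[len(t.cds) + len(ins) :]
    edited = Transcript(
        transcript_id=t.transcript_id,
        cds=new_cds,
        gene_symbol=t.gene_symbol,
        three_prime_flank=new_flank,
        expression_fpkm=t.expression_fpkm,
    )
    variant = CodingVariant(
        patient_id="implant",
        transcript_id=t.transcript_id,
        cds_pos=site,
        ref_allele="",
        alt_allele=ins,
        variant_class=VariantClass.INSERTION,
    )
    fp = extract_functional_peptide(edited, variant)
    assert fp is not None and fp.length_aa == target_fp_length, (
        f"implant round-trip failed: {fp.length_aa if fp else None} != {target_fp_length}"
    )
    return variant, edited


# --- direct frameshift-length simulation (uniform-nucleotide model) --------


def simulate_fp_lengths(
    n: int,
    rng: np.random.Generator | int = 0,
    cds_codons: int = 40,
    flank_length: int = 900,
) -> list[int]:
    """Simulate ``n`` frameshift functional-peptide lengths end to end.

    Each replicate builds a transcript whose bases are i.i.d. uniform
    (ATG start; internal stops allowed — this is the raw-sequence model,
    not a curated ORF), applies a random 1- or 2-nt insertion or deletion
    at a random early position, and extracts the functional peptide through
    the standard pipeline.  Under this model the length is geometric with
    per-codon stop probability 3/64.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    lengths: list[int] = []
    cds_len = 3 * cds_codons
    for i in range(n):
        cds = "ATG" + "".join(rng.choice(BASES, size=cds_len - 3))
        flank = "".join(rng.choice(BASES, size=flank_length))
        t = Transcript(f"SIM{i}", cds=cds, three_prime_flank=flank)
        pos = int(rng.integers(4, cds_len // 2))
        size = int(rng.integers(1, 3))  # 1 or 2 nt
        if rng.random() < 0.5:
            v = CodingVariant(
                "sim", t.transcript_id, pos, "", "".join(rng.choice(BASES, size=size)),
                VariantClass.INSERTION,
            )
        else:
            v = CodingVariant(
                "sim", t.transcript_id, pos, cds[pos - 1 : pos - 1 + size], "",
                VariantClass.DELETION,
            )
        fp = extract_functional_peptide(t, v)
        assert fp is not None
        lengths.append(fp.length_aa)
    return lengths


# --- survival --------------------------------------------------------------


def simulate_survival(
    n: int,
    frac_long: float,
    rng: np.random.Generator | int,
    baseline_hazard: float = 1.0 / 40.0,
    hazard_ratio: float = 0.5,
    censoring_fraction: float = 0.30,
) -> pd.DataFrame:
    """Exponential survival with group-dependent hazard and independent censoring.

    Long-FP patients have hazard ``baseline_hazard * hazard_ratio``.
    Censoring times are exponential with a rate chosen so the expected
    censored share approximates ``censoring_fraction``.
    Returns columns: patient_id, group ("long"/"short"), time, event.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n_long = int(round(n * frac_long))
    groups = np.array(["long"] * n_long + ["short"] * (n - n_long))
    hazards = np.where(groups == "long", baseline_hazard * hazard_ratio, baseline_hazard)
    times = rng.exponential(1.0 / hazards)
    if censoring_fraction > 0:
        mean_h = float(hazards.mean())
        cens_rate = mean_h * censoring_fraction / (1.0 - censoring_fraction)
        cens = rng.exponential(1.0 / cens_rate, size=n)
        event = times <= cens
        obs = np.minimum(times, cens)
    else:
        event = np.ones(n, dtype=bool)
        obs = times
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "group": groups,
            "time": np.round(obs, 4),
            "event": event.astype(int),
        }
    )


# --- cohort ----------------------------------------------------------------

_CLASSIFICATION = {
    (VariantClass.SNV, False): "Missense_Mutation",
    (VariantClass.INSERTION, True): "Frame_Shift_Ins",
    (VariantClass.INSERTION, False): "In_Frame_Ins",
    (VariantClass.DELETION, True): "Frame_Shift_Del",
    (VariantClass.DELETION, False): "In_Frame_Del",
    (VariantClass.DELINS, True): "Frame_Shift_Del",
    (VariantClass.DELINS, False): "In_Frame_Del",
}

_VARIANT_TYPE = {
    VariantClass.SNV: "SNP",
    VariantClass.INSERTION: "INS",
    VariantClass.DELETION: "DEL",
    VariantClass.DELINS: "ONP",
}


def hgvs_c(v: CodingVariant) -> str:
    """Serialize a CodingVariant back to HGVS c. notation."""
    if v.variant_class is VariantClass.SNV:
        return f"c.{v.cds_pos}{v.ref_allele}>{v.alt_allele}"
    if v.variant_class is VariantClass.INSERTION:
        return f"c.{v.cds_pos}_{v.cds_pos + 1}ins{v.alt_allele}"
    end = v.cds_pos + len(v.ref_allele) - 1
    if v.variant_class is VariantClass.DELETION:
        if end == v.cds_pos:
            return f"c.{v.cds_pos}del{v.ref_allele}"
        return f"c.{v.cds_pos}_{end}del{v.ref_allele}"
    return f"c.{v.cds_pos}_{end}delins{v.alt_allele}"


def write_maf(
    variants: list[CodingVariant], transcripts: dict[str, Transcript], path: Path
) -> Path:
    """Write a minimal TCGA-dialect MAF with HGVSc strings."""
    rows = []
    for v in variants:
        fs = classify_frameshift(v) is not FrameshiftClass.IN_FRAME
        gene = transcripts[v.transcript_id].gene_symbol if v.transcript_id in transcripts else ""
        rows.append(
            {
                "Hugo_Symbol": gene,
                "Transcript_ID": v.transcript_id,
                "Tumor_Sample_Barcode": v.patient_id,
                "Variant_Classification": _CLASSIFICATION[(v.variant_class, fs)],
                "Variant_Type": _VARIANT_TYPE[v.variant_class],
                "HGVSc": hgvs_c(v),
                "Reference_Allele": v.ref_allele or "-",
                "Tumor_Seq_Allele2": v.alt_allele or "-",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


@dataclass
class SimulatedCohort:
    """Everything one seeded run produced, in memory plus on disk."""

    config: SimConfig
    transcripts: dict[str, Transcript]
    variants: list[CodingVariant]
    truth: dict[str, dict]
    clinical: pd.DataFrame
    fasta_path: Path | None = None
    expression_path: Path | None = None
    maf_path: Path | None = None
    clinical_path: Path | None = None
    truth_path: Path | None = None


def _direct_fp_length(cds: str, flank: str, v: CodingVariant) -> int:
    """Ground-truth functional-peptide length by direct string splicing.

    Kept deliberately separate from the pipeline's extraction path (its own
    splice, its own codon walk) so generator truth and pipeline output are
    two routes to the same number.
    """
    stops = ("TAA", "TAG", "TGA")
    if v.variant_class is VariantClass.INSERTION:
        seq = cds[: v.cds_pos] + v.alt_allele + cds[v.cds_pos :] + flank
        p_star = v.cds_pos + 1
    else:
        end = v.cds_pos + len(v.ref_allele) - 1
        seq = cds[: v.cds_pos - 1] + v.alt_allele + cds[end:] + flank
        p_star = v.cds_pos
    start = ((p_star + 2) // 3 - 1) * 3
    count = 0
    for i in range(start, len(seq) - 2, 3):
        if seq[i : i + 3] in stops:
            return count
        count += 1
    return count


def generate_cohort(cfg: SimConfig, outdir: str | Path | None = None) -> SimulatedCohort:
    """Generate transcriptome + MAF + clinical table + ground-truth JSON.

    Under ``uniform_sequence`` the FP lengths arise from the sequence model;
    under ``implanted`` each patient receives one knocked-in frameshift with
    an exact target length on a dedicated transcript.  Survival times are
    exponential with hazard ``h0 * hazard_ratio**I(long FP)`` and
    independent exponential censoring.
    """
    rng = np.random.default_rng(cfg.seed)
    clean = cfg.fp_length_model == "implanted"
    transcripts = generate_transcriptome(cfg, rng, clean_orf=clean)
    tx_ids = sorted(transcripts)

    variants: list[CodingVariant] = []
    truth: dict[str, dict] = {}
    indel_lengths = sorted(cfg.indel_length_probs)
    indel_probs = [cfg.indel_length_probs[k] for k in indel_lengths]
    nb_r = cfg.mutations_dispersion
    nb_p = nb_r / (nb_r + cfg.mutations_mean)

    for pi in range(cfg.n_patients):
        patient = f"P{pi:04d}"
        n_mut = int(rng.negative_binomial(nb_r, nb_p))
        max_fp = 0
        n_fs = 0
        pvars: list[CodingVariant] = []
        for _ in range(n_mut):
            tid = tx_ids[int(rng.integers(len(tx_ids)))]
            t = transcripts[tid]
            if rng.random() < cfg.indel_fraction:
                size = int(rng.choice(indel_lengths, p=indel_probs))
                v = _random_indel(rng, patient, t, size)
            else:
                v = _random_snv(rng, patient, t)
            pvars.append(v)
            if classify_frameshift(v) is not FrameshiftClass.IN_FRAME:
                n_fs += 1
                max_fp = max(
                    max_fp, _direct_fp_length(t.cds, t.three_prime_flank, v)
                )
        if cfg.fp_length_model == "implanted":
            target = _draw_implant_target(rng, cfg)
            fs_type = (
                FrameshiftClass.TYPE1 if rng.random() < 0.5 else FrameshiftClass.TYPE2
            )
            imp_tid = f"TXIMP{pi:04d}"
            base = _implant_host_transcript(rng, cfg, imp_tid, target)
            variant, edited = implant_frameshift(base, target, fs_type)
            transcripts[imp_tid] = edited
            v = CodingVariant(
                patient_id=patient,
                transcript_id=imp_tid,
                cds_pos=variant.cds_pos,
                ref_allele=variant.ref_allele,
                alt_allele=variant.alt_allele,
                variant_class=variant.variant_class,
            )
            pvars.append(v)
            n_fs += 1
            max_fp = max(max_fp, target)
        variants.extend(pvars)
        truth[patient] = {
            "max_fp_length": int(max_fp),
            "long_fp": bool(max_fp > cfg.fp_threshold_aa),
            "n_frameshift": int(n_fs),
            "n_mutations": len(pvars),
        }

    clinical = _cohort_survival(rng, cfg, truth)

    cohort = SimulatedCohort(
        config=cfg,
        transcripts=transcripts,
        variants=variants,
        truth=truth,
        clinical=clinical,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cohort.fasta_path, cohort.expression_path = write_transcriptome(transcripts, outdir)
        cohort.maf_path = write_maf(variants, transcripts, outdir / "cohort.maf")
        cohort.clinical_path = outdir / "clinical.tsv"
        clinical.to_csv(cohort.clinical_path, sep="\t", index=False)
        cohort.truth_path = outdir / "truth.json"
        with open(cohort.truth_path, "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    return cohort


def _random_snv(rng: np.random.Generator, patient: str, t: Transcript) -> CodingVariant:
    pos = int(rng.integers(1, len(t.cds) + 1))
    ref = t.cds[pos - 1]
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return CodingVariant(patient, t.transcript_id, pos, ref, alt, VariantClass.SNV)


def _random_indel(
    rng: np.random.Generator, patient: str, t: Transcript, size: int
) -> CodingVariant:
    if rng.random() < 0.5:
        pos = int(rng.integers(1, len(t.cds)))
        alt = "".join(rng.choice(BASES, size=size))
        return CodingVariant(patient, t.transcript_id, pos, "", alt, VariantClass.INSERTION)
    pos = int(rng.integers(1, len(t.cds) - size + 1))
    ref = t.cds[pos - 1 : pos - 1 + size]
    return CodingVariant(patient, t.transcript_id, pos, ref, "", VariantClass.DELETION)


def _draw_implant_target(rng: np.random.Generator, cfg: SimConfig) -> int:
    if rng.random() < cfg.implant_long_fraction:
        lo, hi = cfg.implant_long_range
    else:
        lo, hi = cfg.implant_short_range
    return int(rng.integers(lo, hi + 1))


def _implant_host_transcript(
    rng: np.random.Generator, cfg: SimConfig, tid: str, target: int
) -> Transcript:
    n_codons = max(target + 12, 40)
    cds = _random_cds(rng, n_codons, clean_orf=True)
    flank = "".join(rng.choice(BASES, size=60))
    return Transcript(
        tid, cds=cds, gene_symbol=f"GENE_{tid}", three_prime_flank=flank,
        expression_fpkm=float(np.exp(rng.normal(1.0, 1.5))),
    )


def _cohort_survival(
    rng: np.random.Generator, cfg: SimConfig, truth: dict[str, dict]
) -> pd.DataFrame:
    patients = sorted(truth)
    long_flags = np.array([truth[p]["long_fp"] for p in patients])
    hazards = np.where(
        long_flags, cfg.baseline_hazard * cfg.hazard_ratio, cfg.baseline_hazard
    )
    times = rng.exponential(1.0 / hazards)
    if cfg.censoring_fraction > 0:
        mean_h = float(hazards.mean())
        rate = mean_h * cfg.censoring_fraction / (1.0 - cfg.censoring_fraction)
        cens = rng.exponential(1.0 / rate, size=len(patients))
        event = times <= cens
        obs = np.minimum(times, cens)
    else:
        event = np.ones(len(patients), dtype=bool)
        obs = times
    return pd.DataFrame(
        {"patient_id": patients, "time": np.round(obs, 4), "event": event.astype(int)}
    )
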