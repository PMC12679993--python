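"""Missense neoepitope filter cascade.

Three stages, each leaving an auditable pass flag on every candidate:

1. binding   — best mutant window rank ≤ rank_threshold on any allele
               (top-1% rule, inclusive);
2. ratio     — mutant/wild-type affinity ratio at the best window's
               coordinates ≥ ratio_threshold;
3. expression— transcript FPKM ≥ fpkm_threshold (candidates with no
               expression value fail with reason "no_expression").

Output is sorted by best mutant rank ascending.  Default cutoffs (ratio 1.0
— mutant binds at least as well as wild type — and FPKM 1.0) are
deliberately conservative and prominently configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import pandas as pd

from .epitopes import Predictor

DEFAULT_ALLELES = ("H2-Kb", "H2-Db")
DEFAULT_LENGTHS = (8, 9, 10, 11)


@dataclass
class MissenseCandidate:
    """One missense substitution with its screen scores and stage flags."""

    transcript_id: str
    gene: str
    protein_pos: int  # 1-based residue index
    wt_aa: str
    mut_aa: str
    protein: str  # wild-type protein sequence
    fpkm: float | None = None
    best_mut_rank: float = math.nan
    best_mut_affinity: float = math.nan
    matched_wt_affinity: float = math.nan
    affinity_ratio: float = math.nan
    best_allele: str = ""
    passes: dict[str, bool] = field(default_factory=dict)
    fail_reason: str = ""

    def __post_init__(self) -> None:
        if self.wt_aa == self.mut_aa:
            raise ValueError(
                f"{self.transcript_id} p.{self.protein_pos}: synonymous change "
                f"({self.wt_aa}) is not a missense candidate"
            )

    @property
    def passes_all(self) -> bool:
        return bool(self.passes) and all(self.passes.values())


def mutant_windows(
    protein: str, protein_pos: int, mut_aa: str, lengths
) -> list[tuple[str, str, int]]:
    """All WT/mutant window pairs overlapping the substituted residue.

    Returns (wt_window, mut_window, start) with 1-based starts; the two
    windows share coordinates and differ at exactly the substituted
    position.
    """
    if not 1 <= protein_pos <= len(protein):
        raise ValueError(
            f"protein_pos {protein_pos} outside protein of length {len(protein)}"
        )
    i = protein_pos - 1
    mutant = protein[:i] + mut_aa + protein[i + 1 :]
    pairs: list[tuple[str, str, int]] = []
    for k in sorted(set(lengths)):
        lo = max(0, i - k + 1)
        hi = min(i, len(protein) - k)
        for s in range(lo, hi + 1):
            pairs.append((protein[s : s + k], mutant[s : s + k], s + 1))
    return pairs


def screen(
    candidates: list[MissenseCandidate],
    predictor: Predictor,
    alleles=DEFAULT_ALLELES,
    rank_threshold: float = 1.0,
    ratio_threshold: float = 1.0,
    fpkm_threshold: float = 1.0,
    lengths=DEFAULT_LENGTHS,
) -> list[MissenseCandidate]:
    """Run the three-stage cascade; every candidate keeps per-stage flags.

    Stage 1 scans every mutant window over every allele and keeps the best
    (lowest) rank; the wild-type affinity is measured on the same window
    coordinates and allele as the best mutant window, so the ratio compares
    like with like.  Survivors of all stages sort first (by best mutant
    rank ascending); non-survivors follow, also rank-sorted.
    """
    for cand in candidates:
        best_rank, best_aff, best_wt, best_allele = math.inf, math.nan, math.nan, ""
        for wt_win, mut_win, _start in mutant_windows(
            cand.protein, cand.protein_pos, cand.mut_aa, lengths
        ):
            for allele in alleles:
                if len(mut_win) not in predictor.supported_lengths(allele):
                    continue
                aff, rank = predictor.predict(mut_win, allele)
                if rank < best_rank:
                    best_rank = rank
                    best_aff = aff
                    best_wt = predictor.predict(wt_win, allele)[0]
                    best_allele = allele
        cand.best_mut_rank = best_rank
        cand.best_mut_affinity = best_aff
        cand.matched_wt_affinity = best_wt
        cand.best_allele = best_allele
        cand.affinity_ratio = (
            best_aff / best_wt if best_wt and not math.isnan(best_wt) else math.nan
        )

        cand.passes["binding"] = best_rank <= rank_threshold
        cand.passes["ratio"] = (
            not math.isnan(cand.affinity_ratio)
            and cand.affinity_ratio >= ratio_threshold
        )
        if cand.fpkm is None:
            cand.passes["expression"] = False
            cand.fail_reason = "no_expression"
        else:
            cand.passes["expression"] = cand.fpkm >= fpkm_threshold
    return sorted(
        candidates, key=lambda c: (not c.passes_all, c.best_mut_rank, c.transcript_id)
    )


def screen_report(candidates: list[MissenseCandidate]) -> pd.DataFrame:
    """Ranked TSV-ready table with per-stage pass flags."""
    return pd.DataFrame(
        [
            {
                "transcript_id": c.transcript_id,
                "gene": c.gene,
                "protein_pos": c.protein_pos,
                "wt_aa": c.wt_aa,
                "mut_aa": c.mut_aa,
                "best_allele": c.best_allele,
                "best_mut_rank": c.best_mut_rank,
                "best_mut_affinity": c.best_mut_affinity,
                "matched_wt_affinity": c.matched_wt_affinity,
                "affinity_ratio": c.affinity_ratio,
                "fpkm": c.fpkm,
                "pass_binding": c.passes.get("binding", False),
                "pass_ratio": c.passes.get("ratio", False),
                "pass_expression": c.passes.get("expression", False),
                "pass_all": c.passes_all,
                "fail_reason": c.fail_reason,
            }
            for c in candidates
        ]
    )


def funnel_counts(candidates: list[MissenseCandidate]) -> dict[str, int]:
    """Staged candidate counts (input, after each cumulative filter)."""
    n = len(candidates)
    s1 = [c for c in candidates if c.passes.get("binding")]
    s2 = [c for c in s1 if c.passes.get("ratio")]
    s3 = [c for c in s2 if c.passes.get("expression")]
    return {
        "input": n,
        "after_binding": len(s1),
        "after_ratio": len(s2),
        "after_expression": len(s3),
    }
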