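"""MHC I/II window scanning, strong-binder calling, and CTA classification.

A *complete T cell antigen* (CTA) is a single peptide chain that carries at
least one MHC class I–restricted and at least one MHC class II–restricted
strong-binding window, so that CD8+ and CD4+ T cells can be primed against
the same chain.  "Strong binder" is a rank criterion: a window whose
predicted binding rank is within the top 1% for an allele (inclusive
threshold, configurable).

Binding prediction itself is delegated to a pluggable predictor: either
scores ingested from an external tool's TSV output, or the built-in
deterministic anchor-motif mock used for testing and simulation.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Default scan window lengths per MHC class.
DEFAULT_LENGTHS = {"I": (8, 9, 10, 11), "II": (15,)}

#: Default strong-binder rank threshold (percent, inclusive).
STRONG_RANK_THRESHOLD = 1.0


@dataclass(frozen=True)
class EpitopeCall:
    """One (window, allele) binding call within a parent chain."""

    peptide: str
    start: int  # 1-based offset in the parent chain
    allele: str
    mhc_class: str  # "I" or "II"
    affinity_value: float  # 1/IC50 x 100, IC50 in nM; NaN if prediction failed
    rank_percent: float  # in (0, 100]; NaN if prediction failed
    strong_binder: bool


@dataclass(frozen=True)
class CTAStatus:
    chain_id: str
    n_mhci_strong: int
    n_mhcii_strong: int
    best_rank_i: float = math.nan
    best_rank_ii: float = math.nan

    @property
    def is_cta(self) -> bool:
        return self.n_mhci_strong >= 1 and self.n_mhcii_strong >= 1


class Predictor(Protocol):
    """Binding-predictor contract: deterministic (peptide, allele) -> scores."""

    name: str

    def supported_alleles(self) -> set[str]: ...

    def supported_lengths(self, allele: str) -> set[int]: ...

    def predict(self, peptide: str, allele: str) -> tuple[float, float]:
        """Return (affinity_value, rank_percent) for one peptide/allele."""
        ...


def enumerate_windows(chain: str, lengths) -> list[tuple[str, int]]:
    """All contiguous windows of each requested length with 1-based starts.

    Deterministic order: length ascending, then start ascending.  A chain
    shorter than ``k`` contributes no length-``k`` windows.
    """
    if not chain:
        raise ValueError("chain must be non-empty")
    out: list[tuple[str, int]] = []
    for k in sorted(set(lengths)):
        for i in range(len(chain) - k + 1):
            out.append((chain[i : i + k], i + 1))
    return out


def call_strong_binders(
    chain_id: str,
    chain: str,
    predictor: Predictor,
    alleles,
    mhc_class: str,
    strong_rank_threshold: float = STRONG_RANK_THRESHOLD,
    lengths=None,
) -> list[EpitopeCall]:
    """Scan ``chain`` with every (window, allele) pair and flag strong binders.

    A predictor failure on a window is recorded as a call with NaN scores
    and a warning — never silently dropped.
    """
    if lengths is None:
        lengths = DEFAULT_LENGTHS[mhc_class]
    lengths = sorted(set(lengths))
    for allele in alleles:
        if allele not in predictor.supported_alleles():
            raise ValueError(f"predictor {predictor.name} does not support allele {allele}")
        unsupported = set(lengths) - predictor.supported_lengths(allele)
        if unsupported:
            raise ValueError(
                f"predictor {predictor.name} does not support lengths "
                f"{sorted(unsupported)} for {allele}"
            )
    calls: list[EpitopeCall] = []
    for window, start in enumerate_windows(chain, lengths):
        for allele in alleles:
            try:
                affinity, rank = predictor.predict(window, allele)
            except Exception as exc:  # record, never drop
                logger.warning(
                    "%s: prediction failed for %s/%s at %d: %s",
                    chain_id, window, allele, start, exc,
                )
                affinity, rank = math.nan, math.nan
            strong = bool(rank <= strong_rank_threshold) if not math.isnan(rank) else False
            calls.append(
                EpitopeCall(
                    peptide=window,
                    start=start,
                    allele=allele,
                    mhc_class=mhc_class,
                    affinity_value=affinity,
                    rank_percent=rank,
                    strong_binder=strong,
                )
            )
    return calls


def classify_cta(chain_id: str, calls: list[EpitopeCall]) -> CTAStatus:
    """Count distinct strong-binder windows per MHC class and call CTA status.

    Windows are distinct by (start, length, allele); overlapping windows each
    count.  A chain is a CTA iff both classes contribute at least one strong
    binder.
    """
    strong_i: set[tuple[int, int, str]] = set()
    strong_ii: set[tuple[int, int, str]] = set()
    best_i, best_ii = math.inf, math.inf
    for c in calls:
        if not math.isnan(c.rank_percent):
            if c.mhc_class == "I":
                best_i = min(best_i, c.rank_percent)
            else:
                best_ii = min(best_ii, c.rank_percent)
        if not c.strong_binder:
            continue
        key = (c.start, len(c.peptide), c.allele)
        (strong_i if c.mhc_class == "I" else strong_ii).add(key)
    return CTAStatus(
        chain_id=chain_id,
        n_mhci_strong=len(strong_i),
        n_mhcii_strong=len(strong_ii),
        best_rank_i=best_i if math.isfinite(best_i) else math.nan,
        best_rank_ii=best_ii if math.isfinite(best_ii) else math.nan,
    )


def cta_report(statuses: list[CTAStatus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chain_id": s.chain_id,
                "n_mhci_strong": s.n_mhci_strong,
                "n_mhcii_strong": s.n_mhcii_strong,
                "is_cta": s.is_cta,
                "best_rank_I": s.best_rank_i,
                "best_rank_II": s.best_rank_ii,
            }
            for s in statuses
        ],
        columns=["chain_id", "n_mhci_strong", "n_mhcii_strong", "is_cta",
                 "best_rank_I", "best_rank_II"],
    )


# --- built-in deterministic mock predictor ---------------------------------


@dataclass(frozen=True)
class AlleleMotif:
    """Anchor motif defining the mock predictor's scoring for one allele.

    ``anchors`` maps a 0-based peptide position (−1 = C-terminal residue) to
    the set of favoured residues at that position.
    """

    mhc_class: str
    lengths: tuple[int, ...]
    anchors: dict[int, str] = field(default_factory=dict)


#: Anchor motifs loosely shaped after the murine alleles used throughout:
#: H2-Kb (p5 aromatic, C-term aliphatic), H2-Db (p5 Asn, C-term aliphatic),
#: I-Ab (acidic p4, basic p9).  These are a deterministic test double, not a
#: trained binding model.
DEFAULT_MOTIFS: dict[str, AlleleMotif] = {
    "H2-Kb": AlleleMotif("I", (8, 9, 10, 11), {4: "FY", -1: "LMIV"}),
    "H2-Db": AlleleMotif("I", (8, 9, 10, 11), {4: "N", -1: "MIL"}),
    "I-Ab": AlleleMotif("II", (15,), {3: "DE", 8: "KR", 11: "ST"}),
}


class MockPredictor:
    """Deterministic anchor-motif predictor with a seeded random background.

    The raw score of a peptide is its anchor-match count plus a
    hash-derived jitter in [0, 1), so a peptide matching every anchor always
    outranks any peptide that misses one.  ``rank_percent`` is the
    percentile of that score within a seeded background of random peptides
    of the allele's supported lengths: with a background of size N and k
    background scores strictly above the query, rank = 100*(k+1)/(N+1).
    Fully reproducible given (motifs, background_size, seed).
    """

    def __init__(
        self,
        motifs: dict[str, AlleleMotif] | None = None,
        background_size: int = 2000,
        seed: int = 0,
    ):
        self.name = "mock-anchor"
        self.motifs = motifs if motifs is not None else DEFAULT_MOTIFS
        self.background_size = background_size
        self.seed = seed
        self._backgrounds: dict[str, np.ndarray] = {}

    def supported_alleles(self) -> set[str]:
        return set(self.motifs)

    def supported_lengths(self, allele: str) -> set[int]:
        return set(self.motifs[allele].lengths)

    def _score(self, peptide: str, allele: str) -> float:
        motif = self.motifs[allele]
        matches = 0
        for pos, residues in motif.anchors.items():
            idx = pos if pos >= 0 else len(peptide) + pos
            if 0 <= idx < len(peptide) and peptide[idx] in residues:
                matches += 1
        jitter = zlib.crc32(f"{allele}|{peptide}".encode()) / 2**32
        return matches + jitter

    def _background(self, allele: str) -> np.ndarray:
        if allele not in self._backgrounds:
            motif = self.motifs[allele]
            rng = np.random.default_rng(
                [self.seed, zlib.crc32(allele.encode()) % 2**31]
            )
            lengths = rng.choice(motif.lengths, size=self.background_size)
            aa = np.array(list(AMINO_ACIDS))
            scores = np.empty(self.background_size)
            for i, k in enumerate(lengths):
                pep = "".join(rng.choice(aa, size=int(k)))
                scores[i] = self._score(pep, allele)
            self._backgrounds[allele] = np.sort(scores)
        return self._backgrounds[allele]

    def predict(self, peptide: str, allele: str) -> tuple[float, float]:
        if allele not in self.motifs:
            raise ValueError(f"unsupported allele {allele}")
        if len(peptide) not in self.motifs[allele].lengths:
            raise ValueError(
                f"unsupported length {len(peptide)} for {allele}"
            )
        score = self._score(peptide, allele)
        bg = self._background(allele)
        n_above = len(bg) - np.searchsorted(bg, score, side="right")
        rank = 100.0 * (n_above + 1) / (len(bg) + 1)
        # pseudo-IC50 decreasing in score; affinity = 1/IC50 x 100
        ic50_nm = 50000.0 * math.exp(-2.0 * score)
        affinity = 100.0 / ic50_nm
        return affinity, rank


class TablePredictor:
    """Predictor backed by an external tool's results TSV.

    Expected columns: peptide, allele, ic50_nM, rank_percent.  Affinity is
    derived as 1/IC50 x 100.  Lookups for (peptide, allele) pairs absent
    from the table raise KeyError, which the scanner records as a failed
    call.
    """

    def __init__(self, table_path: str | Path, mhc_class_by_allele: dict[str, str] | None = None):
        self.name = f"table:{table_path}"
        tab = pd.read_csv(table_path, sep="\t")
        required = {"peptide", "allele", "ic50_nM", "rank_percent"}
        if not required.issubset(tab.columns):
            raise ValueError(f"predictor table must have columns {sorted(required)}")
        self._scores: dict[tuple[str, str], tuple[float, float]] = {}
        self._lengths: dict[str, set[int]] = {}
        for row in tab.itertuples(index=False):
            affinity = 100.0 / float(row.ic50_nM)
            self._scores[(row.peptide, row.allele)] = (affinity, float(row.rank_percent))
            self._lengths.setdefault(row.allele, set()).add(len(row.peptide))

    def supported_alleles(self) -> set[str]:
        return {a for _, a in self._scores}

    def supported_lengths(self, allele: str) -> set[int]:
        return self._lengths.get(allele, set())

    def predict(self, peptide: str, allele: str) -> tuple[float, float]:
        return self._scores[(peptide, allele)]
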