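"""Per-patient mutation statistics, stratification, and survival comparison.

The biomarker of interest is the *maximal functional-peptide length* per
patient: the length (AA) of the longest frameshift-derived peptide any of
the patient's mutations can produce.  Patients are split into long-FP
(> 120 AA, strict) and short-FP groups; tumor mutational burden (TMB) and
frameshift-count splits use either a top-quantile rule (default top 20%)
or a median split, and the groups are compared by Kaplan–Meier estimates
with a two-group log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .peptides import FunctionalPeptide
from .variants import CodingVariant, FrameshiftClass, classify_frameshift

FP_THRESHOLD_AA = 120
TOP_QUANTILE = 0.20


@dataclass
class PatientRecord:
    patient_id: str
    n_mutations_total: int = 0
    n_frameshift: int = 0
    max_fp_length: int = 0
    tmb_per_mb: float | None = None
    survival_time: float | None = None
    event: bool | None = None

    def __post_init__(self) -> None:
        if self.n_frameshift > self.n_mutations_total:
            raise ValueError(
                f"{self.patient_id}: n_frameshift {self.n_frameshift} exceeds "
                f"total {self.n_mutations_total}"
            )
        if self.n_frameshift == 0 and self.max_fp_length != 0:
            raise ValueError(
                f"{self.patient_id}: max_fp_length must be 0 without frameshifts"
            )


def summarize_patient(
    patient_id: str,
    variants: list[CodingVariant],
    functional_peptides: list[FunctionalPeptide],
    capture_mb: float | None = None,
    include_stop_lost: bool = True,
) -> PatientRecord:
    """Aggregate one patient's variants and peptides into a PatientRecord.

    TMB is the total somatic mutation count, normalised per megabase when
    the capture size is known.  Stop-lost peptides (no downstream stop
    found) contribute their observed length by default; pass
    ``include_stop_lost=False`` to exclude them from the maximum.
    """
    variants = [v for v in variants if v.patient_id == patient_id]
    fps = [p for p in functional_peptides if p.patient_id == patient_id]
    if not include_stop_lost:
        fps = [p for p in fps if p.stop_found]
    n_fs = sum(
        1 for v in variants if classify_frameshift(v) is not FrameshiftClass.IN_FRAME
    )
    return PatientRecord(
        patient_id=patient_id,
        n_mutations_total=len(variants),
        n_frameshift=n_fs,
        max_fp_length=max((p.length_aa for p in fps), default=0),
        tmb_per_mb=(len(variants) / capture_mb) if capture_mb else None,
    )


def summarize_cohort(
    variants: list[CodingVariant],
    functional_peptides: list[FunctionalPeptide],
    capture_mb: float | None = None,
    include_stop_lost: bool = True,
) -> list[PatientRecord]:
    patients = sorted({v.patient_id for v in variants})
    return [
        summarize_patient(p, variants, functional_peptides, capture_mb, include_stop_lost)
        for p in patients
    ]


def attach_clinical(records: list[PatientRecord], clinical_path: str | Path) -> list[PatientRecord]:
    """Join survival time and event flag from a clinical TSV (patient_id, time, event)."""
    clin = pd.read_csv(clinical_path, sep="\t")
    required = {"patient_id", "time", "event"}
    if not required.issubset(clin.columns):
        raise ValueError(f"clinical table must have columns {sorted(required)}")
    by_id = clin.set_index("patient_id")
    for rec in records:
        if rec.patient_id in by_id.index:
            row = by_id.loc[rec.patient_id]
            rec.survival_time = float(row["time"])
            rec.event = bool(int(row["event"]))
    return records


@dataclass
class StratifiedCohort:
    """Group labels per patient for the FP / TMB / FS stratifications."""

    labels: pd.DataFrame  # columns: patient_id, fp_group, tmb_group, fs_group
    fp_threshold_aa: int
    split: str  # "quantile:<q>" or "median"


def _high_low(values: np.ndarray, top_quantile: float | None) -> np.ndarray:
    """Label 'high' for the top fraction (ties at the cut all high), else median split."""
    if top_quantile is None:  # median split
        cut = float(np.median(values))
        labels = np.where(values > cut, "high", "low")
    else:
        cut = float(np.quantile(values, 1.0 - top_quantile, method="higher"))
        labels = np.where(values >= cut, "high", "low")
    if (labels == "high").all():
        warnings.warn("statistic is constant: entire cohort labelled high", stacklevel=3)
    return labels


def stratify(
    records: list[PatientRecord],
    fp_threshold_aa: int = FP_THRESHOLD_AA,
    top_quantile: float | None = TOP_QUANTILE,
) -> StratifiedCohort:
    """Label each patient long/short-FP and high/low TMB and frameshift count.

    Long FP means max_fp_length strictly greater than the threshold
    (120 AA default).  With ``top_quantile`` set (default 0.20) the TMB and
    FS "high" groups are the patients at or above the (1−q) quantile, ties
    included; with ``top_quantile=None`` a median split is used instead.
    """
    if not records:
        raise ValueError("cannot stratify an empty cohort")
    tmb = np.array(
        [r.tmb_per_mb if r.tmb_per_mb is not None else r.n_mutations_total for r in records],
        dtype=float,
    )
    fs = np.array([r.n_frameshift for r in records], dtype=float)
    labels = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "fp_group": [
                "long" if r.max_fp_length > fp_threshold_aa else "short" for r in records
            ],
            "tmb_group": _high_low(tmb, top_quantile),
            "fs_group": _high_low(fs, top_quantile),
        }
    )
    split = "median" if top_quantile is None else f"quantile:{top_quantile}"
    return StratifiedCohort(labels=labels, fp_threshold_aa=fp_threshold_aa, split=split)


def km_logrank(
    records: list[PatientRecord], group_labels: dict[str, str] | pd.Series
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan–Meier curves per group plus a two-group log-rank test.

    Returns ({group: KM table (time, at_risk, events, survival)},
    logrank chi-square statistic with 1 df, p-value).  A group with zero
    observed events still enters the statistic, with a warning.
    """
    if isinstance(group_labels, pd.Series):
        group_labels = dict(group_labels)
    rows = [
        (r.survival_time, bool(r.event), group_labels[r.patient_id])
        for r in records
        if r.survival_time is not None and r.patient_id in group_labels
    ]
    if not rows:
        raise ValueError("no patients with survival data and group labels")
    df = pd.DataFrame(rows, columns=["time", "event", "group"])
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError(f"need >=2 non-empty groups, got {groups}")
    if len(groups) > 2:
        raise ValueError("log-rank comparison implemented for exactly two groups")

    curves: dict[str, pd.DataFrame] = {}
    for g in groups:
        sub = df[df["group"] == g]
        if sub["event"].sum() == 0:
            warnings.warn(f"group {g!r} has zero observed events", stacklevel=2)
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"], label=str(g))
        tab = kmf.event_table.copy()
        curves[g] = pd.DataFrame(
            {
                "time": tab.index.to_numpy(dtype=float),
                "at_risk": tab["at_risk"].to_numpy(dtype=int),
                "events": tab["observed"].to_numpy(dtype=int),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
            }
        )
    a, b = (df[df["group"] == g] for g in groups)
    res = logrank_test(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return curves, float(res.test_statistic), float(res.p_value)


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "n_mutations_total": r.n_mutations_total,
                "n_frameshift": r.n_frameshift,
                "max_fp_length": r.max_fp_length,
                "tmb_per_mb": r.tmb_per_mb,
                "time": r.survival_time,
                "event": r.event,
            }
            for r in records
        ]
    )
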