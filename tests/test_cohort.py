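"""Patient summaries, stratification, Kaplan-Meier and log-rank machinery."""

import numpy as np
import pytest

from fsneo.cohort import (
    PatientRecord,
    km_logrank,
    records_to_frame,
    stratify,
    summarize_patient,
)
from fsneo.peptides import FunctionalPeptide
from fsneo.variants import CodingVariant, FrameshiftClass, VariantClass

# Hand-computed two-group log-rank for times 1..6, alternating groups, no
# censoring (O-E/V at each death time): sum(O-E) = 23/30, sum V = 1091/900,
# chi-square = (23/30)^2 / (1091/900) = 529/1091.
HAND_LOGRANK_CHI2 = 529.0 / 1091.0


def _variant(patient, pos, ref, alt, vclass, tid="T1"):
    return CodingVariant(patient, tid, pos, ref, alt, vclass)


def _fp(patient, length, stop_found=True, tid="T1"):
    v = _variant(patient, 5, "G", "", VariantClass.DELETION, tid)
    return FunctionalPeptide(
        patient_id=patient, transcript_id=tid, variant=v,
        fs_class=FrameshiftClass.TYPE1, sequence="A" * length,
        stop_found=stop_found, start_codon_index=2,
    )


def _record(pid, time, event, max_fp=0, n_fs=0, n_mut=0, tmb=None):
    return PatientRecord(
        patient_id=pid, n_mutations_total=max(n_mut, n_fs),
        n_frameshift=n_fs, max_fp_length=max_fp, tmb_per_mb=tmb,
        survival_time=time, event=event,
    )


class TestSummarizePatient:
    def test_tmb_arithmetic(self):
        variants = [
            _variant("p1", 4, "G", "C", VariantClass.SNV),
            _variant("p1", 6, "A", "T", VariantClass.SNV),
            _variant("p1", 8, "G", "", VariantClass.DELETION),
        ]
        rec = summarize_patient("p1", variants, [], capture_mb=30.0)
        assert rec.tmb_per_mb == pytest.approx(0.1)
        assert rec.n_mutations_total == 3 and rec.n_frameshift == 1

    def test_max_fp_length(self):
        fps = [_fp("p1", 119), _fp("p1", 121)]
        rec = summarize_patient("p1", [_variant("p1", 5, "G", "", VariantClass.DELETION)], fps)
        assert rec.max_fp_length == 121

    def test_snv_only_patient_has_zero_fp(self):
        variants = [_variant("p1", 4, "G", "C", VariantClass.SNV)]
        rec = summarize_patient("p1", variants, [])
        assert rec.n_frameshift == 0 and rec.max_fp_length == 0

    def test_stop_lost_exclusion_flag(self):
        fps = [_fp("p1", 200, stop_found=False), _fp("p1", 50, stop_found=True)]
        variants = [_variant("p1", 5, "G", "", VariantClass.DELETION)]
        with_rt = summarize_patient("p1", variants, fps)
        without = summarize_patient("p1", variants, fps, include_stop_lost=False)
        assert with_rt.max_fp_length == 200
        assert without.max_fp_length == 50

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            PatientRecord("p", n_mutations_total=1, n_frameshift=2)
        with pytest.raises(ValueError):
            PatientRecord("p", n_mutations_total=1, n_frameshift=0, max_fp_length=5)


class TestStratify:
    def test_fp_threshold_strict(self):
        records = [
            _record("a", 10, True, max_fp=150, n_fs=1, n_mut=1),
            _record("b", 10, True, max_fp=120, n_fs=1, n_mut=1),
            _record("c", 10, True, max_fp=121, n_fs=1, n_mut=1),
        ]
        labels = stratify(records).labels.set_index("patient_id")["fp_group"]
        assert labels["a"] == "long"
        assert labels["b"] == "short"  # 120 is NOT longer than 120
        assert labels["c"] == "long"

    def test_top_quantile_counts(self):
        # 10 patients, distinct frameshift counts, top 20% -> exactly 2 high
        records = [
            _record(f"p{i}", 10, True, n_fs=i, n_mut=i + 1) for i in range(10)
        ]
        labels = stratify(records, top_quantile=0.20).labels
        assert (labels["fs_group"] == "high").sum() == 2
        high = set(labels.loc[labels["fs_group"] == "high", "patient_id"])
        assert high == {"p8", "p9"}

    def test_ties_at_boundary_all_high(self):
        counts = [0, 1, 2, 3, 4, 5, 6, 7, 8, 8]
        records = [
            _record(f"p{i}", 10, True, n_fs=c, n_mut=c + 1)
            for i, c in enumerate(counts)
        ]
        labels = stratify(records, top_quantile=0.20).labels
        assert (labels["fs_group"] == "high").sum() == 2  # both count-8 patients

    def test_median_split_mode(self):
        records = [
            _record(f"p{i}", 10, True, n_fs=i, n_mut=i + 1, tmb=float(i))
            for i in range(10)
        ]
        strat = stratify(records, top_quantile=None)
        assert strat.split == "median"
        assert (strat.labels["tmb_group"] == "high").sum() == 5

    def test_constant_statistic_warns(self):
        records = [_record(f"p{i}", 10, True, n_mut=3, tmb=2.0) for i in range(4)]
        with pytest.warns(UserWarning, match="constant"):
            stratify(records)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            stratify([])


class TestKmLogrank:
    def test_identical_groups_statistic_zero(self):
        records = []
        groups = {}
        for g in ("A", "B"):
            for i, t in enumerate([2.0, 4.0, 6.0, 8.0]):
                pid = f"{g}{i}"
                records.append(_record(pid, t, event=True))
                groups[pid] = g
        _, stat, p = km_logrank(records, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computation_six_subjects(self):
        records = [
            _record(f"p{i}", float(t), event=True)
            for i, t in enumerate([1, 2, 3, 4, 5, 6])
        ]
        groups = {f"p{i}": ("A" if i % 2 == 0 else "B") for i in range(6)}
        _, stat, _ = km_logrank(records, groups)
        assert stat == pytest.approx(HAND_LOGRANK_CHI2, rel=1e-10)

    def test_invariant_under_monotone_time_relabeling(self):
        rng = np.random.default_rng(11)
        times = rng.exponential(10, size=40)
        events = rng.random(40) < 0.7
        records1, records2, groups = [], [], {}
        for i, (t, e) in enumerate(zip(times, events)):
            pid = f"p{i}"
            records1.append(_record(pid, float(t), bool(e)))
            records2.append(_record(pid, float(np.sqrt(t) * 3 + 1), bool(e)))
            groups[pid] = "A" if i % 2 == 0 else "B"
        _, s1, p1 = km_logrank(records1, groups)
        _, s2, p2 = km_logrank(records2, groups)
        assert s1 == pytest.approx(s2, rel=1e-9)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_km_curve_non_increasing_from_one(self):
        rng = np.random.default_rng(5)
        records, groups = [], {}
        for i in range(30):
            pid = f"p{i}"
            records.append(_record(pid, float(rng.exponential(10) + 0.1),
                                   bool(rng.random() < 0.8)))
            groups[pid] = "A" if i < 15 else "B"
        curves, _, _ = km_logrank(records, groups)
        for tab in curves.values():
            s = tab["survival"].to_numpy()
            assert s[0] <= 1.0 + 1e-12
            assert np.all(np.diff(s) <= 1e-12)

    def test_zero_event_group_warns_but_computes(self):
        records, groups = [], {}
        for i in range(6):
            pid = f"p{i}"
            records.append(_record(pid, float(i + 1), event=(i % 2 == 0)))
            groups[pid] = "A" if i % 2 == 0 else "B"  # B all censored
        with pytest.warns(UserWarning, match="zero observed events"):
            _, stat, p = km_logrank(records, groups)
        assert np.isfinite(stat) and np.isfinite(p)

    def test_single_group_rejected(self):
        records = [_record("p1", 1.0, True), _record("p2", 2.0, True)]
        with pytest.raises(ValueError, match="2"):
            km_logrank(records, {"p1": "A", "p2": "A"})


class TestPowerAndSize:
    """Operating characteristics of the survival contrast on simulated cohorts."""

    @staticmethod
    def _rejection_rate(hazard_ratio, n_reps=200, n=400, alpha=0.05):
        from lifelines.statistics import logrank_test

        from fsneo.simulate import simulate_survival

        rejections = 0
        for i in range(n_reps):
            df = simulate_survival(
                n, frac_long=0.5, rng=np.random.default_rng([97, i]),
                hazard_ratio=hazard_ratio, censoring_fraction=0.30,
            )
            a = df[df.group == "long"]
            b = df[df.group == "short"]
            res = logrank_test(a.time, b.time, event_observed_A=a.event,
                               event_observed_B=b.event)
            rejections += res.p_value < alpha
        return rejections / n_reps

    def test_power_at_half_hazard(self):
        assert self._rejection_rate(0.5) >= 0.80

    def test_size_at_null(self):
        assert self._rejection_rate(1.0) <= 0.08

    def test_median_survival_ordering_long_beats_short(self):
        from fsneo.simulate import simulate_survival

        wins = 0
        for i in range(100):
            df = simulate_survival(400, 0.5, rng=np.random.default_rng([53, i]),
                                   hazard_ratio=0.5, censoring_fraction=0.0)
            med = df.groupby("group")["time"].median()
            wins += med["long"] > med["short"]
        assert wins >= 95
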