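import numpy as np
import pandas as pd
import pytest

from tagarray import qc_engine
from tagarray.panel_io import GenotypeMatrix
from tagarray.qc_engine import (
    QCThresholds,
    concordance,
    filter_markers,
    maf_spectrum,
    qc_samples,
    replicate_reproducibility,
    select_best_probeset,
    stage1_call_rate,
)
from tagarray.synthdata import corrupt_calls, make_pilot_qc_fixture


def sample_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["sample_id", "plate_id", "control_type", "scan_ok", "dqc",
                 "stage1_call_rate"],
    )


class TestQCSamples:
    def test_pilot_fixture_counts(self):
        """636 study samples: 1 scan failure, 8 low-DQC, 5 low call rate
        leave 622 passing (97.80 %)."""
        samples, _ = make_pilot_qc_fixture()
        decisions, plates, summary = qc_samples(samples)
        assert summary["n_samples"] == 636
        assert summary["n_passed"] == 622
        assert round(100 * summary["pass_rate"], 2) == 97.80
        assert (summary["n_scan_fail"], summary["n_dqc_fail"],
                summary["n_call_rate_fail"]) == (1, 8, 5)
        assert summary["n_negative_controls"] == 7
        # negative controls never enter the decision table
        assert not decisions["sample_id"].str.startswith("NEG").any()

    def test_dqc_rule_is_strictly_below(self):
        rows = [("a", "P1", "study", True, 0.82, 0.99),
                ("b", "P1", "study", True, 0.8199, 0.99)]
        decisions, _, _ = qc_samples(sample_frame(rows))
        by_id = decisions.set_index("sample_id")
        assert by_id.loc["a", "passed"]
        assert not by_id.loc["b", "passed"]
        assert by_id.loc["b", "reason_codes"] == [qc_engine.DQC_BELOW_MIN]

    def test_call_rate_rule_is_strictly_below(self):
        rows = [("a", "P1", "study", True, 0.9, 0.97),
                ("b", "P1", "study", True, 0.9, 0.9699)]
        decisions, _, _ = qc_samples(sample_frame(rows))
        by_id = decisions.set_index("sample_id")
        assert by_id.loc["a", "passed"]
        assert by_id.loc["b", "reason_codes"] == [
            qc_engine.STAGE1_CALLRATE_BELOW_MIN]

    def test_one_primary_reason_in_rule_order(self):
        # fails all three rules; scan failure wins
        rows = [("a", "P1", "study", False, 0.5, 0.5)]
        decisions, _, _ = qc_samples(sample_frame(rows))
        assert decisions.loc[0, "reason_codes"] == [qc_engine.SCAN_FAIL]
        # fails DQC and call rate; DQC wins
        rows = [("a", "P1", "study", True, 0.5, 0.5)]
        decisions, _, _ = qc_samples(sample_frame(rows))
        assert decisions.loc[0, "reason_codes"] == [qc_engine.DQC_BELOW_MIN]

    def test_all_clean_pass_with_empty_reasons(self):
        rows = [(f"s{i}", "P1", "study", True, 0.95, 0.99) for i in range(5)]
        decisions, _, summary = qc_samples(sample_frame(rows))
        assert decisions["passed"].all()
        assert all(r == [] for r in decisions["reason_codes"])
        assert summary["pass_rate"] == 1.0

    def test_order_insensitive_and_duplicate_rejected(self):
        samples, _ = make_pilot_qc_fixture()
        shuffled = samples.sample(frac=1.0, random_state=1).reset_index(drop=True)
        d1, p1, s1 = qc_samples(samples)
        d2, p2, s2 = qc_samples(shuffled)
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(p1, p2)
        assert s1 == s2
        dup = pd.concat([samples, samples.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            qc_samples(dup)

    def test_plate_summary(self):
        rows = [("a", "P1", "study", True, 0.95, 0.99),
                ("b", "P1", "study", True, 0.5, 0.8),   # DQC fail
                ("c", "P2", "study", True, 0.95, 0.98)]
        _, plates, _ = qc_samples(sample_frame(rows))
        p1 = plates.set_index("plate_id").loc["P1"]
        assert p1["pass_rate"] == pytest.approx(0.5)
        # mean stage-1 call rate only over DQC-passing scans
        assert p1["mean_stage1_call_rate"] == pytest.approx(0.99)


class TestStage1CallRate:
    def gm(self):
        calls = np.array([[0, 1], [2, -1], [1, 0], [-1, -1]], dtype=np.int8)
        return GenotypeMatrix(["m1", "m2", "m3", "m4"], ["a", "b"], calls)

    def test_fraction_over_subset(self):
        gm = self.gm()
        rates = stage1_call_rate(gm, ["m1", "m2", "m3"])
        assert rates["a"] == pytest.approx(1.0)
        assert rates["b"] == pytest.approx(2 / 3)

    def test_single_missing_marker_is_zero(self):
        rates = stage1_call_rate(self.gm(), ["m4"])
        assert rates["a"] == 0.0 and rates["b"] == 0.0

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            stage1_call_rate(self.gm(), [])


class TestBestProbeset:
    def manifest(self, rows):
        return pd.DataFrame(
            rows,
            columns=["marker_id", "probeset_id", "classification",
                     "validation_status", "call_rate"],
        )

    def test_classification_rank_wins(self):
        best = select_best_probeset(self.manifest([
            ("m1", "p1", "Other", "validated", 0.99),
            ("m1", "p2", "PolyHighResolution", "validated", 0.90),
        ]))
        assert best.loc[0, "probeset_id"] == "p2"

    def test_call_rate_breaks_ties_then_probeset_id(self):
        best = select_best_probeset(self.manifest([
            ("m1", "p1", "PolyHighResolution", "validated", 0.98),
            ("m1", "p2", "PolyHighResolution", "validated", 0.99),
        ]))
        assert best.loc[0, "probeset_id"] == "p2"
        best = select_best_probeset(self.manifest([
            ("m1", "pB", "NoMinorHom", "validated", 0.99),
            ("m1", "pA", "NoMinorHom", "validated", 0.99),
        ]))
        assert best.loc[0, "probeset_id"] == "pA"

    def test_single_probeset_is_itself(self):
        rows = [("m1", "p1", "OTV", "de_novo", 0.5)]
        best = select_best_probeset(self.manifest(rows))
        assert len(best) == 1 and best.loc[0, "probeset_id"] == "p1"

    def test_one_row_per_marker(self):
        best = select_best_probeset(self.manifest([
            ("m1", "p1", "Other", "validated", 0.99),
            ("m1", "p2", "NoMinorHom", "validated", 0.90),
            ("m2", "p3", "MonoHighResolution", "de_novo", 0.95),
        ]))
        assert sorted(best["marker_id"]) == ["m1", "m2"]


class TestFilterMarkers:
    def test_pilot_fixture_arithmetic(self):
        """The pilot marker table keeps 582,143 of 646,247 (90.08 %) with
        the printed per-rule removal counts."""
        _, markers = make_pilot_qc_fixture()
        best = select_best_probeset(markers)
        assert len(best) == 646247
        decisions, counts = filter_markers(best)
        assert counts["kept"] == 582143
        assert round(100 * counts["kept"] / counts["total"], 2) == 90.08
        assert counts[qc_engine.CLASS_OTHER] == 48083
        assert counts[qc_engine.CLASS_CALLRATE] == 7014
        assert counts[qc_engine.CLASS_OTV] == 1765
        assert counts[qc_engine.CLASS_HEMIZYGOUS] == 181
        assert counts[qc_engine.CLASS_MONO_FAILED_VALIDATION] == 7061
        # partition invariant: kept + removed = total, reasons sum to removed
        assert counts["kept"] + counts["removed"] == counts["total"]
        reason_sum = sum(counts[c] for c in (
            qc_engine.CLASS_OTHER, qc_engine.CLASS_CALLRATE, qc_engine.CLASS_OTV,
            qc_engine.CLASS_HEMIZYGOUS, qc_engine.CLASS_MONO_FAILED_VALIDATION))
        assert reason_sum == counts["removed"]

    def test_mono_kept_only_when_validated_or_de_novo(self):
        df = pd.DataFrame({
            "marker_id": ["m1", "m2", "m3"],
            "probeset_id": ["p1", "p2", "p3"],
            "classification": ["MonoHighResolution"] * 3,
            "validation_status": ["validated", "failed_validation", "de_novo"],
            "call_rate": [0.99] * 3,
        })
        decisions, counts = filter_markers(df)
        by_id = decisions.set_index("marker_id")
        assert by_id.loc["m1", "passed"] and by_id.loc["m3", "passed"]
        assert by_id.loc["m2", "reason_codes"] == [
            qc_engine.CLASS_MONO_FAILED_VALIDATION]

    def test_conditional_keep_flags(self):
        df = pd.DataFrame({
            "marker_id": ["m1", "m2"],
            "probeset_id": ["p1", "p2"],
            "classification": ["OTV", "Hemizygous"],
            "validation_status": ["validated", "validated"],
            "call_rate": [0.99, 0.99],
        })
        _, strict = filter_markers(df)
        assert strict["kept"] == 0
        _, lenient = filter_markers(df, keep_otv=True, keep_hemizygous=True)
        assert lenient["kept"] == 2

    def test_empty_input(self):
        decisions, counts = filter_markers(pd.DataFrame(
            columns=["marker_id", "probeset_id", "classification",
                     "validation_status", "call_rate"]))
        assert counts["kept"] == 0 and counts["removed"] == 0


class TestReproducibility:
    def test_identical_duplicates(self):
        calls = np.array([[0, 0], [1, 1], [2, 2]], dtype=np.int8)
        gm = GenotypeMatrix(["m1", "m2", "m3"], ["a", "a_rep"], calls)
        mean, per = replicate_reproducibility(gm, [("a", "a_rep")])
        assert mean == 1.0

    def test_one_discordant_of_ten(self):
        col = np.arange(10, dtype=np.int8) % 3
        other = col.copy()
        other[0] = (other[0] + 1) % 3
        gm = GenotypeMatrix([f"m{i}" for i in range(10)], ["a", "b"],
                            np.column_stack([col, other]))
        mean, _ = replicate_reproducibility(gm, [("a", "b")])
        assert mean == pytest.approx(0.9)

    def test_missing_excluded_from_denominator(self):
        a = np.array([0, 1, 2, -1], dtype=np.int8)
        b = np.array([0, 1, -1, 2], dtype=np.int8)  # disagreements only at missing
        gm = GenotypeMatrix(["m1", "m2", "m3", "m4"], ["a", "b"],
                            np.column_stack([a, b]))
        mean, _ = replicate_reproducibility(gm, [("a", "b")])
        assert mean == 1.0

    def test_pair_with_no_overlap_excluded(self):
        a = np.array([0, -1], dtype=np.int8)
        b = np.array([-1, 0], dtype=np.int8)
        c = np.array([0, 0], dtype=np.int8)
        gm = GenotypeMatrix(["m1", "m2"], ["a", "b", "c"],
                            np.column_stack([a, b, c]))
        mean, per = replicate_reproducibility(gm, [("a", "b"), ("a", "c")])
        assert len(per) == 1  # the empty-overlap pair is dropped
        with pytest.raises(ValueError):
            replicate_reproducibility(gm, [("a", "b")])


class TestConcordance:
    def gm(self, calls, samples, markers=None):
        markers = markers or [f"m{i}" for i in range(calls.shape[0])]
        return GenotypeMatrix(markers, samples, calls)

    def test_identity_is_one(self, rng):
        calls = rng.integers(0, 3, size=(20, 4)).astype(np.int8)
        a = self.gm(calls, ["s1", "s2", "s3", "s4"])
        b = self.gm(calls.copy(), ["s1", "s2", "s3", "s4"])
        overall, per = concordance(a, b)
        assert overall == 1.0 and (per == 1.0).all()

    def test_one_fully_discordant_sample_of_four(self):
        calls = np.zeros((10, 4), dtype=np.int8)
        ref = calls.copy()
        ref[:, 3] = 1
        overall, _ = concordance(
            self.gm(calls, ["a", "b", "c", "d"]),
            self.gm(ref, ["a", "b", "c", "d"]),
        )
        assert overall == pytest.approx(0.75)

    def test_reference_call_rate_filter(self):
        calls = np.zeros((2, 2), dtype=np.int8)
        ref = np.array([[0, 0], [-1, 1]], dtype=np.int8)  # m2 ref call rate 0.5
        overall, _ = concordance(
            self.gm(calls, ["a", "b"]), self.gm(ref, ["a", "b"]),
            min_ref_call_rate=0.95,
        )
        assert overall == 1.0  # m2 (with its mismatch) excluded entirely

    def test_corruption_strictly_degrades(self, rng):
        calls = rng.integers(0, 3, size=(300, 10)).astype(np.int8)
        gm = self.gm(calls, [f"s{i}" for i in range(10)])
        noisy = corrupt_calls(gm, discordance_rate=0.2, missing_rate=0.0, seed=4)
        overall, _ = concordance(noisy, gm)
        assert overall < 1.0
        noisier = corrupt_calls(gm, discordance_rate=0.5, missing_rate=0.0, seed=4)
        worse, _ = concordance(noisier, gm)
        assert worse < overall

    def test_no_shared_samples_is_error(self):
        a = self.gm(np.zeros((2, 1), dtype=np.int8), ["x"])
        b = self.gm(np.zeros((2, 1), dtype=np.int8), ["y"])
        with pytest.raises(ValueError):
            concordance(a, b)


class TestMafSpectrum:
    def test_bin_boundaries(self):
        # markers engineered to MAF 0.5 (all het), 0, exactly 0.01, 0.049, 0.05
        n = 100
        het = np.ones(n, dtype=np.int8)
        mono = np.zeros(n, dtype=np.int8)
        maf_001 = np.zeros(n, dtype=np.int8); maf_001[0] = 2  # p = 0.01
        maf_0049 = np.zeros(n, dtype=np.int8)
        maf_0049[:5] = 1; maf_0049[5] = 1  # 6/200 = 0.03
        maf_005 = np.zeros(n, dtype=np.int8); maf_005[:10] = 1  # 10/200 = 0.05
        calls = np.vstack([het, mono, maf_001, maf_0049, maf_005])
        gm = GenotypeMatrix([f"m{i}" for i in range(5)],
                            [f"s{i}" for i in range(n)], calls)
        counts = maf_spectrum(gm)
        assert counts == {
            "monomorphic": 1,
            "(0,0.01)": 0,
            "[0.01,0.05)": 2,  # 0.01 inclusive lower bound; 0.03
            "[0.05,0.5]": 2,   # 0.05 inclusive; 0.5
        }
        assert sum(counts.values()) == 5

    def test_missing_ignored_in_frequency(self):
        col = np.array([[1, -1, -1, -1]], dtype=np.int8)  # MAF 0.5 of called
        gm = GenotypeMatrix(["m"], ["a", "b", "c", "d"], col)
        assert maf_spectrum(gm)["[0.05,0.5]"] == 1


class TestDedupReplicates:
    def test_keeps_highest_call_rate(self):
        rates = pd.Series({"a": 0.99, "a_rep": 0.95, "b": 0.9, "b_rep": 0.9})
        drop = qc_engine.dedup_replicates(rates, [["a", "a_rep"], ["b", "b_rep"]])
        assert drop == {"a_rep", "b_rep"}  # tie on b broken by id
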