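"""Unit tests for delta calling, class binning, and spectrum tables."""

import numpy as np
import pytest

from tractflux import (
    TRACT_DESIGNS,
    AssayDesign,
    SpectrumModel,
    aggregate_classes,
    call_delta_units,
    classify_delta,
    compare_spectra,
    simulate_resistant_clones,
    spectrum_from_counts,
    spectrum_table,
)
from tractflux.spectra import CLASS_LABELS, AmbiguousSizingError

GT49 = TRACT_DESIGNS["GT49"]  # unit 2, ref 49, flank 120 -> L_ref 218
ELEVEN = TRACT_DESIGNS["11mer_x4"]

# Integer count compositions consistent with the published percentage rows
# (uniquely determined given the clone totals; verified by brute force in
# test_unique_composition below).
GT49_WT_COUNTS = {"LARGE_DEL": 24, "-1": 2, "+1": 56, "LARGE_ADD": 3}  # n=85
GT49_MUT_COUNTS = {"LARGE_DEL": 35, "-1": 1, "0": 1, "+1": 33, "LARGE_ADD": 5}  # n=75


class TestCallDelta:
    def test_plus_one_with_small_residual(self):
        call = call_delta_units(220.3, GT49)
        assert call.delta == 1
        assert call.residual_bp == pytest.approx(0.3)

    def test_eleven_mer_two_unit_deletion(self):
        size = ELEVEN.ref_length_bp - 22.1
        assert call_delta_units(size, ELEVEN).delta == -2

    def test_half_unit_residual_is_ambiguous(self):
        with pytest.raises(AmbiguousSizingError) as err:
            call_delta_units(GT49.ref_length_bp + 1.0, GT49)
        assert abs(err.value.residual_bp) == pytest.approx(1.0)

    def test_mononucleotide_refused(self):
        with pytest.raises(ValueError, match="capillary"):
            call_delta_units(139.0, TRACT_DESIGNS["mono_G18"])


class TestClassifyDelta:
    @pytest.mark.parametrize(
        "delta,label",
        [(-5, "LARGE_DEL"), (-3, "LARGE_DEL"), (-2, "-2"), (-1, "-1"), (0, "0"),
         (1, "+1"), (2, "+2"), (3, "LARGE_ADD"), (7, "LARGE_ADD")],
    )
    def test_boundaries(self, delta, label):
        assert classify_delta(delta) == label

    def test_monotone_in_delta(self):
        order = [CLASS_LABELS.index(classify_delta(d)) for d in range(-6, 7)]
        assert order == sorted(order)


def clones_from_counts(counts, design, deltas_for_large=(-4, 4)):
    """Exact-size clones realizing a class-count composition."""
    from tractflux import CloneRecord

    delta_of = {"-2": -2, "-1": -1, "0": 0, "+1": 1, "+2": 2,
                "LARGE_DEL": deltas_for_large[0], "LARGE_ADD": deltas_for_large[1]}
    clones = []
    for label, n in counts.items():
        delta = delta_of[label]
        size = design.flank_bp + design.unit_bp * (design.ref_units + delta)
        for i in range(n):
            clones.append(CloneRecord(f"{label}.{i}", "t", size,
                                      true_delta_units=delta, coding_hit=label == "0"))
    return clones


class TestSpectrumTable:
    def test_all_zero_class_is_hundred_percent(self):
        clones = clones_from_counts({"0": 66}, GT49)
        table = spectrum_table(clones, GT49)
        assert table.percentages["0"] == 100
        assert table.n_clones == 66

    def test_published_microsatellite_rows(self):
        wt = spectrum_table(clones_from_counts(GT49_WT_COUNTS, GT49), GT49)
        assert [wt.percentages[c] for c in ("LARGE_DEL", "-1", "+1", "LARGE_ADD")] == [
            28, 2, 66, 4
        ]
        mut = spectrum_table(clones_from_counts(GT49_MUT_COUNTS, GT49), GT49)
        assert [
            mut.percentages[c] for c in ("LARGE_DEL", "-1", "0", "+1", "LARGE_ADD")
        ] == [47, 1, 1, 44, 7]

    def test_unique_composition(self):
        # brute force: the published integer percentages pin down the counts
        def match(n, targets):
            sols = []
            labels = list(targets)
            def rec(i, left, acc):
                if i == len(labels):
                    if left == 0:
                        sols.append(tuple(acc))
                    return
                for c in range(left + 1):
                    if int(np.floor(100 * c / n + 0.5)) == targets[labels[i]]:
                        rec(i + 1, left - c, acc + [c])
            rec(0, n, [])
            return sols

        assert match(85, {"LARGE_DEL": 28, "-1": 2, "+1": 66, "LARGE_ADD": 4}) == [
            (24, 2, 56, 3)
        ]
        assert match(
            75, {"LARGE_DEL": 47, "-1": 1, "0": 1, "+1": 44, "LARGE_ADD": 7}
        ) == [(35, 1, 1, 33, 5)]

    def test_counts_sum_and_percentage_window(self):
        table = spectrum_from_counts(GT49_MUT_COUNTS)
        assert sum(table.class_counts.values()) == table.n_clones
        assert 98 <= sum(table.percentages.values()) <= 102

    def test_ambiguous_clone_propagates_with_offender(self):
        clones = clones_from_counts({"+1": 3}, GT49)
        bad = clones[0]._replace if hasattr(clones[0], "_replace") else None
        from tractflux import CloneRecord

        clones.append(CloneRecord("bad1", "t", GT49.ref_length_bp + 1.0))
        with pytest.raises(AmbiguousSizingError, match="bad1"):
            spectrum_table(clones, GT49)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            spectrum_table([], GT49)


class TestAggregate:
    def test_minisatellite_one_or_two_unit_deletions(self):
        # published 20-mer rows: wt 46/46/8 over 63; mutant 11/81/6/2 over 54
        wt = spectrum_from_counts({"-2": 29, "-1": 29, "+1": 5})
        assert wt.percentages["-2"] == 46 and wt.percentages["-1"] == 46
        assert aggregate_classes(wt, ["-1", "-2"]).percentage == 92
        mut = spectrum_from_counts({"-2": 6, "-1": 44, "0": 3, "+1": 1})
        assert aggregate_classes(mut, ["-1", "-2"]).percentage == 92

    def test_empty_class_set(self):
        table = spectrum_from_counts({"+1": 10})
        assert aggregate_classes(table, []) == (0, 0)

    def test_all_classes_complete(self):
        table = spectrum_from_counts(GT49_WT_COUNTS)
        agg = aggregate_classes(table, list(CLASS_LABELS))
        assert agg.count == 85
        assert 98 <= agg.percentage <= 102

    def test_unknown_class_is_error(self):
        with pytest.raises(ValueError):
            aggregate_classes(spectrum_from_counts({"+1": 5}), ["+9"])


class TestCompareSpectra:
    def test_identical_spectra_statistic_zero(self):
        a = spectrum_from_counts(GT49_WT_COUNTS, tract_id="GT49", strain="a")
        b = spectrum_from_counts(GT49_WT_COUNTS, tract_id="GT49", strain="b")
        assert compare_spectra(a, b).statistic == pytest.approx(0.0)

    def test_hand_pearson_on_published_tables(self):
        a = spectrum_from_counts(GT49_WT_COUNTS, tract_id="GT49")
        b = spectrum_from_counts(GT49_MUT_COUNTS, tract_id="GT49")
        res = compare_spectra(a, b, min_expected=0.0)  # no pooling
        obs = np.array([
            [24, 2, 0, 56, 3],
            [35, 1, 1, 33, 5],
        ], dtype=float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        hand = ((obs - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(hand, rel=1e-12)

    def test_sparse_class_pooling_recorded(self):
        a = spectrum_from_counts({"-1": 40, "0": 1, "+1": 40}, tract_id="t")
        b = spectrum_from_counts({"-1": 35, "+1": 45}, tract_id="t")
        res = compare_spectra(a, b)
        assert "pooled" in res.detail

    def test_single_shared_class_is_error(self):
        a = spectrum_from_counts({"+1": 10}, tract_id="t")
        b = spectrum_from_counts({"+1": 12}, tract_id="t")
        with pytest.raises(ValueError):
            compare_spectra(a, b)


class TestRoundTrip:
    @pytest.mark.parametrize(
        "name,probs",
        [
            ("GT49", {1: 0.5, -1: 0.2, -4: 0.2, 4: 0.1}),
            ("TNR25", {5: 0.6, 6: 0.3, "coding_hit": 0.1}),
            ("11mer_x4", {-2: 0.8, -1: 0.05, "coding_hit": 0.1, 2: 0.05}),
            ("20mer_x3", {-2: 0.45, -1: 0.45, "coding_hit": 0.05, 1: 0.05}),
        ],
    )
    def test_planted_deltas_recovered(self, name, probs):
        design = TRACT_DESIGNS[name]
        sd = min(0.3, design.unit_bp / 10)
        model = SpectrumModel(design=design, class_probs=probs, sizing_sd_bp=sd)
        clones = simulate_resistant_clones(model, 2000, seed=101)
        for clone in clones:
            call = call_delta_units(clone.size_bp, design)
            assert call.delta == clone.true_delta_units

    def test_recovered_proportions_inside_multinomial_ci(self):
        # planted spectrum mimicking the dominant-deletion minisatellite row
        probs = {-2: 0.85, "coding_hit": 0.11, -1: 0.02, 2: 0.02}
        model = SpectrumModel(design=ELEVEN, class_probs=probs, sizing_sd_bp=0.3)
        clones = simulate_resistant_clones(model, 500, seed=7)
        table = spectrum_table(clones, ELEVEN, strain="sim")
        for label, p in (("-2", 0.85), ("0", 0.11), ("-1", 0.02), ("+2", 0.02)):
            se = np.sqrt(p * (1 - p) / 500)
            observed = table.class_counts[label] / 500
            assert abs(observed - p) < 2.58 * se + 1e-9  # 99% CI
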