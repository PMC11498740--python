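"""Technique-comparison percent statistics and repeatability summaries.

The packaged replicate tables (four insect specimens, four digitization
techniques, two operators, three replicates; plus a 20-replicate series of
one distance) are published rounded to 0.01 mm, so derived cells reproduce
the published values to about +-0.01 on their printed scale.
"""

import pytest

from spheremark import (
    MeasurementSeries,
    aggregate_differences,
    build_comparison_rows,
    dispersion,
    global_absolute_summary,
    interoperator_diff,
    pct_diff_to_reference,
    repeatability_summary,
)
from spheremark.comparison_stats import (
    load_bundled_measurements,
    load_bundled_repeatability,
)
from spheremark.errors import EmptyInput, MismatchedKeys, TooFewValues

SPHERE = "Sphere"  # the sphere-of-images triangulation workflow
REF = "uCT"


def _series(values, specimen="S", dist="d", tech="T", op="A"):
    return MeasurementSeries(
        specimen=specimen, distance_label=dist, technique=tech, operator=op,
        values=tuple(values),
    )


@pytest.fixture(scope="module")
def rows():
    return build_comparison_rows(load_bundled_measurements(), REF)


class TestPctDiffToReference:
    def test_published_eupholus_cell(self):
        s = _series((26.68, 26.80, 26.85), tech=SPHERE)
        r = _series((27.34, 27.37, 27.38), tech=REF)
        assert pct_diff_to_reference(s, r) == pytest.approx(-2.14, abs=0.01)

    def test_identity_is_zero(self):
        s = _series((5.0, 5.1))
        assert pct_diff_to_reference(s, s) == 0.0

    def test_one_percent(self):
        assert pct_diff_to_reference(
            _series((101.0,) * 3), _series((100.0,) * 3, tech=REF)
        ) == pytest.approx(1.0)

    def test_mismatched_distance_rejected(self):
        with pytest.raises(MismatchedKeys):
            pct_diff_to_reference(_series((1.0,), dist="a"), _series((1.0,), dist="b"))

    def test_reciprocal_identity(self):
        """(1 + d_ab/100)(1 + d_ba/100) = 1 exactly."""
        a, b = _series((4.93, 5.05, 5.11)), _series((5.23, 5.30, 5.32))
        d_ab = pct_diff_to_reference(a, b)
        d_ba = pct_diff_to_reference(b, a)
        assert (1 + d_ab / 100) * (1 + d_ba / 100) == pytest.approx(1.0, abs=1e-12)


class TestInteroperatorDiff:
    def test_published_eupholus_cell(self):
        a = _series((26.68, 26.80, 26.85), tech=SPHERE, op="A")
        b = _series((26.71, 26.75, 26.80), tech=SPHERE, op="B")
        assert interoperator_diff(a, b) == pytest.approx(0.09, abs=0.01)

    def test_identical_values_zero(self):
        a = _series((5.5, 5.6), op="A")
        b = _series((5.5, 5.6), op="B")
        assert interoperator_diff(a, b) == 0.0

    def test_simple_percent(self):
        a = _series((2.02,) * 3, op="A")
        b = _series((2.00,) * 3, op="B")
        assert interoperator_diff(a, b) == pytest.approx(1.0)

    def test_same_operator_rejected(self):
        s = _series((1.0,))
        with pytest.raises(MismatchedKeys):
            interoperator_diff(s, s)


class TestDispersion:
    def test_published_pooled_cell(self):
        pooled = (26.68, 26.80, 26.85, 26.71, 26.75, 26.80)
        assert dispersion(pooled) == pytest.approx(0.64, abs=0.01)

    def test_constant_values(self):
        assert dispersion((3.3, 3.3, 3.3)) == 0.0

    def test_range_over_mean(self):
        assert dispersion((9.0, 11.0)) == pytest.approx(20.0)

    def test_permutation_and_scaling_invariance(self, rng):
        vals = rng.uniform(4, 6, size=8)
        assert dispersion(vals) == pytest.approx(dispersion(vals[::-1]))
        assert dispersion(vals) == pytest.approx(dispersion(3.7 * vals))

    def test_single_value_rejected(self):
        with pytest.raises(TooFewValues):
            dispersion((1.0,))


class TestAggregateDifferences:
    @pytest.mark.parametrize(
        "specimen, expected",
        [
            ("Eupholus", (-2.29, -2.43, -2.36)),
            ("Lycus", (-0.82, -0.84, -0.83)),
            ("Philodicus", (0.62, 0.44, 0.53)),
            ("Ovalisia", (0.73, 0.33, 0.53)),
        ],
    )
    def test_published_specimen_averages(self, rows, specimen, expected):
        got = aggregate_differences(
            [r for r in rows if r.specimen == specimen], SPHERE
        )
        assert got == pytest.approx(expected, abs=0.01)

    def test_all_zero_diffs(self):
        series = [
            _series((5.0,) * 3, tech=t, op=op)
            for t in (REF, SPHERE)
            for op in ("A", "B")
        ]
        rows = build_comparison_rows(series, REF)
        assert aggregate_differences(rows, SPHERE) == (0.0, 0.0, 0.0)

    def test_empty_rejected(self, rows):
        with pytest.raises(EmptyInput):
            aggregate_differences([r for r in rows if r.specimen == "Lycus"], "nope")


class TestGlobalAbsoluteSummary:
    @pytest.mark.parametrize(
        "technique, avg, cum",
        [(SPHERE, 0.99, 35.57), ("SfM", 1.22, 43.95), ("SL", 1.74, 62.49)],
    )
    def test_published_totals(self, rows, technique, avg, cum):
        got_avg, got_cum = global_absolute_summary(rows, technique)
        assert got_avg == pytest.approx(avg, abs=0.01)
        assert got_cum == pytest.approx(cum, abs=0.05)  # 36 summed rounded cells

    def test_absolute_value_single_row(self):
        series = [
            _series((4.90,) * 3, tech=REF, op="A"),
            _series((4.802,) * 3, tech="T", op="A"),  # -2 percent
        ]
        rows = build_comparison_rows(series, REF)
        assert global_absolute_summary(rows, "T") == pytest.approx((2.0, 2.0))

    def test_cumulated_equals_count_times_average(self, rows):
        avg, cum = global_absolute_summary(rows, SPHERE)
        assert cum == pytest.approx(36 * avg, rel=1e-12)


@pytest.fixture(scope="module")
def table():
    t = load_bundled_repeatability()
    return {
        tech: grp.sort_values("replicate")["value_mm"].to_numpy()
        for tech, grp in t.groupby("technique")
    }


class TestRepeatabilitySummary:

    def test_sphere_series_vs_reference(self, table):
        s = repeatability_summary(table[SPHERE], table[REF])
        assert s.n == 20
        assert s.mean == pytest.approx(5.51, abs=0.01)
        assert s.diff_to_reference_pct == pytest.approx(0.33, abs=0.01)
        assert round(s.stdev, 2) == 0.02
        assert round(s.ci95[0], 2) == 5.48 and round(s.ci95[1], 2) == 5.55

    def test_structured_light_series_vs_reference(self, table):
        s = repeatability_summary(table["SL"], table[REF])
        assert s.diff_to_reference_pct == pytest.approx(1.77, abs=0.01)
        assert round(s.mean, 2) == 5.59

    def test_reference_against_itself(self, table):
        s = repeatability_summary(table[REF], table[REF])
        assert s.diff_to_reference_pct == 0.0
        assert round(s.mean, 2) == 5.50
        assert round(s.ci95[0], 2) == 5.47 and round(s.ci95[1], 2) == 5.52

    def test_identical_values_degenerate(self):
        s = repeatability_summary([5.5] * 20, [5.5] * 20)
        assert s.stdev == 0.0
        assert s.dispersion_pct == 0.0
        assert s.ci95 == (5.5, 5.5)

    def test_too_few_values(self):
        with pytest.raises(TooFewValues):
            repeatability_summary([5.5], [5.5, 5.6])


class TestReproductionSuite:
    """Every published derived cell for the sphere-of-images rows."""

    PRINTED = {
        # (specimen, distance): avg_A, diff_A, avg_B, diff_B, AB, dispersion
        ("Eupholus", "F-B"): (26.78, -2.14, 26.75, -2.54, 0.09, 0.64),
        ("Eupholus", "V-L1"): (9.20, -3.73, 9.23, -3.55, -0.29, 3.26),
        ("Eupholus", "D-V"): (8.22, -1.00, 8.22, -1.20, 0.04, 1.22),
        ("Lycus", "F-B"): (14.77, -0.67, 14.74, -1.18, 0.25, 0.34),
        ("Lycus", "L1-R1"): (5.79, -1.19, 5.84, -0.40, -0.91, 1.38),
        ("Lycus", "L2-R2"): (4.45, -1.11, 4.47, -1.98, -0.37, 0.67),
        ("Lycus", "V2-V3"): (5.40, -0.31, 5.42, 0.18, -0.37, 1.11),
        ("Philodicus", "F-B"): (24.14, 0.01, 24.13, -0.15, 0.03, 0.12),
        ("Philodicus", "L-R"): (10.09, 1.07, 10.08, 0.73, 0.13, 1.69),
        ("Philodicus", "W1-W2"): (4.81, 1.12, 4.77, 0.77, 0.77, 2.30),
        ("Philodicus", "W3-W4"): (4.92, 0.27, 4.89, 0.41, 0.55, 2.65),
        ("Ovalisia", "F-B"): (17.93, 0.98, 17.95, 0.02, -0.13, 0.50),
        ("Ovalisia", "L-R"): (5.54, 0.42, 5.53, 0.67, 0.24, 1.27),
        ("Ovalisia", "U-D"): (4.16, -0.48, 4.18, -0.16, -0.32, 0.96),
        ("Ovalisia", "F-U"): (6.76, -0.20, 6.78, 0.30, -0.20, 1.03),
        ("Ovalisia", "B-U"): (12.33, -0.16, 12.31, -0.19, 0.11, 0.65),
        ("Ovalisia", "L1-L2"): (3.01, 2.50, 2.95, 0.91, 2.04, 3.02),
        ("Ovalisia", "L3-L4"): (2.99, 2.05, 2.96, 0.79, 1.01, 4.37),
    }

    def test_every_published_cell_within_rounding(self, rows):
        checked = 0
        for r in rows:
            if r.technique != SPHERE:
                continue
            pa, da, pb, db, ab, disp = self.PRINTED[(r.specimen, r.distance_label)]
            assert r.avg["A"] == pytest.approx(pa, abs=0.011)
            assert r.avg["B"] == pytest.approx(pb, abs=0.011)
            assert r.diff_to_reference["A"] == pytest.approx(da, abs=0.011)
            assert r.diff_to_reference["B"] == pytest.approx(db, abs=0.011)
            assert r.interoperator_diff_pct == pytest.approx(ab, abs=0.011)
            assert r.dispersion_pct == pytest.approx(disp, abs=0.011)
            checked += 1
        assert checked == len(self.PRINTED)
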