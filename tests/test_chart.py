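"""Risk chart loading, lookup, age imputation, and monotonicity audit."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvdrules.chart import (
    RiskCategory,
    audit_chart_monotonicity,
    bundled_chart_path,
    impute_chart_age,
    load_chart_set,
    lookup_risk,
    synthetic_chart_set,
    write_chart_csv,
)
from cvdrules.errors import ChartFormatError, DomainError, GridIncompleteError

INF = float("inf")


class TestChartLoading:
    def test_bundled_chart_loads_complete(self, chart):
        loaded = load_chart_set(bundled_chart_path())
        # full factorial grid: 2 sex x 2 diabetes x 2 smoking x 4 age x 4 sbp (x 5 tc)
        assert len(loaded.high_info_cells) == 2 * 2 * 2 * 4 * 4 * 5
        assert len(loaded.low_info_cells) == 2 * 2 * 2 * 4 * 4
        assert loaded.high_info_cells == chart.high_info_cells
        assert loaded.low_info_cells == chart.low_info_cells
        assert loaded.cholesterol_units == "mmol/L"

    def test_missing_cell_rejected(self, chart, tmp_path):
        path = tmp_path / "chart.csv"
        write_chart_csv(chart, path)
        lines = path.read_text().splitlines()
        # drop the last data row (a cell), keeping header and comments
        del lines[-1]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(GridIncompleteError, match="missing cell"):
            load_chart_set(path)

    def test_unknown_category_label_rejected(self, chart, tmp_path):
        path = tmp_path / "chart.csv"
        write_chart_csv(chart, path)
        text = path.read_text().replace("GT40", "HIGH", 1)
        path.write_text(text)
        with pytest.raises(ChartFormatError, match="HIGH"):
            load_chart_set(path)

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "chart.csv"
        path.write_text("a,b,c\n1,2,3\n")
        with pytest.raises(ChartFormatError, match="header"):
            load_chart_set(path)


class TestAgeImputation:
    @pytest.mark.parametrize(
        "age,expected",
        [(25, 40), (85, 79), (55, 55), (40, 40), (79, 79), (18, 40), (110, 79)],
    )
    def test_worked_examples(self, age, expected):
        assert impute_chart_age(age) == expected

    @pytest.mark.parametrize("age", [17, 111, -5])
    def test_out_of_domain_rejected(self, age):
        with pytest.raises(DomainError):
            impute_chart_age(age)

    @given(st.floats(min_value=18, max_value=110, allow_nan=False))
    @settings(deadline=None)
    def test_idempotent_with_image_40_79(self, age):
        out = impute_chart_age(age)
        assert 40 <= out <= 79
        assert impute_chart_age(out) == out


class TestLookup:
    def test_pathway_follows_cholesterol_availability(self, chart):
        _, pathway = lookup_risk(chart, "female", False, False, 55, 120, tc=None)
        assert pathway == "low_info"
        _, pathway = lookup_risk(chart, "female", False, False, 55, 120, tc=180)
        assert pathway == "high_info"

    def test_named_cell(self, chart):
        # oldest band, highest sbp band, diabetic male smoker, top tc band:
        # maximal score cell of the synthetic chart
        key = ("male", True, True, (70.0, INF), (180.0, INF), (7.0, INF))
        cat, pathway = lookup_risk(chart, "male", True, True, 75, 190, tc=280)
        assert pathway == "high_info"
        assert cat == chart.high_info_cells[key] == RiskCategory.GT40

    def test_exhaustive_scan_matches_grid(self, chart):
        """Banded lookup agrees with direct dictionary enumeration everywhere."""

        def probe(band, fallback_lo):
            lo, hi = band
            if lo == -INF:
                return hi - 1.0
            if hi == INF:
                return lo + 1.0
            return (lo + hi) / 2.0

        for (sex, dm, sm, ab, sb, tb), expected in chart.high_info_cells.items():
            age = min(max(probe(ab, 40), 40), 79)
            sbp = probe(sb, 90)
            tc_mmol = probe(tb, 3.0)
            cat, pathway = lookup_risk(
                chart, sex, dm, sm, age, sbp, tc=tc_mmol, tc_units="mmol/L"
            )
            assert pathway == "high_info"
            assert cat == expected
        for (sex, dm, sm, ab, sb), expected in chart.low_info_cells.items():
            age = min(max(probe(ab, 40), 40), 79)
            sbp = probe(sb, 90)
            cat, _ = lookup_risk(chart, sex, dm, sm, age, sbp, tc=None)
            assert cat == expected

    def test_lookup_is_pure(self, chart):
        args = ("male", True, False, 62, 145, 230)
        first = lookup_risk(chart, *args[:5], tc=args[5])
        for _ in range(5):
            assert lookup_risk(chart, *args[:5], tc=args[5]) == first

    def test_mg_dl_conversion_at_band_edge(self, chart):
        # 5 mmol/L * 38.67 = 193.35 mg/dL; values either side band differently
        below = lookup_risk(chart, "male", True, True, 75, 190, tc=193.0)[0]
        above = lookup_risk(chart, "male", True, True, 75, 190, tc=194.0)[0]
        exact = lookup_risk(chart, "male", True, True, 75, 190, tc=5.0, tc_units="mmol/L")[0]
        assert above == exact
        assert below <= above


class TestMonotonicityAudit:
    def test_monotone_fixture_clean(self, chart):
        assert audit_chart_monotonicity(chart) == []

    def test_single_inversion_detected_and_counted(self, chart):
        cells = dict(chart.high_info_cells)
        # invert the maximal cell downwards: every in-edge to it becomes a violation
        key = ("male", True, True, (70.0, INF), (180.0, INF), (7.0, INF))
        cells[key] = RiskCategory.LT10
        from cvdrules.chart import RiskChartSet

        broken = RiskChartSet(
            region_label="broken",
            high_info_cells=cells,
            low_info_cells=dict(chart.low_info_cells),
        )
        violations = audit_chart_monotonicity(broken)
        assert violations

        # independent brute-force pairwise scan over both grids
        def brute_count(grid):
            ages = sorted({k[3] for k in grid})
            sbps = sorted({k[4] for k in grid})
            count = 0
            for (sex, dm, sm, ab, sb, *rest), cat in grid.items():
                for (sex2, dm2, sm2, ab2, sb2, *rest2), cat2 in grid.items():
                    if (sex, *rest) != (sex2, *rest2) or cat2 >= cat:
                        continue
                    if (dm, sm, sb) == (dm2, sm2, sb2) and (
                        ages.index(ab2) == ages.index(ab) + 1
                    ):
                        count += 1
                    if (dm, sm, ab) == (dm2, sm2, ab2) and (
                        sbps.index(sb2) == sbps.index(sb) + 1
                    ):
                        count += 1
                    if (sm, ab, sb) == (sm2, ab2, sb2) and (not dm and dm2):
                        count += 1
                    if (dm, ab, sb) == (dm2, ab2, sb2) and (not sm and sm2):
                        count += 1
            return count

        expected = brute_count(cells) + brute_count(broken.low_info_cells)
        assert len(violations) == expected
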