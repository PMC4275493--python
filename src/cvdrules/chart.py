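"""Categorical 10-year CVD risk charts in the WHO/ISH style.

A risk chart is a total lookup table mapping (sex, diabetes, smoking,
age band, systolic-BP band, [total-cholesterol band]) to one of five
ordered 10-year risk categories.  Two grids coexist: the
*high-information* grid, used when a total cholesterol measurement is
available, and the *low-information* grid used otherwise; a lookup
chooses the pathway automatically from cholesterol availability.

The published, calibrated chart values are copyrighted tables that are
not redistributed here.  The package bundles a synthetic, monotone
stand-in chart with the same grid shape (see :func:`synthetic_chart_set`
and ``data/synthetic_chart.csv``); users transcribe a published chart
into the same CSV format to run against real chart values.
"""

from __future__ import annotations

import csv
import enum
import importlib.resources
from dataclasses import dataclass, field
from typing import Optional

from .errors import ChartFormatError, DomainError, GridIncompleteError

__all__ = [
    "RiskCategory",
    "ChartAxis",
    "RiskChartSet",
    "MonotonicityViolation",
    "impute_chart_age",
    "lookup_risk",
    "load_chart_set",
    "audit_chart_monotonicity",
    "synthetic_chart_set",
    "write_chart_csv",
    "bundled_chart_path",
    "MG_PER_DL_PER_MMOL",
]

#: Conversion factor for total cholesterol, mg/dL per mmol/L.
MG_PER_DL_PER_MMOL = 38.67

INF = float("inf")


class RiskCategory(enum.IntEnum):
    """Ordered 10-year CVD risk bands: <10%, 10-20%, 20-30%, 30-40%, >40%."""

    LT10 = 0
    R10_20 = 1
    R20_30 = 2
    R30_40 = 3
    GT40 = 4

    def __str__(self) -> str:  # CSV spelling
        return self.name

    @classmethod
    def parse(cls, label: str) -> "RiskCategory":
        try:
            return cls[label.strip()]
        except KeyError:
            raise ChartFormatError(
                f"unknown risk category label {label!r}; expected one of "
                + "|".join(c.name for c in cls)
            ) from None


Band = tuple[float, float]  # half-open [lo, hi); topmost hi may be +inf


@dataclass(frozen=True)
class ChartAxis:
    """One chart dimension: binary levels or ordered half-open numeric bands."""

    name: str
    bands: tuple = ()  # numeric axes: ordered (lo, hi) tuples
    levels: tuple = ()  # binary axes: e.g. ("female", "male")

    def __post_init__(self):
        if self.bands:
            for (alo, ahi), (blo, bhi) in zip(self.bands, self.bands[1:]):
                if ahi != blo:
                    raise ChartFormatError(
                        f"axis {self.name}: bands not contiguous at {ahi} vs {blo}"
                    )

    def band_of(self, value: float) -> Band:
        """Return the band containing *value* (clamped to the covered domain)."""
        lo0 = self.bands[0][0]
        hi_last = self.bands[-1][1]
        v = max(value, lo0) if lo0 > -INF else value
        if hi_last < INF:
            v = min(v, hi_last - 1e-9)
        for lo, hi in self.bands:
            if lo <= v < hi:
                return (lo, hi)
        raise DomainError(f"axis {self.name}: value {value} outside covered domain")


def band_label(band: Band) -> str:
    """Canonical text form of a half-open band, e.g. ``[140,160)``."""
    lo, hi = band
    lo_s = "-inf" if lo == -INF else f"{lo:g}"
    hi_s = "inf" if hi == INF else f"{hi:g}"
    return f"[{lo_s},{hi_s})"


# Normative default band boundaries (configurable via the chart file).
DEFAULT_AGE_BANDS: tuple[Band, ...] = ((40.0, 50.0), (50.0, 60.0), (60.0, 70.0), (70.0, INF))
DEFAULT_SBP_BANDS: tuple[Band, ...] = ((-INF, 140.0), (140.0, 160.0), (160.0, 180.0), (180.0, INF))
DEFAULT_TC_BANDS: tuple[Band, ...] = ((-INF, 4.0), (4.0, 5.0), (5.0, 6.0), (6.0, 7.0), (7.0, INF))

SEXES = ("female", "male")

# Cell keys: (sex, diabetes, smoking, age_band, sbp_band[, tc_band])
HighKey = tuple[str, bool, bool, Band, Band, Band]
LowKey = tuple[str, bool, bool, Band, Band]


@dataclass
class RiskChartSet:
    """A complete pair of high- and low-information risk grids."""

    region_label: str
    high_info_cells: dict[HighKey, RiskCategory]
    low_info_cells: dict[LowKey, RiskCategory]
    axes: list[ChartAxis] = field(default_factory=list)
    cholesterol_units: str = "mmol/L"

    def __post_init__(self):
        if self.cholesterol_units not in ("mmol/L", "mg/dL"):
            raise ChartFormatError(
                f"cholesterol_units must be 'mmol/L' or 'mg/dL', got {self.cholesterol_units!r}"
            )
        if not self.axes:
            self.axes = [
                ChartAxis("sex", levels=SEXES),
                ChartAxis("diabetes", levels=(False, True)),
                ChartAxis("smoking", levels=(False, True)),
                ChartAxis("age_band", bands=DEFAULT_AGE_BANDS),
                ChartAxis("sbp_band", bands=DEFAULT_SBP_BANDS),
                ChartAxis("tc_band", bands=DEFAULT_TC_BANDS),
            ]
        self._validate_complete()

    def axis(self, name: str) -> ChartAxis:
        for ax in self.axes:
            if ax.name == name:
                return ax
        raise KeyError(name)

    def _iter_keys(self, with_tc: bool):
        age_ax = self.axis("age_band")
        sbp_ax = self.axis("sbp_band")
        tc_ax = self.axis("tc_band")
        for sex in SEXES:
            for dm in (False, True):
                for sm in (False, True):
                    for ab in age_ax.bands:
                        for sb in sbp_ax.bands:
                            if with_tc:
                                for tb in tc_ax.bands:
                                    yield (sex, dm, sm, ab, sb, tb)
                            else:
                                yield (sex, dm, sm, ab, sb)

    def _validate_complete(self):
        for with_tc, cells, grid in (
            (True, self.high_info_cells, "high_info"),
            (False, self.low_info_cells, "low_info"),
        ):
            for key in self._iter_keys(with_tc):
                if key not in cells:
                    raise GridIncompleteError(
                        f"{grid} grid is missing cell {key!r}"
                    )


def impute_chart_age(age: float) -> float:
    """Chart age used for risk lookup: ages below 40 read at 40, above 79 at 79.

    Idempotent; image is [40, 79].  Ages outside [18, 110] are rejected.
    """
    if not 18 <= age <= 110:
        raise DomainError(f"age {age} outside the screening domain [18, 110]")
    return max(40.0, min(79.0, float(age)))


def lookup_risk(
    chart_set: RiskChartSet,
    sex: str,
    diabetes: bool,
    smoking: bool,
    age: float,
    sbp: float,
    tc: Optional[float] = None,
    tc_units: str = "mg/dL",
) -> tuple[RiskCategory, str]:
    """Read the chart cell for one patient.

    Returns ``(category, pathway)`` where pathway is ``"high_info"``
    when a total cholesterol value is supplied and ``"low_info"``
    otherwise.  *tc* is converted to the chart's cholesterol units
    before banding.
    """
    if sex not in SEXES:
        raise DomainError(f"sex must be one of {SEXES}, got {sex!r}")
    chart_age = impute_chart_age(age)
    age_band = chart_set.axis("age_band").band_of(chart_age)
    sbp_band = chart_set.axis("sbp_band").band_of(sbp)
    if tc is None:
        key = (sex, bool(diabetes), bool(smoking), age_band, sbp_band)
        return chart_set.low_info_cells[key], "low_info"
    tc_chart = float(tc)
    if tc_units != chart_set.cholesterol_units:
        if tc_units == "mg/dL":  # chart wants mmol/L
            tc_chart = tc_chart / MG_PER_DL_PER_MMOL
        else:  # chart wants mg/dL
            tc_chart = tc_chart * MG_PER_DL_PER_MMOL
    tc_band = chart_set.axis("tc_band").band_of(tc_chart)
    key = (sex, bool(diabetes), bool(smoking), age_band, sbp_band, tc_band)
    return chart_set.high_info_cells[key], "high_info"


@dataclass(frozen=True)
class MonotonicityViolation:
    pathway: str
    axis: str
    key_lower: tuple
    key_higher: tuple
    category_lower: RiskCategory
    category_higher: RiskCategory


def audit_chart_monotonicity(chart_set: RiskChartSet) -> list[MonotonicityViolation]:
    """List adjacent cell pairs where risk *decreases* as a risk factor rises.

    Checks the sbp-band and age-band axes and the no->yes steps of
    smoking and diabetes, all else fixed.  Advisory only — a published
    chart may legitimately contain non-monotone cells; the report is
    never fatal.
    """
    violations: list[MonotonicityViolation] = []
    for pathway, cells in (
        ("high_info", chart_set.high_info_cells),
        ("low_info", chart_set.low_info_cells),
    ):
        for key, cat in cells.items():
            sex, dm, sm, ab, sb = key[:5]
            rest = key[5:]
            age_ax = chart_set.axis("age_band").bands
            sbp_ax = chart_set.axis("sbp_band").bands
            neighbours = []
            ai = age_ax.index(ab)
            if ai + 1 < len(age_ax):
                neighbours.append(("age_band", (sex, dm, sm, age_ax[ai + 1], sb) + rest))
            si = sbp_ax.index(sb)
            if si + 1 < len(sbp_ax):
                neighbours.append(("sbp_band", (sex, dm, sm, ab, sbp_ax[si + 1]) + rest))
            if not sm:
                neighbours.append(("smoking", (sex, dm, True, ab, sb) + rest))
            if not dm:
                neighbours.append(("diabetes", (sex, True, sm, ab, sb) + rest))
            for axis, nkey in neighbours:
                ncat = cells[nkey]
                if ncat < cat:
                    violations.append(
                        MonotonicityViolation(pathway, axis, key, nkey, cat, ncat)
                    )
    violations.sort(key=lambda v: (v.pathway, v.axis, repr(v.key_lower)))
    return violations


# ---------------------------------------------------------------------------
# Chart file I/O
#
# CSV columns: region,pathway,sex,diabetes,smoking,age_lo,age_hi,sbp_lo,
# sbp_hi,tc_lo,tc_hi,category.  tc columns are empty on low_info rows.
# Lines starting with '#' are comments; '# cholesterol_units=...' sets units.

CHART_COLUMNS = [
    "region", "pathway", "sex", "diabetes", "smoking",
    "age_lo", "age_hi", "sbp_lo", "sbp_hi", "tc_lo", "tc_hi", "category",
]


def _parse_bound(text: str) -> float:
    t = text.strip()
    if t in ("inf", "+inf"):
        return INF
    if t == "-inf":
        return -INF
    try:
        return float(t)
    except ValueError:
        raise ChartFormatError(f"bad numeric band bound {text!r}") from None


def _parse_flag(text: str, column: str) -> bool:
    t = text.strip().lower()
    if t in ("1", "true", "yes"):
        return True
    if t in ("0", "false", "no"):
        return False
    raise ChartFormatError(f"bad flag value {text!r} in column {column}")


def load_chart_set(path) -> RiskChartSet:
    """Load a chart table file, validating grid completeness.

    Band boundaries are taken from the file itself, so transcribed
    charts may use different boundaries than the bundled defaults.
    """
    high: dict[HighKey, RiskCategory] = {}
    low: dict[LowKey, RiskCategory] = {}
    units = "mmol/L"
    region = ""
    age_bands, sbp_bands, tc_bands = set(), set(), set()
    with open(path, newline="") as fh:
        header = None
        for lineno, raw in enumerate(csv.reader(fh), start=1):
            if not raw or (raw[0].startswith("#")):
                directive = ",".join(raw).lstrip("#").strip()
                if directive.startswith("cholesterol_units="):
                    units = directive.split("=", 1)[1].strip()
                continue
            if header is None:
                header = [c.strip() for c in raw]
                if header != CHART_COLUMNS:
                    raise ChartFormatError(
                        f"line {lineno}: header must be {','.join(CHART_COLUMNS)}"
                    )
                continue
            if len(raw) != len(CHART_COLUMNS):
                raise ChartFormatError(f"line {lineno}: expected {len(CHART_COLUMNS)} fields")
            row = dict(zip(CHART_COLUMNS, raw))
            region = row["region"] or region
            sex = row["sex"].strip().lower()
            if sex not in SEXES:
                raise ChartFormatError(f"line {lineno}: sex must be female|male, got {sex!r}")
            dm = _parse_flag(row["diabetes"], "diabetes")
            sm = _parse_flag(row["smoking"], "smoking")
            ab = (_parse_bound(row["age_lo"]), _parse_bound(row["age_hi"]))
            sb = (_parse_bound(row["sbp_lo"]), _parse_bound(row["sbp_hi"]))
            age_bands.add(ab)
            sbp_bands.add(sb)
            cat = RiskCategory.parse(row["category"])
            pathway = row["pathway"].strip()
            if pathway == "high_info":
                if not row["tc_lo"].strip() or not row["tc_hi"].strip():
                    raise ChartFormatError(f"line {lineno}: high_info row lacks tc bounds")
                tb = (_parse_bound(row["tc_lo"]), _parse_bound(row["tc_hi"]))
                tc_bands.add(tb)
                high[(sex, dm, sm, ab, sb, tb)] = cat
            elif pathway == "low_info":
                low[(sex, dm, sm, ab, sb)] = cat
            else:
                raise ChartFormatError(
                    f"line {lineno}: pathway must be high_info|low_info, got {pathway!r}"
                )
    if not high or not low:
        raise ChartFormatError("chart file must contain both high_info and low_info rows")
    axes = [
        ChartAxis("sex", levels=SEXES),
        ChartAxis("diabetes", levels=(False, True)),
        ChartAxis("smoking", levels=(False, True)),
        ChartAxis("age_band", bands=tuple(sorted(age_bands))),
        ChartAxis("sbp_band", bands=tuple(sorted(sbp_bands))),
        ChartAxis("tc_band", bands=tuple(sorted(tc_bands))),
    ]
    return RiskChartSet(
        region_label=region,
        high_info_cells=high,
        low_info_cells=low,
        axes=axes,
        cholesterol_units=units,
    )


def write_chart_csv(chart_set: RiskChartSet, path) -> None:
    """Write a chart set back out in the chart table format."""

    def fmt(x: float) -> str:
        if x == INF:
            return "inf"
        if x == -INF:
            return "-inf"
        return f"{x:g}"

    with open(path, "w", newline="") as fh:
        fh.write(f"# cholesterol_units={chart_set.cholesterol_units}\n")
        w = csv.writer(fh)
        w.writerow(CHART_COLUMNS)
        for (sex, dm, sm, ab, sb, tb), cat in sorted(
            chart_set.high_info_cells.items(), key=lambda kv: repr(kv[0])
        ):
            w.writerow([chart_set.region_label, "high_info", sex, int(dm), int(sm),
                        fmt(ab[0]), fmt(ab[1]), fmt(sb[0]), fmt(sb[1]),
                        fmt(tb[0]), fmt(tb[1]), cat.name])
        for (sex, dm, sm, ab, sb), cat in sorted(
            chart_set.low_info_cells.items(), key=lambda kv: repr(kv[0])
        ):
            w.writerow([chart_set.region_label, "low_info", sex, int(dm), int(sm),
                        fmt(ab[0]), fmt(ab[1]), fmt(sb[0]), fmt(sb[1]),
                        "", "", cat.name])


def synthetic_chart_set(region_label: str = "synthetic-monotone") -> RiskChartSet:
    """Construct the bundled synthetic, monotone stand-in chart.

    Cell values come from a linear score over band indices with
    positive weights for every risk factor, so risk is monotone
    non-decreasing along every audited axis by construction.  The
    values are NOT the published WHO/ISH chart values.
    """
    def category(score: float) -> RiskCategory:
        if score < 4.0:
            return RiskCategory.LT10
        if score < 6.0:
            return RiskCategory.R10_20
        if score < 7.5:
            return RiskCategory.R20_30
        if score < 9.0:
            return RiskCategory.R30_40
        return RiskCategory.GT40

    high: dict[HighKey, RiskCategory] = {}
    low: dict[LowKey, RiskCategory] = {}
    for sex in SEXES:
        male = 0.6 if sex == "male" else 0.0
        for dm in (False, True):
            for sm in (False, True):
                for ai, ab in enumerate(DEFAULT_AGE_BANDS):
                    for si, sb in enumerate(DEFAULT_SBP_BANDS):
                        base = 1.2 * ai + 1.1 * si + 1.5 * dm + 1.0 * sm + male
                        for ti, tb in enumerate(DEFAULT_TC_BANDS):
                            high[(sex, dm, sm, ab, sb, tb)] = category(base + 0.8 * ti)
                        # low-info grid carries the mean cholesterol contribution
                        low[(sex, dm, sm, ab, sb)] = category(base + 1.6)
    return RiskChartSet(region_label=region_label, high_info_cells=high, low_info_cells=low)


def bundled_chart_path():
    """Path to the bundled synthetic chart CSV (importable package data)."""
    return importlib.resources.files("cvdrules").joinpath("data/synthetic_chart.csv")
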