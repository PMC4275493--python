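"""Exception hierarchy for cvdrules."""


class CvdRulesError(Exception):
    """Base class for all package errors."""


class DomainError(CvdRulesError, ValueError):
    """An input value lies outside its clinically valid domain."""


class ChartFormatError(CvdRulesError, ValueError):
    """A risk-chart file does not conform to the chart table format."""


class GridIncompleteError(ChartFormatError):
    """A risk-chart grid is missing at least one cell combination."""


class JoinError(CvdRulesError, ValueError):
    """Follow-up records could not be joined to assessments."""

    def __init__(self, orphan_ids):
        self.orphan_ids = sorted(orphan_ids)
        super().__init__(
            "follow-up records with no matching assessment: "
            + ", ".join(self.orphan_ids)
        )
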