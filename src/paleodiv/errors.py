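"""Exception types shared across the pipeline."""


class PaleodivError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(PaleodivError):
    """A configuration object failed validation.

    ``fields`` lists the offending field names.
    """

    def __init__(self, message, fields=()):
        super().__init__(message)
        self.fields = tuple(fields)


class UnmappedTaxonError(PaleodivError):
    """A raw taxon name has no entry in the harmonization table."""

    def __init__(self, taxon, record_id):
        super().__init__(
            f"taxon {taxon!r} in record {record_id!r} is not covered by the "
            "harmonization table"
        )
        self.taxon = taxon
        self.record_id = record_id


class InvalidRegionMapError(PaleodivError):
    """The region map contains overlapping rectangles."""


class UnassignedRegionError(PaleodivError):
    """A site falls in no region rectangle."""


class CalibrationRangeError(PaleodivError):
    """A radiocarbon age falls outside the calibration curve support."""


class MonotoneSamplingError(PaleodivError):
    """Monotone conditioning of control ages failed for a record."""


class ZeroVarianceError(PaleodivError):
    """A region has zero variance and cannot be standardized."""


class StageOrderError(PaleodivError):
    """A CLI stage was invoked before its upstream stage produced output."""

    def __init__(self, stage, missing_stage):
        super().__init__(
            f"stage {stage!r} requires output of stage {missing_stage!r}; "
            f"run {missing_stage!r} first"
        )
        self.stage = stage
        self.missing_stage = missing_stage
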