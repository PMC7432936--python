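"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A study or scene configuration is invalid."""


class PlacementError(RuntimeError):
    """Monitoring-site placement failed for a site type after bounded retries."""


class ScheduleError(ValueError):
    """A campaign schedule is inconsistent (e.g. overlapping periods)."""


class DataError(ValueError):
    """An input layer or series is missing required attributes."""


class AlignmentError(ValueError):
    """A measurement period has no co-temporal reference period."""


class SchemaError(KeyError):
    """A predictor matrix is missing a column required by a model."""


class SingularDesignError(ValueError):
    """The design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; dependent columns: "
            + ", ".join(map(str, self.columns))
        )
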