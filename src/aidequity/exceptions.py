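"""Package-specific exception types."""


class ConfigurationError(ValueError):
    """A configuration value violates a documented constraint."""


class GenerationError(RuntimeError):
    """The synthetic-data generator produced an impossible quantity."""


class CollinearityError(RuntimeError):
    """The regression design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


class FixtureError(RuntimeError):
    """A packaged data fixture failed an integrity check."""
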