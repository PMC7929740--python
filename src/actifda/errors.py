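"""Exception hierarchy shared across the pipeline stages."""


class ActifdaError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(ActifdaError):
    """A configuration value is outside its documented range."""


class DataIntegrityError(ActifdaError):
    """Input data violate a structural contract (duplicates, bad schema)."""


class DegenerateInputError(ActifdaError):
    """Too little data for the requested computation."""


class CollinearityError(ActifdaError):
    """Rank-deficient design matrix; carries the offending column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; offending columns: "
            + ", ".join(self.columns)
        )
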