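"""Exception hierarchy: configuration, schema, validation, and degenerate-statistic errors."""


class HybridMSError(Exception):
    """Base class for all package errors."""


class ConfigError(HybridMSError, ValueError):
    """A configuration value is out of its admissible range."""


class SchemaError(HybridMSError, ValueError):
    """A table is missing required columns or has an unrecognisable layout."""


class ValidationError(HybridMSError, ValueError):
    """Cell-level contents violate a domain invariant (range, duplication)."""


class MonotonicityError(ValidationError):
    """Outcome labels decrease across horizons within a record."""

    def __init__(self, record_ids):
        self.record_ids = list(record_ids)
        super().__init__(
            f"non-monotone outcome labels for {len(self.record_ids)} record(s): "
            f"{self.record_ids[:10]}"
        )


class UndefinedAUCError(HybridMSError, ValueError):
    """AUC requested on a label vector with a single class."""

    def __init__(self, n_pos, n_neg):
        self.n_pos = int(n_pos)
        self.n_neg = int(n_neg)
        super().__init__(
            f"AUC undefined: {self.n_pos} positive and {self.n_neg} negative labels"
        )


class UndefinedConcordanceError(HybridMSError, ValueError):
    """Concordance requested on fewer than two unitary predictions."""


class EmptyResultError(HybridMSError, ValueError):
    """An aggregation was asked for but no eligible records remain."""
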