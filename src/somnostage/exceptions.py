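"""Exception hierarchy. Configuration errors are caller mistakes; data errors
describe input that cannot be processed; undefined-metric errors mark nights
for which a sleep metric has no value (e.g. SOL with no N2 epoch)."""


class SomnostageError(Exception):
    pass


class ConfigurationError(SomnostageError):
    """Invalid parameter or configuration (e.g. filter edge above Nyquist)."""


class DataError(SomnostageError):
    """Input data violates a precondition (e.g. too short, rank-deficient)."""


class UnsupportedOperationError(SomnostageError):
    """Requested operation is deliberately not supported (e.g. upsampling)."""


class UndefinedMetricError(SomnostageError):
    """A sleep metric is undefined for this hypnogram (e.g. no N2 epoch)."""
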