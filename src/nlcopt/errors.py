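"""Exception hierarchy shared across the package."""


class NlcoptError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(NlcoptError):
    """A table is missing a required column or has the wrong layout."""


class ValidationError(NlcoptError):
    """A value violates a domain invariant (range, sign, consistency)."""


class UnsupportedDesignError(NlcoptError):
    """Requested experimental design is outside what the package builds."""


class InfeasibleSplitError(NlcoptError):
    """A cross-validation split cannot be constructed (e.g. k > n)."""


class TrainingFailureError(NlcoptError):
    """Network training diverged (non-finite loss)."""


class CorruptedFixtureError(NlcoptError):
    """A packaged data fixture failed its checksum."""


class FitFailureError(NlcoptError):
    """A model fit could not be computed at all."""
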