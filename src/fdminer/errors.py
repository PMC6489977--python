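"""Exception hierarchy for fdminer."""


class FDMinerError(Exception):
    """Base class for all fdminer errors."""


class MalformedFileError(FDMinerError):
    """The input file cannot be parsed into a rectangular relation."""


class SchemaError(FDMinerError):
    """An attribute reference or schema invariant is violated."""


class SyntheticSpecError(FDMinerError):
    """A synthetic-relation specification is internally inconsistent."""


class GenerationError(FDMinerError):
    """Synthetic data generation failed to satisfy its postcondition."""


class KeyExplosionError(FDMinerError):
    """The number of candidate keys exceeded the configured cap."""
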