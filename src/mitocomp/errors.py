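"""Exception hierarchy shared across the toolkit."""


class MitocompError(Exception):
    """Base class for all toolkit errors."""


class ParseError(MitocompError):
    """A file could not be parsed; the message names the offending feature."""


class ConsistencyError(MitocompError):
    """Sequence and annotation disagree (lengths, coordinates out of range)."""


class LookupFailure(MitocompError):
    """A requested gene or taxon is absent from a record."""


class SaturationError(MitocompError):
    """A distance is undefined because substitutions are saturated."""


class HomologyError(MitocompError):
    """Alignment identity too low to trust a homology-based projection."""


class ArrangementError(MitocompError):
    """Gene-order extraction failed (missing or duplicated genes)."""


class SimSpecError(MitocompError):
    """A synthetic-cohort specification is internally inconsistent."""


class ConfigError(MitocompError):
    """A pipeline run configuration is invalid."""
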