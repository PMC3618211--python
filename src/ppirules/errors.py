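"""Exception hierarchy shared by all modules."""


class PPIRulesError(Exception):
    """Base class for all package errors."""


class CorpusParseError(PPIRulesError):
    """Malformed corpus input (XML syntax, bad offsets); carries position info."""


class CorpusIntegrityError(PPIRulesError):
    """Structurally valid corpus that violates referential integrity."""


class NormalizationError(PPIRulesError):
    """Text normalization cannot proceed (e.g. overlapping entity spans)."""


class AlignmentError(PPIRulesError):
    """A dependency parse does not align with its masked sentence."""


class ClassificationError(PPIRulesError):
    """A candidate pair could not be classified (e.g. missing parse)."""


class ConfigError(PPIRulesError):
    """Invalid configuration values."""
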