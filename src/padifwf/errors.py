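"""Exception taxonomy shared across the workflow."""


class PadifError(Exception):
    """Base class for all package errors."""


class ParseError(PadifError):
    """Malformed record in a docking-output file; message names the line/block."""


class SchemaError(PadifError):
    """A record is missing a required column or field."""


class EmptyInputError(PadifError):
    """An operation received an empty collection it cannot act on."""


class ConsistencyError(PadifError):
    """Cross-record invariant violated (mixed molecule ids, unknown atom ids, ...)."""


class VocabularyError(PadifError):
    """Residue name or atom class outside the declared vocabulary."""


class LayoutError(PadifError):
    """Fingerprint layout mismatch between a sparse map and a dense vector."""


class CapacityError(PadifError):
    """A sampling pool is smaller than the requested draw."""


class ParameterError(PadifError):
    """A parameter is outside its documented domain."""


class SplitInfeasibleError(PadifError):
    """A grouped split cannot be made with fewer than two groups."""


class StagedDependencyError(PadifError):
    """A pipeline stage was invoked before the stage that produces its input."""
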