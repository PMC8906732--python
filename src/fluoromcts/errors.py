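"""Exception hierarchy shared across the package."""


class FluoromctsError(Exception):
    """Base class for all package errors."""


class InvalidSmilesError(FluoromctsError):
    """The string is not a chemically valid SMILES."""


class ElementConstraintError(FluoromctsError):
    """The molecule contains an element outside the allowed alphabet."""


class StructureError(FluoromctsError):
    """A structure-level operation (e.g. kekulization) failed."""


class VocabularyError(FluoromctsError):
    """A token is not part of the model vocabulary."""


class InputError(FluoromctsError):
    """A precondition on user-supplied input was violated."""


class TDLogParseError(FluoromctsError):
    """A TD-DFT output log could not be parsed; the message names the line."""


class SearchStateError(FluoromctsError):
    """The search tree reached an inconsistent internal state."""


class ExpansionError(FluoromctsError):
    """Attempted to expand a terminal or already-expanded node."""


class FilterInapplicableError(FluoromctsError):
    """A filter was applied to a profile whose evaluation failed."""


class UndefinedCorrelationError(FluoromctsError):
    """Pearson correlation is undefined (zero variance)."""


class ConfigError(FluoromctsError):
    """A run configuration is invalid."""


class LedgerFormatError(FluoromctsError):
    """A ledger CSV row is malformed; the message names the line number."""
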