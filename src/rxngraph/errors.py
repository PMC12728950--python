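"""Exception hierarchy for the toolkit."""


class RxnGraphError(Exception):
    """Base class for all toolkit errors."""


class ParseError(RxnGraphError):
    """Unparsable linear notation (SMILES)."""


class ValidationError(RxnGraphError):
    """Semantically invalid input (duplicate atom maps, malformed rule, ...)."""


class SerializationError(RxnGraphError):
    """A graph state that has no valid textual representation."""


class SchemaError(RxnGraphError):
    """Malformed GML rule text (dangling endpoints, unknown labels, ...)."""


class ITSError(RxnGraphError):
    """ITS construction refused (unbalanced record) or reversion failed."""


class StitchError(RxnGraphError):
    """No valid alignment while concatenating mechanism steps."""


class RuleError(RxnGraphError):
    """Invalid rule span or empty reaction center."""


class RouteError(RxnGraphError):
    """Route search contract violations (e.g. negative scorer costs)."""
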