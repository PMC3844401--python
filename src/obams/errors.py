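"""Exception hierarchy shared across the package."""


class ObamsError(Exception):
    """Base class for all package errors."""


class OboParseError(ObamsError):
    """Malformed OBO input; message names the offending line."""


class OntologyError(ObamsError):
    """Structural problem in an ontology graph (dangling edge, cycle, ...)."""


class ValidationError(ObamsError):
    """Invalid user input: bad thresholds, unmapped labels, missing data."""


class QueryError(ObamsError):
    """A signature query that cannot be answered (unknown class, bad pair)."""
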