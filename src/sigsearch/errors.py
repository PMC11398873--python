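"""Exception hierarchy.

``InputError`` covers malformed user inputs (files, annotations, ids);
``ValidationError`` covers domain invariant violations (signature sizes,
panel structure); ``ScoringError`` covers failures inside a signature
search method for a specific drug. The CLI maps the first two to exit
code 1 (user error) and anything else to 2 (internal error).
"""


class SigsearchError(Exception):
    """Base class for all package errors."""


class InputError(SigsearchError):
    """A user-supplied file or value could not be interpreted."""


class ValidationError(SigsearchError):
    """A domain invariant does not hold for the given inputs."""


class ScoringError(SigsearchError):
    """A signature search method could not produce a score."""
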