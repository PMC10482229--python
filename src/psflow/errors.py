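"""Exception hierarchy.

``PsfError`` is the base for everything the library raises on purpose;
the CLI maps it to exit code 2 (data/validation error) so callers can
distinguish bad inputs from bugs.
"""


class PsfError(Exception):
    """Base class for all psflow errors."""


class ValidationError(PsfError):
    """An input object violates a model invariant or precondition."""


class ParseError(PsfError):
    """A file could not be parsed (malformed KGML, bad table row, bad JSON)."""
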