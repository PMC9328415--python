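"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`TreeError`,
so callers can catch one type. Subclasses additionally derive from the closest
builtin (``ValueError``, ``KeyError``) so idiomatic except-clauses keep working.
"""


class TreeError(Exception):
    """Base class for all errors raised by phylokit."""


class TreeStructureError(TreeError):
    """An operation would corrupt the tree (cycle, detached root, wrong tree...)."""


class UnsupportedTopologyError(TreeError):
    """The tree's branching pattern is outside an operation's domain."""


class UndefinedStatisticError(TreeError):
    """A statistic has no defined value on this input (e.g. no measured edges)."""


class LabelLookupError(TreeError, KeyError):
    """One or more requested leaf labels are absent or ambiguous."""

    def __init__(self, message: str, missing=()):
        super().__init__(message)
        self.missing = tuple(missing)

    def __str__(self) -> str:  # KeyError quotes its arg; we want the message
        return self.args[0]


class TreeParseError(TreeError, ValueError):
    """Malformed input text. ``offset`` is the 0-based character position, if known."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at character {offset})"
        super().__init__(message)
        self.offset = offset


class NotUltrametricError(TreeError, ValueError):
    """Leaf depths deviate from the tree height beyond tolerance.

    ``max_deviation`` reports the largest |leaf depth - height| observed.
    """

    def __init__(self, message: str, max_deviation: float):
        super().__init__(message)
        self.max_deviation = max_deviation
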