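"""Exception hierarchy.

Everything raised deliberately by the package derives from
:class:`PlastEditError`, so callers can catch one type at the CLI boundary.
"""


class PlastEditError(Exception):
    """Base class for all plastedit errors."""


class FormatError(PlastEditError):
    """A file does not conform to the expected dialect (missing column,
    unknown strand symbol, unparsable field)."""


class ValidationError(PlastEditError):
    """Well-formed input with invalid content (negative count, exon outside
    its gene span, duplicated site key)."""


class ContractError(PlastEditError):
    """An operation was called outside its stated preconditions."""


class RangeError(PlastEditError):
    """A coordinate falls outside the reference sequence."""


class MissingDataError(PlastEditError):
    """A required efficiency or sample is absent."""


class UndefinedEfficiencyError(PlastEditError):
    """Editing efficiency requested at a position with zero coverage."""


class ConfigError(PlastEditError):
    """Inconsistent or incomplete run configuration."""


class GenerationError(PlastEditError):
    """An infeasible simulation request (e.g. more sites than available Cs)."""
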