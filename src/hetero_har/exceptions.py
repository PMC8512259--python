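"""Exception hierarchy.

Everything derives from ``ValueError`` so callers that do not care about the
fine distinctions can catch one base class.
"""


class VocabularyError(ValueError):
    """A task label outside the ten-task vocabulary was supplied."""


class UnitError(ValueError):
    """An acceleration unit tag is unknown or inconsistent."""


class ScenarioError(ValueError):
    """A scenario specification violates its own constraints."""


class InsufficientDataError(ValueError):
    """Too few samples for the requested operation."""


class ConfigError(ValueError):
    """An experiment configuration is inconsistent."""


class DataError(ValueError):
    """Input data violate an experiment's preconditions."""
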