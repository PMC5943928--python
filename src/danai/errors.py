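"""Exception hierarchy.

Everything the library raises deliberately derives from :class:`DanaiError`,
so callers (and the CLI) can separate user/input errors from genuine bugs.
"""


class DanaiError(Exception):
    """Base class for all errors raised by this package."""


class NotationError(DanaiError):
    """Malformed or semantically invalid interaction expression."""


class TypingError(DanaiError):
    """Atom labelling / chemical-group perception failure."""


class TopologyError(DanaiError):
    """Invalid molecular topology (bonds, molecule membership, schema)."""


class TrajectoryError(DanaiError):
    """Configuration/trajectory file problem (truncation, drift, mismatch)."""


class DetectionError(DanaiError):
    """Interaction-detection failure (bad criteria, missing roles...)."""


class MatchingError(DanaiError):
    """Motif counting cannot proceed (unexpanded wildcard, size refusal...)."""


class StatisticsError(DanaiError):
    """Undefined statistical quantity (e.g. correlation of a constant series)."""


class PlacementError(DanaiError):
    """A synthetic-configuration builder could not realise the requested layout."""
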