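"""Exception hierarchy.

Every error raised by the package derives from :class:`BrainModesError`,
so callers can catch one type at pipeline boundaries while still being
able to distinguish parse, alignment, contract, and numerical failures.
"""


class BrainModesError(Exception):
    """Base class for all package errors."""


class ParseError(BrainModesError):
    """Malformed input file (ragged rows, non-numeric cells, duplicate ids)."""


class ConfigError(BrainModesError):
    """Invalid or incomplete pipeline configuration."""


class AlignmentError(BrainModesError):
    """Node or subject identifiers do not line up between inputs."""


class ContractError(BrainModesError):
    """An input violates a documented precondition (e.g. not z-scored)."""


class NumericalError(BrainModesError):
    """Non-finite values or a failed numerical routine."""


class ZeroVarianceNode(ContractError):
    """A node's time course has zero variance and cannot be standardized."""

    def __init__(self, node_id):
        self.node_id = node_id
        super().__init__(f"node {node_id!r} has zero variance over time")


class UndefinedSimilarity(BrainModesError):
    """Similarity undefined because one of the inputs has zero variance."""
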