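"""Exception hierarchy.

Every anticipated failure mode raises a distinct subclass of
:class:`FoldscreenError` so callers (and the CLI) can map failures to
diagnostics without string matching.
"""


class FoldscreenError(Exception):
    """Base class for all errors raised by this package."""


class StructureReadError(FoldscreenError):
    """A coordinate file is missing, unreadable, or fails to parse."""


class EmptyStructureError(FoldscreenError):
    """A structure contains no chains (or no residues/atoms)."""


class DuplicateChainError(FoldscreenError):
    """Two chains in one model share a chain identifier."""


class StructureWriteError(FoldscreenError):
    """A coordinate file could not be written."""


class ConfidenceFormatError(FoldscreenError):
    """A confidence file lacks required keys or has malformed values."""


class ConfidenceMismatchError(FoldscreenError):
    """Confidence data is inconsistent with the paired structure
    (length mismatch, non-square PAE, out-of-range values)."""


class SingleChainError(FoldscreenError):
    """An inter-chain operation was requested on a single-chain model."""


class ParamsMismatchError(FoldscreenError):
    """Contact sets being combined were extracted with different parameters."""


class MissingScoreError(FoldscreenError):
    """A ranking key is absent from one or more metric rows."""


class EmptyScreenError(FoldscreenError):
    """A screen manifest has no entries."""


class DegenerateGeometryError(FoldscreenError):
    """Too few or collinear points for a rigid-body superposition."""


class PairingError(FoldscreenError):
    """A chain pairing cannot be resolved in one of the models."""


class SelectorError(FoldscreenError):
    """An atom selector resolves to zero or multiple atoms."""


class AssemblyError(FoldscreenError):
    """An assembly step references a component that is not placed."""


class GeneratorError(FoldscreenError):
    """A synthetic-fixture specification is infeasible."""
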