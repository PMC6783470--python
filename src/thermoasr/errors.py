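"""Exception hierarchy shared across the package."""


class ThermoASRError(Exception):
    """Base class for all package errors."""


class AlignmentShapeError(ThermoASRError):
    """Rows of an alignment have unequal lengths."""


class AlphabetError(ThermoASRError):
    """A sequence contains a character outside the allowed alphabet."""


class IdentityError(ThermoASRError):
    """Duplicate or missing identifiers."""


class TreeError(ThermoASRError):
    """Malformed tree: unbalanced Newick, missing/negative lengths, bad structure."""


class RangeError(ThermoASRError):
    """A numeric value lies outside its allowed range."""


class DegenerateInputError(ThermoASRError):
    """Input is formally valid but carries no usable signal."""


class SingularFitError(ThermoASRError):
    """A regression cannot be fitted (no variance in the predictor)."""


class InsufficientDataError(ThermoASRError):
    """Too few observations for the requested fit."""


class ClassificationError(ThermoASRError):
    """A residue cannot be assigned to a charged/polar/other class."""
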