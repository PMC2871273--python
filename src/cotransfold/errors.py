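"""Exception types shared across the package."""


class CotransfoldError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CotransfoldError, ValueError):
    """An argument violates a documented precondition."""


class MalformedStructureError(CotransfoldError):
    """A structure file or object is missing required backbone atoms."""


class EmptyLibraryError(CotransfoldError):
    """Fragment harvesting produced no usable torsion windows."""


class NoMoveError(CotransfoldError):
    """A Monte Carlo stage has no eligible insertion window."""


class GenerationError(CotransfoldError):
    """A synthetic fixture could not be built within the retry budget."""


class FixtureError(CotransfoldError):
    """A packaged results fixture failed its integrity check."""
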