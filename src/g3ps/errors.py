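"""Exception hierarchy for the g3ps package."""


class G3PSError(Exception):
    """Base class for all g3ps errors."""


class ParseError(G3PSError):
    """A pharmacophore file could not be parsed.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NoSeedError(G3PSError):
    """Fewer than three label-compatible feature pairs exist; no seed guess."""


class UnderdeterminedError(G3PSError):
    """Fewer than three point pairs were given to the superposition solver."""


class DegenerateGeometryError(G3PSError):
    """Point configuration is collinear or coincident; the rotation is ambiguous."""


class AmbiguousAlignmentError(G3PSError):
    """Query size minus the omitted-feature budget is below three.

    Three matched pairs are the minimum that determines an unambiguous
    rigid 3D transformation.
    """


class FixtureError(G3PSError):
    """Synthetic fixture generation failed (e.g. packing constraint unmet)."""
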