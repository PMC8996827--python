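"""Exception hierarchy for reaction parsing, encoding and modelling."""


class DrfpError(Exception):
    """Base class for all package-specific errors."""


class MalformedReaction(DrfpError):
    """Reaction SMILES does not contain exactly two ``>`` separators."""


class EmptySide(DrfpError):
    """A reaction with no left-side molecules or no product molecules."""


class UnparsableMolecule(DrfpError):
    """A molecule SMILES rejected by RDKit.

    Carries the offending component and, when available, the 1-based
    line/row number of the input it came from.
    """

    def __init__(self, component: str, line: int | None = None,
                 detail: str = ""):
        self.component = component
        self.line = line
        where = f" (line {line})" if line is not None else ""
        msg = f"unparsable molecule SMILES {component!r}{where}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class MissingColumn(DrfpError):
    """A named column is absent from a reaction table."""


class UnknownFormat(DrfpError):
    """Unrecognized fingerprint serialization format."""


class IOFailure(DrfpError):
    """Filesystem-level read/write failure."""


class EmptyTrainingSet(DrfpError):
    """A model was fitted on zero rows."""


class TooFewRows(DrfpError):
    """Not enough rows to carve a non-empty validation split."""


class LengthMismatch(DrfpError):
    """Paired label vectors differ in length."""


class ConstantTruth(DrfpError):
    """R-squared is undefined for a constant truth vector."""


class LabelEncodingError(DrfpError):
    """Class labels could not be encoded as 0..C-1, or C < 2."""


class PoolExhausted(DrfpError):
    """The substituent pool cannot supply enough distinct instances."""


class IndexOutOfRange(DrfpError, IndexError):
    """Bit index outside [0, d)."""
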