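"""Exception hierarchy for the aptazyme design pipeline.

Every error raised by the package derives from :class:`AptazymeError`, so
callers (and the CLI) can catch a single base class.  Misfolded constructs are
*not* errors: they are flagged on the record and excluded downstream.
"""


class AptazymeError(Exception):
    """Base class for all package errors."""


# --- scaffold / sequence handling ---
class InvalidLoop(AptazymeError):
    """A loop insert is empty or otherwise unusable."""


class InvalidAlphabet(AptazymeError):
    """A sequence contains characters outside {A, C, G, U} (after T→U)."""


class BackendError(AptazymeError):
    """The requested folding backend is unavailable or failed."""


class InputTooLong(AptazymeError):
    """Sequence exceeds the folder's configured maximum length."""


# --- encoder ---
class EncodingOverflow(AptazymeError):
    """A stem-loop walk does not fit in the configured number of rows."""


class EmptyBatch(AptazymeError):
    """batch_encode received no records."""


# --- models ---
class ShapeError(AptazymeError):
    """Mismatched tensor/label shapes."""


class LabelError(AptazymeError):
    """A training label is non-finite."""


class MetadataError(AptazymeError):
    """Encoder metadata does not match the model's training metadata."""


# --- facs_seq ---
class BoundaryError(AptazymeError):
    """Bin boundaries are not strictly increasing."""


class EmptyInput(AptazymeError):
    """No reads / records supplied."""


# --- designer ---
class AnnotationError(AptazymeError):
    """A binding-bulge annotation falls outside the aptamer sequence."""


class NoBulge(AptazymeError):
    """No internal loop/bulge could be located in the aptamer structure."""


class ConfigError(AptazymeError):
    """Invalid enumeration / run configuration."""


class SelectionError(AptazymeError):
    """Requested more candidates than are scoreable."""

    def __init__(self, msg: str, scoreable: int | None = None):
        super().__init__(msg)
        self.scoreable = scoreable


# --- evaluation ---
class DegenerateData(AptazymeError):
    """Zero variance in measured values; R² undefined."""


class SplitError(AptazymeError):
    """Too few records to split."""


class HoldoutError(AptazymeError):
    """Fewer than two qualifying structural segments."""


class ControlError(AptazymeError):
    """Non-positive control fluorescence ratio."""


# --- motifs ---
class NoMatch(AptazymeError):
    """Motif matched no records."""


class EmptyLibrary(AptazymeError):
    """A designed library contains no sequences."""
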