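"""Exception hierarchy for the L test segmentation pipeline."""


class LTestError(Exception):
    """Base class for all pipeline errors."""


class FormatError(LTestError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class ValidationError(LTestError):
    """An in-memory object violates a structural invariant."""


class RangeCoverageError(LTestError):
    """A ground-truth event falls outside its configured subtask data range."""


class NoEventDetectedError(LTestError):
    """Per-sample predictions contain no positive run after smoothing."""


class IntegrityError(LTestError):
    """A run-manifest hash does not match the file on disk."""
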