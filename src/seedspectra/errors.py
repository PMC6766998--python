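"""Exception types shared across the pipeline stages."""


class SeedSpectraError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SeedSpectraError):
    """A file on disk does not conform to the expected container format."""


class StateError(SeedSpectraError):
    """An operation was applied to an object in the wrong state
    (e.g. calibrating an already-calibrated scene)."""


class GenerationError(SeedSpectraError):
    """The synthetic-scene generator could not satisfy its constraints
    (e.g. non-overlapping seed placement failed after bounded retries)."""


class SplitError(SeedSpectraError):
    """A requested dataset partition is infeasible for at least one class."""


class TrainingError(SeedSpectraError):
    """Network optimisation failed (diverging / non-finite loss)."""
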