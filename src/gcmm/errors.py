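"""Exception hierarchy for network construction and training."""


class GcmmError(Exception):
    """Base class for all package errors."""


class FormatError(GcmmError, ValueError):
    """A file does not conform to the expected dialect."""


class DuplicateKeyError(FormatError):
    """An identifier appears more than once in a registry file."""


class ResolutionError(GcmmError, KeyError):
    """An identifier cannot be resolved against a registry."""

    def __init__(self, kind: str, offenders):
        self.kind = kind
        self.offenders = sorted(set(offenders))
        super().__init__(f"unknown {kind} id(s): {', '.join(map(str, self.offenders))}")


class AcyclicityError(GcmmError, ValueError):
    """The ontology edge list contains a cycle."""


class AlignmentError(GcmmError, ValueError):
    """A protein sequence is empty or contains an illegal residue."""


class DimensionError(GcmmError, ValueError):
    """Array shapes are incompatible."""


class TrainingFailureError(GcmmError, RuntimeError):
    """The optimizer produced a non-finite loss."""

    def __init__(self, epoch: int, loss):
        self.epoch = epoch
        super().__init__(f"non-finite loss ({loss!r}) at epoch {epoch}")


class ConfigError(GcmmError, ValueError):
    """An infeasible or inconsistent configuration."""
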