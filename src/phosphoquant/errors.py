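"""Exception hierarchy for the phosphoquant pipeline."""


class PhosphoQuantError(Exception):
    """Base class for all phosphoquant errors."""


class SchemaError(PhosphoQuantError):
    """A table is missing a mandatory column or holds an unparseable value."""


class DesignMismatchError(PhosphoQuantError):
    """A PSM table refers to channels or plexes absent from the design."""


class InvalidDesignError(PhosphoQuantError):
    """The experimental-design table violates the 8-plex pairing contract."""


class DegenerateGroupError(PhosphoQuantError):
    """A normalization group has a channel with zero total intensity."""


class AnnotationError(PhosphoQuantError):
    """An annotation table is malformed (e.g. duplicate keys)."""


class SimulationError(PhosphoQuantError):
    """The synthetic-data generator was given an infeasible configuration."""


class PipelineError(PhosphoQuantError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
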