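"""Exception types shared across the pipeline."""


class BiofilmFlowError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BiofilmFlowError, ValueError):
    """A file did not match the expected on-disk format."""


class CrowdLimitError(BiofilmFlowError, ValueError):
    """A pooled input exceeds the embedding crowd limit (default 150,000 events).

    t-SNE embeddings of very large point sets collapse distant points onto
    nearby map regions ("crowding"), so pooled inputs are capped hard rather
    than silently truncated.
    """


class GateOverlapError(BiofilmFlowError, ValueError):
    """Two subpopulation gates overlap by more than the allowed tolerance."""


class PipelineStageError(BiofilmFlowError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
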