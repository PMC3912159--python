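"""Exception hierarchy shared across the package."""


class MxevolveError(Exception):
    """Base class for all package errors."""


class GeneModelError(MxevolveError):
    """Invalid gene structure, sequence, or annotation input."""


class PhaseError(GeneModelError):
    """Codon-phase bookkeeping violated (phase chain, trailing phase)."""


class SearchError(MxevolveError):
    """MXE candidate search over invalid input."""


class AlignmentError(MxevolveError):
    """Gene-structure / MSA mapping failure."""


class TreeError(MxevolveError):
    """Species tree or presence/absence matrix inconsistency."""


class SimulationError(MxevolveError):
    """Infeasible or invalid synthetic-data specification."""


class PipelineError(MxevolveError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
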