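"""Exception hierarchy shared across the pipeline stages."""


class NmrbindError(Exception):
    """Base class for all package-specific errors."""


class PeakListFormatError(NmrbindError, ValueError):
    """A peak list, alignment or coordinate file could not be parsed."""


class IntegrityError(NmrbindError, ValueError):
    """Input violates an internal-consistency invariant (e.g. duplicate residue)."""


class AnalysisError(NmrbindError, RuntimeError):
    """A stage cannot produce a result from the given inputs (e.g. no paired residues)."""


class ScreenError(AnalysisError):
    """A dispersion screen is missing the required pulse delays."""
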