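"""Exception hierarchy.

Every error raised by the package derives from :class:`KirgateError`, so
callers can catch one base class.  Subclasses distinguish the failure modes
that the analysis pipeline treats differently (bad file vs. empty selection
vs. infeasible generator parameters vs. numerical breakdown).
"""


class KirgateError(Exception):
    """Base class for all kirgate errors."""


class PDBParseError(KirgateError):
    """A PDB record could not be parsed; the message names the line number."""


class PDBFormatError(KirgateError):
    """A value does not fit the fixed columns of the PDB format."""


class EmptyInputError(KirgateError):
    """An operation received zero atoms / frames / segments."""


class EmptySelectionError(KirgateError):
    """A selection resolved to no atoms."""


class GenerationError(KirgateError):
    """Synthetic-structure parameters are geometrically infeasible."""


class ConfigurationError(KirgateError):
    """Invalid parameter object (mixture, trace, excitation config...)."""


class PairingError(KirgateError):
    """Two structures that must share atom identity do not."""


class InsufficientAtomsError(KirgateError):
    """Too few atoms for a geometric fit (helix axis, superposition)."""


class InvalidMeasurementError(KirgateError):
    """A measured quantity is NaN or otherwise unusable."""


class NoVarianceError(KirgateError):
    """All selected descriptor columns are constant."""


class NormalizationError(KirgateError):
    """HDX normalization denominator is non-positive."""


class AlphabetError(KirgateError):
    """Unknown one-letter residue code."""


class ConnectivityError(KirgateError):
    """Elastic-network spring graph is disconnected."""


class IntegrationError(KirgateError):
    """Dynamics integration diverged."""


class FitError(KirgateError):
    """A model fit (Gaussian mixture, ...) failed to converge."""


class LookupError_(KirgateError):
    """A residue/node was not found in a network."""
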