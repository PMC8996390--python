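"""Exception hierarchy for primewindow.

All package-raised errors derive from :class:`PrimewindowError` so callers
(and the CLI) can distinguish validation failures from programming bugs.
"""


class PrimewindowError(Exception):
    """Base class for all primewindow errors."""


class ProfileError(PrimewindowError, ValueError):
    """Invalid editor profile definition (bad PAM pattern, window, offsets)."""


class BoundaryError(PrimewindowError, ValueError):
    """A protospacer or editable window extends past a contig boundary."""


class CoverageError(PrimewindowError, ValueError):
    """Coverage computation is impossible (e.g. no variants after filtering)."""


class VariantParseError(PrimewindowError, ValueError):
    """Malformed variant input; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class DesignError(PrimewindowError, ValueError):
    """pegRNA/ngRNA design failure."""


class EditOutsideWindowError(DesignError):
    """The requested edit does not fall inside the site's editable window."""


class EditUpstreamOfNickError(DesignError):
    """The edit lies 5' of the nick on the nicked strand.

    An RTT is copied onto the 3' end created by the nick, so it can only
    rewrite sequence on the PAM-proximal side of the nick.  Positions 5' of
    the canonical nick are reachable in cells only through the nickase's
    distal cleavage heterogeneity, which this designer does not model.
    """


class RttTooShortError(DesignError):
    """RTT cannot cover the edit plus one nucleotide of downstream homology."""

    def __init__(self, message: str, min_feasible: int):
        self.min_feasible = min_feasible
        super().__init__(message)


class ConfigError(PrimewindowError, ValueError):
    """Invalid run parameters (quantifier, simulator, CLI)."""


class SimulationError(PrimewindowError, ValueError):
    """Synthetic-data generation failure."""


class PlantingError(SimulationError):
    """Could not place the requested number of PAM sites; carries the count achieved."""

    def __init__(self, message: str, achieved: int):
        self.achieved = achieved
        super().__init__(message)
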