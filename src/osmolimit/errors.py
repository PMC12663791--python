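"""Exception hierarchy shared across the package."""


class OsmolimitError(Exception):
    """Base class for all package-specific errors."""


class DomainError(OsmolimitError, ValueError):
    """An input value lies outside the physical/mathematical domain of an operation."""


class ConfigurationError(OsmolimitError):
    """A configuration value, registry lookup or file layout is invalid."""


class SchemaError(ConfigurationError):
    """A tabular input does not match its declared schema."""


class MissingDataError(OsmolimitError):
    """A required measurement is absent and no fill policy allows proceeding."""


class NoSolutionError(OsmolimitError):
    """A root-finding problem has no solution for the given inputs."""


class BracketError(NoSolutionError):
    """The requested root lies outside the search bracket; carries diagnostics."""

    def __init__(self, message: str, *, lo: float, hi: float, f_lo: float, f_hi: float):
        super().__init__(
            f"{message} (bracket [{lo:g}, {hi:g}] with values [{f_lo:g}, {f_hi:g}])"
        )
        self.lo, self.hi, self.f_lo, self.f_hi = lo, hi, f_lo, f_hi
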