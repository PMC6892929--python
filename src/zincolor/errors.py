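"""Error hierarchy shared across the package.

Each class carries a distinct process exit code so the command-line
interface can signal the failure class to shell callers.
"""


class ZincAssayError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(ZincAssayError):
    """Invalid or inconsistent configuration (thresholds, palette, volumes)."""

    exit_code = 2


class InputError(ZincAssayError):
    """Unreadable or undecodable input file."""

    exit_code = 3


class LayoutError(ZincAssayError):
    """Tube layout table missing required tubes or columns."""

    exit_code = 4


class GeometryError(ZincAssayError):
    """Pixel geometry violation: center outside image, disc out of bounds."""

    exit_code = 5


class CalibrationError(ZincAssayError):
    """Not enough distinct standards to fit a calibration curve."""

    exit_code = 6


class DomainError(ZincAssayError, ValueError):
    """Argument outside its physical domain (negative zinc, score off scale)."""

    exit_code = 7
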