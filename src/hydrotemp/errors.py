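"""Typed errors raised by the pipeline stages."""

from __future__ import annotations


class HydrotempError(Exception):
    """Base class for all package errors."""


# --- ingest ---------------------------------------------------------------

class TemperatureError(HydrotempError):
    """Base for acquisition-temperature rejections."""


class MissingTemperature(TemperatureError):
    pass


class MultipleTemperatures(TemperatureError):
    pass


class ImplausibleTemperature(TemperatureError):
    pass


class ModelMismatch(HydrotempError):
    """NMR models of one chain disagree in residue count or types."""


class UnknownResidue(HydrotempError):
    """Residue type outside the 20-letter alphabet."""


class MalformedRow(HydrotempError):
    """Counts-table row with the wrong number of columns."""

    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


# --- potentials -----------------------------------------------------------

class EmptyBin(HydrotempError):
    pass


class ZeroCountError(HydrotempError):
    """A count needed in a log-ratio is zero; the cell is missing."""


class ZeroContacts(ZeroCountError):
    pass


class ZeroCell(ZeroCountError):
    pass


class ZeroArea(ZeroCountError):
    pass


class MissingReference(HydrotempError):
    pass


class UnknownClass(HydrotempError):
    pass


# --- inference ------------------------------------------------------------

class MissingCell(HydrotempError):
    pass


class TooFewChains(HydrotempError):
    pass


class DegenerateFit(HydrotempError):
    pass


# --- synthetic ------------------------------------------------------------

class InvalidConfig(HydrotempError):
    pass
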