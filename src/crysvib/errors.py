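"""Exception hierarchy."""


class CrysvibError(Exception):
    """Base class for all package errors."""


class FormatError(CrysvibError):
    """A structure or trajectory file could not be parsed."""


class ElementError(CrysvibError):
    """An element symbol is not in the known periodic-table set."""


class TopologyError(CrysvibError):
    """A bond-graph operation is impossible (e.g. rotating inside a ring)."""


class UndefinedDihedralError(CrysvibError):
    """Three consecutive dihedral atoms are collinear."""


class InvalidDonorError(CrysvibError):
    """Hydrogen-bond donor H is not covalently bonded to a sulfur."""


class ConfigurationError(CrysvibError):
    """Inconsistent or incomplete configuration of an analysis."""


class IntegrationError(CrysvibError):
    """Molecular-dynamics integration became unstable."""
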