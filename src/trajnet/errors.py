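"""Exception hierarchy shared across the package."""


class TrajnetError(Exception):
    """Base class for all package errors."""


class PDBParseError(TrajnetError):
    """Malformed PDB content; message carries the offending line number."""


class TopologyError(TrajnetError):
    """Inconsistent atom layout (e.g. frame/model atom-count mismatch)."""


class SelectionError(TrajnetError):
    """Invalid atom-selection specification."""


class SpecError(TrajnetError, ValueError):
    """Invalid generator or analysis parameterisation."""


class DegeneracyError(TrajnetError):
    """Geometric degeneracy (too few / collinear points)."""


class ConvergenceError(TrajnetError):
    """Iterative solver failed to reach tolerance."""
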