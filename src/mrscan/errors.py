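"""Structured exceptions raised across the package.

Every error carries a short machine-checkable ``stage`` tag so callers
(notably the CLI) can map failures to exit codes without string matching.
"""

from __future__ import annotations


class MRScanError(Exception):
    """Base class for all package errors."""

    stage = "general"


class PdbParseError(MRScanError):
    """Input text could not be parsed as PDB format."""

    stage = "parse"


class EmptyStructureError(MRScanError):
    """No usable C-alpha records in the input."""

    stage = "parse"


class ChainNotFoundError(MRScanError):
    """Requested chain identifier absent from the structure."""

    stage = "parse"


class DisconnectedNetworkError(MRScanError):
    """Contact graph has an isolated site or more than one component."""

    stage = "network"


class RankDeficiencyError(MRScanError):
    """Hessian null space larger than the six rigid-body modes."""

    stage = "rank"


class InconsistentInputsError(MRScanError):
    """Shapes or site counts of the supplied objects do not match."""

    stage = "inputs"


class IsolatedSiteError(MRScanError):
    """Operation requested at a site with no contacts."""

    stage = "inputs"


class InvalidParameterError(MRScanError):
    """A parameter is outside its admissible range."""

    stage = "inputs"


class NonNormalizableError(MRScanError):
    """Matrix cannot be normalized to mean one (grand mean <= 0)."""

    stage = "compare"


class BadFixtureError(MRScanError):
    """Synthetic structure violates the connectivity requirement."""

    stage = "fixture"


class FixtureOverflowError(MRScanError):
    """Structure too large for fixed-width PDB fields."""

    stage = "fixture"


class OracleRangeError(MRScanError):
    """Brute-force oracle invoked outside its feasible problem size."""

    stage = "oracle"


class ResampleRequired(MRScanError):
    """Signal that a degenerate random draw must be redrawn."""

    stage = "sampling"
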