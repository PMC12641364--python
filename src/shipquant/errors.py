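"""Exception hierarchy shared across the package."""


class ShipQuantError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(ShipQuantError, ValueError):
    """An argument is outside its valid domain (probability, concentration, DOL...)."""


class DesignError(ShipQuantError, ValueError):
    """An assay or lane design is internally inconsistent (overlapping bands,
    missing well pairs, fractions that do not sum to one)."""


class ConfigurationError(ShipQuantError, ValueError):
    """A gate or run configuration references missing channels/groups or
    violates panel invariants (e.g. no isotype control)."""


class EmptyPopulationError(ShipQuantError, ValueError):
    """No qualifying events for a geometric-MFI computation."""


class InvalidSpectrumError(ShipQuantError, ValueError):
    """Absorbance inputs leave no protein signal after dye correction."""


class InvalidMeasurementError(ShipQuantError, ValueError):
    """A quench pair or MFI is unusable (nonpositive unquenched signal,
    wrong temperature, zero quenching efficiency)."""


class InsufficientReplicatesError(ShipQuantError, ValueError):
    """A statistical comparison requires more observations than provided."""
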