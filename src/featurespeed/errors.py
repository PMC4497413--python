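"""Exception types shared across the pipeline."""


class FeatureSpeedError(Exception):
    """Base class for all package-specific errors."""


class PlacementError(FeatureSpeedError):
    """Raised when a simulated feature set cannot be placed on the proteome."""


class DegenerateBaseError(FeatureSpeedError):
    """A nucleotide class has zero variance, so per-base z-scoring is undefined."""

    def __init__(self, base: str):
        self.base = base
        super().__init__(f"zero variance for base {base!r}: z-score undefined")


class DegeneratePairError(FeatureSpeedError):
    """One of the two vectors handed to Pearson has zero variance."""


class InsufficientDataError(FeatureSpeedError):
    """Fewer complete windows / segments than the statistic requires."""


class EmptyMatrixError(FeatureSpeedError):
    """No mappable instance of a feature survived the filters."""

    def __init__(self, feature_name: str):
        self.feature_name = feature_name
        super().__init__(f"no mappable instances for feature {feature_name!r}")


class TrnaLookupError(FeatureSpeedError, KeyError):
    """A codon was not found in the tRNA concentration table."""
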