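"""Exception hierarchy for carliu."""


class CarliuError(Exception):
    """Base class for all carliu errors."""


class InvalidWeightsError(CarliuError, ValueError):
    """Spatial weights violate the contiguity-matrix contract."""


class IsolatedSiteError(InvalidWeightsError):
    """A site has no neighbors; D = diag(1/w_i+) is undefined."""


class DomainError(CarliuError, ValueError):
    """A parameter lies outside its admissible domain (e.g. rho, d)."""


class SingularDesignError(CarliuError, ValueError):
    """Design matrix (or a projected block of it) is rank deficient."""


class FitError(CarliuError, RuntimeError):
    """Likelihood maximization failed to produce a usable optimum."""


class DataError(CarliuError, ValueError):
    """Tabular input violates the dataset contract (NA, non-numeric, shape)."""


class ConfigError(CarliuError, ValueError):
    """Configuration file violates the schema."""
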