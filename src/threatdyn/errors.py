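"""Exception types shared across the package."""


class ThreatDynError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ThreatDynError):
    """Invalid generator / simulator / sweep configuration."""


class SchemaError(ThreatDynError):
    """A table is missing required columns.

    Parameters
    ----------
    missing : list of str
        The column names that were required but absent.
    """

    def __init__(self, missing, message=None):
        self.missing = list(missing)
        super().__init__(message or f"missing required columns: {self.missing}")


class UndefinedReliabilityError(ThreatDynError):
    """Cronbach's alpha is undefined (zero total variance)."""


class ConvergenceError(ThreatDynError):
    """Iterative estimation failed to converge."""

    def __init__(self, message, n_iter=None, gradient_norm=None):
        self.n_iter = n_iter
        self.gradient_norm = gradient_norm
        super().__init__(message)


class CollinearityError(ThreatDynError):
    """Design matrix is rank deficient."""

    def __init__(self, terms, message=None):
        self.terms = list(terms)
        super().__init__(message or f"collinear terms in design matrix: {self.terms}")


class IntegrationError(ThreatDynError):
    """A simulated stock became non-finite."""

    def __init__(self, stock, t, message=None):
        self.stock = stock
        self.t = t
        super().__init__(message or f"non-finite value in stock '{stock}' at t={t}")


class SweepError(ThreatDynError):
    """Too many failed runs in a parameter sweep."""
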