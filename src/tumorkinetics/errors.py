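"""Exception types shared across the pipeline stages."""


class ConfigurationError(ValueError):
    """A cohort-configuration field is invalid; message names the field."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested estimate."""


class SingularDesignError(ValueError):
    """Regression design matrix is rank-deficient (e.g. one distinct week)."""


class DegenerateDataError(ValueError):
    """Data carry no information for the requested fit (e.g. constant counts)."""


class UndefinedDurationError(ValueError):
    """A kinetic duration is undefined for the given inputs."""
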