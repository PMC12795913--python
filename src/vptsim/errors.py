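"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A device, observer, or study configuration is invalid or incomplete."""


class RunawayTrackError(RuntimeError):
    """A tracking procedure exceeded its hard duration/trial cap without terminating."""


class FitError(RuntimeError):
    """A mixed-model fit could not be performed on the supplied data."""
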