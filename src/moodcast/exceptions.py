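"""Package exceptions."""


class ConfigurationError(ValueError):
    """A configuration field is out of its valid range."""


class ValidationError(ValueError):
    """Input data violate the questionnaire schema or a model contract."""


class ColdStartError(RuntimeError):
    """A separate (per-patient) model was asked to predict an unseen patient."""


class LeakageError(RuntimeError):
    """A cross-validation plan places future information in a training set."""
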