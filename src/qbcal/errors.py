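"""Exception types shared across the package."""


class QbcalError(Exception):
    """Base class for package errors."""


class ValidationError(QbcalError, ValueError):
    """An input violated a documented invariant (bad distribution, bad fraction, ...)."""


class NotFittedError(QbcalError, RuntimeError):
    """A classifier was asked to predict before being fitted."""
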