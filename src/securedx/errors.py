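"""Exception hierarchy for the securedx toolkit.

Every stage raises a subclass of :class:`SecureDxError` so callers (and the
CLI) can map failures to distinct exit codes: authentication failures,
cryptographic integrity failures, and plain usage/configuration errors.
"""


class SecureDxError(Exception):
    """Base class for all securedx errors."""


class ConfigurationError(SecureDxError, ValueError):
    """Invalid configuration value (rates out of range, nonpositive sizes...)."""


class ValidationError(SecureDxError, ValueError):
    """Invalid input to an operation (empty id, off-curve point, shape mismatch)."""


class RegistrationError(SecureDxError):
    """Credential registration failed (e.g. duplicate username)."""


class AuthorizationError(SecureDxError):
    """An operation requiring a verified login was attempted without one."""


class EncodingError(SecureDxError):
    """Plaintext could not be embedded as curve points."""


class DecodingError(SecureDxError):
    """Curve points did not decode to well-formed plaintext (bad padding)."""


class KeyDerivationError(SecureDxError):
    """Secret-scalar derivation failed (identity shared point)."""


class IntegrityError(SecureDxError):
    """Decryption produced data that fails structural checks."""


class PreprocessingError(SecureDxError):
    """Table cleaning failed (e.g. a fully missing attribute column)."""


class NumericalError(SecureDxError):
    """A numerical routine produced non-finite results."""
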