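"""Exception hierarchy for the MRSE simulator.

Every failure mode the protocol distinguishes gets its own class so tests
and callers can assert on the precise condition rather than on messages.
"""


class MRSEError(Exception):
    """Base class for all simulator errors."""


class InvalidIdentityError(MRSEError):
    """A name field is empty after normalization."""


class InvalidDateError(MRSEError):
    """A birth date is not a valid calendar date."""


class InvalidTokenError(MRSEError):
    """A phonetic encoder received something other than an A-Z token."""


class CryptoError(MRSEError):
    """Base class for cryptographic failures."""


class DecryptionError(CryptoError):
    """Authenticated decryption failed: wrong key or tampered ciphertext."""


class ConfigurationError(MRSEError):
    """An actor is missing key material or the config is inconsistent."""


class ConsentError(MRSEError):
    """The patient consent flag is absent; the request is refused."""


class AuthenticationError(MRSEError):
    """A challenge-response authentication failed."""


class IsolationViolationError(MRSEError):
    """A message crossed the forbidden MRSE1 <-> MRSE2 channel."""

    def __init__(self, message: str, offending=None):
        super().__init__(message)
        self.offending = offending


class JoinFailureError(MRSEError):
    """The two request parts a hospital received carry different request numbers."""


class ProtocolAbortError(MRSEError):
    """An MRSE could not decrypt its request part; the run is aborted."""


class IncompleteBundleError(MRSEError):
    """Not every directory hospital answered a request."""

    def __init__(self, message: str, absentees=()):
        super().__init__(message)
        self.absentees = list(absentees)


class CriteriaError(MRSEError):
    """A selection-criteria field is malformed (e.g. inverted date interval)."""


class UnknownPatientError(MRSEError):
    """A patient id is absent from a synthetic world's truth map."""
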