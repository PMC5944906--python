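"""Exception hierarchy for compact-identifier handling.

Every failure mode a caller may want to branch on gets its own class; the
CLI maps these to exit codes and the redirect service maps them to HTTP
status codes, so the classes are part of the public contract.
"""

from __future__ import annotations


class CompactIdError(Exception):
    """Base class for all errors raised by this package."""


class GrammarError(CompactIdError):
    """The input string does not match the compact-identifier grammar
    ``(<resolver>/)<provider>/<prefix>:<LUI>`` (missing colon, empty LUI,
    internal whitespace, ...)."""


class NotFoundError(CompactIdError):
    """A namespace prefix, alias, or provider code is not registered."""

    def __init__(self, message: str, token: str | None = None):
        super().__init__(message)
        self.token = token


class ProviderMismatchError(NotFoundError):
    """The provider code exists in the registry but belongs to a different
    namespace than the one in the compact identifier."""


class UnknownResolverError(NotFoundError):
    """The URL's host is not a recognized meta-resolver host."""


class PatternError(CompactIdError):
    """The LUI does not full-match the namespace's registered pattern."""

    def __init__(self, message: str, pattern: str | None = None):
        super().__init__(message)
        self.pattern = pattern


class SchemaError(CompactIdError):
    """The registry document is structurally malformed (not the same thing
    as a constraint violation, which the validator reports as data)."""


class RegistryParseError(SchemaError):
    """The registry source is not well-formed YAML."""


class ConfigurationError(CompactIdError):
    """A provider record is unusable, e.g. its URL template lacks the
    ``{id}`` placeholder."""
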