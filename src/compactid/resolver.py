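"""Provider selection, LUI validation, template expansion, resolution.

Given a parsed compact identifier and a registry, resolution picks the
hosting provider (an explicit provider code wins; otherwise the
namespace's primary provider, else the first listed), checks the LUI
against the namespace's registered pattern, substitutes it into the
provider's URL template to obtain the *non-persistent* target location,
and constructs the persistent citable URLs — one per configured
meta-resolver base — that redirect there.

Production meta-resolvers pick a default provider dynamically from
uptime and reliability; here the choice is encoded statically in the
registry (``primary`` flag, else first listed) so resolution is a pure
function of (registry, input, bases). A dynamic availability policy
could be layered on by reordering providers before calling
:func:`select_provider`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .curie import (
    ParsedIdentifier,
    parse_compact_id,
    parse_resolver_url,
    quote_lui,
    render,
)
from .errors import ConfigurationError, NotFoundError, PatternError
from .registry import PrefixRecord, ProviderRecord, Registry, lookup_namespace

__all__ = [
    "DEFAULT_RESOLVER_BASES",
    "Resolution",
    "validate_lui",
    "select_provider",
    "expand",
    "persistent_urls",
    "resolve",
]

#: Meta-resolver base URLs used for persistent citable URLs.
DEFAULT_RESOLVER_BASES = ("https://identifiers.org", "https://n2t.net")


@dataclass
class Resolution:
    """Outcome of resolving one compact identifier."""

    parsed: ParsedIdentifier
    provider: ProviderRecord
    target_url: str
    persistent_urls: list[str] = field(default_factory=list)


def validate_lui(rec: PrefixRecord, lui: str) -> bool:
    """True iff the namespace has no pattern or the LUI full-matches it."""
    if rec.pattern is None:
        return True
    return re.fullmatch(rec.pattern, lui) is not None


def select_provider(rec: PrefixRecord, explicit_code: str | None = None) -> ProviderRecord:
    """Pick the provider: the explicit code if given (it must belong to
    this record), else the primary, else the first listed."""
    if explicit_code is not None:
        cf = explicit_code.casefold()
        for p in rec.providers:
            if p.code.casefold() == cf:
                return p
        raise NotFoundError(
            f"provider code {explicit_code!r} is not a provider of "
            f"namespace {rec.namespace!r}",
            explicit_code,
        )
    return rec.default_provider()


def expand(provider: ProviderRecord, lui: str) -> str:
    """Substitute the percent-encoded LUI into the provider's template."""
    if provider.url_template.count("{id}") != 1:
        raise ConfigurationError(
            f"template of provider {provider.code!r} must contain "
            "'{id}' exactly once: " + repr(provider.url_template)
        )
    if not lui:
        raise ConfigurationError("cannot expand an empty LUI")
    return provider.url_template.replace("{id}", quote_lui(lui))


def persistent_urls(
    p: ParsedIdentifier, reg: Registry, resolver_bases=DEFAULT_RESOLVER_BASES
) -> list[str]:
    """Resolver-hosted citable URLs, one per base, e.g.
    ``https://identifiers.org/taxon:9606`` and the n2t.net twin.

    The provider segment appears iff the identifier carries an explicit
    provider code."""
    bases = list(resolver_bases)
    if not bases:
        raise ValueError("resolver_bases must be nonempty")
    rendered = render(p, reg)
    return [base.rstrip("/") + "/" + rendered for base in bases]


def resolve(reg: Registry, input: str, resolver_bases=DEFAULT_RESOLVER_BASES) -> Resolution:
    """Resolve a compact identifier or resolver URL end to end.

    Dispatches on the presence of an http(s) scheme, validates the LUI
    against the namespace pattern (a mismatch is an error, not a
    warning: no redirect is emitted for a malformed accession), selects
    the provider, expands the template, and builds the persistent URLs.
    """
    s = input.strip()
    if s.lower().startswith(("http://", "https://")):
        parsed = parse_resolver_url(s, reg)
    else:
        parsed = parse_compact_id(s, reg)
    record = lookup_namespace(reg, parsed.namespace)
    if not validate_lui(record, parsed.lui):
        raise PatternError(
            f"LUI {parsed.lui!r} does not match pattern {record.pattern!r} "
            f"of namespace {record.namespace!r}",
            record.pattern,
        )
    provider = select_provider(record, parsed.provider_code)
    return Resolution(
        parsed=parsed,
        provider=provider,
        target_url=expand(provider, parsed.lui),
        persistent_urls=persistent_urls(parsed, reg, resolver_bases),
    )
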