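"""Compact-identifier grammar: parsing, normalization, rendering.

A compact identifier concatenates a registered namespace prefix, a colon,
and the locally unique identifier (LUI) the source database assigned:
``pdb:2gc4``. An optional provider code selects a specific host and is
prepended with a slash: ``rcsb/pdb:2gc4``. Presented to a meta-resolver
the whole thing rides on a URL: ``https://identifiers.org/rcsb/pdb:2gc4``.
The full grammar is therefore ``(<resolver>/)<provider>/<prefix>:<LUI>``.

Two wrinkles make this more than string splitting:

* Some authorities issue accessions that already embed the prefix and a
  colon (``GO:0003214``, ``MGI:80863``). Naively prepending the prefix
  would duplicate it (``GO:GO:0003214``), so one duplicated head is
  stripped during normalization. Prefixes embedded *without* a colon
  (``CHEMBL2842``) are part of the accession proper and are retained:
  ``chembl.target:CHEMBL2842``.
* LUIs may legitimately contain ``:`` and ``/``, so the prefix is split
  at the *first* colon and a provider segment is only recognized before
  the first slash when that segment itself contains no colon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from urllib.parse import quote, unquote, urlsplit

from .errors import (
    GrammarError,
    NotFoundError,
    ProviderMismatchError,
    UnknownResolverError,
)
from .registry import PrefixRecord, Registry, lookup_namespace, lookup_provider

__all__ = [
    "DEFAULT_RESOLVER_HOSTS",
    "ParsedIdentifier",
    "parse_compact_id",
    "parse_resolver_url",
    "render",
    "normalize",
    "quote_lui",
]

#: Meta-resolver hosts recognized by default when parsing resolver URLs.
DEFAULT_RESOLVER_HOSTS = ("identifiers.org", "n2t.net")

# Path-safe characters that are NOT percent-encoded inside a LUI when it
# is rendered into a URL. ':' and '/' stay literal, matching how printed
# persistent URLs carry accessions like E-GEOD-2599 or MGI:80863.
_LUI_SAFE = ":/@!$&'()*+,;=~-._"


@dataclass
class ParsedIdentifier:
    """A compact identifier after grammar and normalization rules.

    ``lui`` is stored *without* a duplicated ``<prefix>:`` head (the
    stripping has already happened); ``raw`` keeps the verbatim input.
    """

    namespace: str
    lui: str
    provider_code: str | None = None
    raw: str = field(default="", compare=False)


def quote_lui(lui: str) -> str:
    """Percent-encode a LUI for use in a URL path, leaving ``:`` and
    ``/`` (and other path-safe characters) literal."""
    return quote(lui, safe=_LUI_SAFE)


def _strip_duplicated_head(namespace: str, lui: str) -> str:
    """Remove one ``<namespace>:`` head from the LUI, case-insensitively.

    Applied exactly once: an accession whose post-strip form still begins
    with the prefix and colon is taken at face value.
    """
    head = namespace.casefold() + ":"
    if lui.casefold().startswith(head):
        return lui[len(head):]
    return lui


def parse_compact_id(s: str, reg: Registry) -> ParsedIdentifier:
    """Parse a bare compact identifier, optionally with a provider code.

    Splits the provider segment at the first ``/`` (only when that
    segment contains no colon), the prefix at the first ``:`` of the
    remainder, strips one duplicated prefix head from the LUI, and
    resolves the prefix (namespaces first, then aliases,
    case-insensitively). Everything after the prefix colon is the LUI
    verbatim — embedded colons and slashes survive.
    """
    raw = s
    s = s.strip()
    if not s:
        raise GrammarError("empty compact identifier")
    if any(ch.isspace() for ch in s):
        raise GrammarError(f"whitespace inside compact identifier {raw!r}")

    provider_token: str | None = None
    body = s
    slash = s.find("/")
    if slash != -1 and ":" not in s[:slash]:
        provider_token, body = s[:slash], s[slash + 1:]
        if not provider_token:
            raise GrammarError(f"empty provider segment in {raw!r}")

    colon = body.find(":")
    if colon == -1:
        raise GrammarError(f"no colon separating prefix from LUI in {raw!r}")
    prefix_token, lui = body[:colon], body[colon + 1:]
    if not prefix_token:
        raise GrammarError(f"empty namespace prefix in {raw!r}")
    if not lui:
        raise GrammarError(f"empty LUI in {raw!r}")

    record = lookup_namespace(reg, prefix_token)
    lui = _strip_duplicated_head(record.namespace, lui)
    if not lui:
        raise GrammarError(f"empty LUI after removing duplicated prefix in {raw!r}")

    provider_code: str | None = None
    if provider_token is not None:
        owner, provider = lookup_provider(reg, provider_token)
        if owner is not record:
            raise ProviderMismatchError(
                f"provider code {provider_token!r} belongs to namespace "
                f"{owner.namespace!r}, not {record.namespace!r}",
                provider_token,
            )
        provider_code = provider.code

    return ParsedIdentifier(
        namespace=record.namespace, lui=lui, provider_code=provider_code, raw=raw
    )


def render(p: ParsedIdentifier, reg: Registry) -> str:
    """Render ``[<provider>/]<display_prefix>:<LUI>``.

    Uses the namespace's registered display form (``GO``, ``MGI``) when
    one exists, else the lowercase namespace. ``parse_compact_id`` of the
    result returns an identifier equal to ``p``.
    """
    record = lookup_namespace(reg, p.namespace)
    head = f"{p.provider_code}/" if p.provider_code else ""
    return f"{head}{record.display}:{p.lui}"


def normalize(prefix_token: str, lui: str, reg: Registry) -> str:
    """Canonical compact-identifier string for a (prefix, LUI) pair.

    At most one prefix occurrence survives before the colon: a LUI like
    ``GO:0003214`` under prefix ``go`` collapses to ``GO:0003214``, while
    a colon-free embedded prefix (``CHEMBL2842``) is retained. Idempotent
    for identifiers with a single duplicated head.
    """
    record = lookup_namespace(reg, prefix_token)
    if not lui:
        raise GrammarError("empty LUI")
    stripped = _strip_duplicated_head(record.namespace, lui)
    if not stripped:
        raise GrammarError(f"empty LUI after removing duplicated prefix in {lui!r}")
    return f"{record.display}:{stripped}"


def _host_matches(host: str, resolver_hosts) -> bool:
    host = host.casefold()
    if host.startswith("www."):
        host = host[4:]
    return host in {h.casefold() for h in resolver_hosts}


def parse_resolver_url(
    url: str, reg: Registry, resolver_hosts=DEFAULT_RESOLVER_HOSTS
) -> ParsedIdentifier:
    """Parse a meta-resolver URL such as
    ``https://identifiers.org/ols/taxon:9606``.

    The scheme and a recognized resolver host (``www.``-prefixed variants
    accepted) are stripped, the path is percent-decoded, and the
    remainder is handed to :func:`parse_compact_id`.
    """
    parts = urlsplit(url.strip())
    if parts.scheme not in ("http", "https"):
        raise GrammarError(f"not an absolute http(s) URL: {url!r}")
    if not _host_matches(parts.hostname or "", resolver_hosts):
        raise UnknownResolverError(
            f"host {parts.hostname!r} is not a recognized resolver "
            f"(known: {', '.join(resolver_hosts)})",
            parts.hostname,
        )
    path = unquote(parts.path)
    if path.startswith("/"):
        path = path[1:]
    if not path:
        raise GrammarError(f"no compact identifier in URL path of {url!r}")
    parsed = parse_compact_id(path, reg)
    parsed.raw = url
    return parsed
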