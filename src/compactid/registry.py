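"""Prefix-registry file format: records, loading, validation, lookup.

The registry is the shared YAML document behind a compact-identifier
meta-resolver: a sequence of prefix records, each naming one identifier
collection (``pdb``, ``taxon``, ``chembl.target`` ...) together with the
hosting providers that can serve its records. Three registry-wide
uniqueness constraints make prefix-based redirection unambiguous:
namespaces are unique, aliases are unique and disjoint from namespaces,
and provider codes are unique across the *entire* registry (so a provider
code alone identifies both the host and the namespace it serves).

Loading and validation are deliberately separate: :func:`load_registry`
rejects only structurally malformed documents, while
:func:`validate_registry` reports every constraint violation at once, so
the package doubles as a registry linter.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field

import yaml

from .errors import NotFoundError, RegistryParseError, SchemaError

__all__ = [
    "ProviderRecord",
    "PrefixRecord",
    "Registry",
    "Violation",
    "RULE_IDS",
    "TOKEN_RE",
    "load_registry",
    "validate_registry",
    "lookup_namespace",
    "lookup_provider",
    "write_registry",
]

# Registered tokens (namespaces, aliases, provider codes) are lowercase
# letters/digits, optionally dot-separated into several such runs — the
# dots accommodate subdivided collections such as ``chembl.target``.
TOKEN_RE = re.compile(r"[a-z0-9]+(?:\.[a-z0-9]+)*")

#: Closed set of rule identifiers the validator may emit.
RULE_IDS = {
    "E_NAMESPACE_DUP": "namespace not unique across the registry",
    "E_ALIAS_DUP": "alias not unique across the registry or collides with a namespace",
    "E_PROVIDER_DUP": "provider code not unique across the registry",
    "E_NAMESPACE_TOKEN": "namespace is empty or not lowercase letters/digits (dots allowed internally)",
    "E_ALIAS_TOKEN": "alias is not a valid token",
    "E_PROVIDER_TOKEN": "provider code is not a valid token",
    "E_ALIAS_SELF": "alias list contains the record's own namespace",
    "E_TITLE_EMPTY": "title is empty",
    "E_NO_PROVIDERS": "record lists no providers",
    "E_MULTI_PRIMARY": "more than one provider is flagged primary",
    "E_TEMPLATE_PLACEHOLDER": "url_template must contain '{id}' exactly once",
    "E_TEMPLATE_SCHEME": "url_template must start with http:// or https://",
    "E_DISPLAY_PREFIX": "display_prefix does not equal the namespace under case folding",
    "E_PATTERN_INVALID": "pattern is not a valid regular expression",
    "W_UNKNOWN_KEY": "unrecognized key (preserved on round-trip)",
}

_RECORD_KEYS = {
    "namespace",
    "title",
    "homepage",
    "aliases",
    "pattern",
    "display_prefix",
    "providers",
}
_PROVIDER_KEYS = {"code", "title", "url_template", "primary"}


@dataclass
class ProviderRecord:
    """One hosting location for a namespace.

    ``url_template`` carries a single literal ``{id}`` placeholder that
    the resolver substitutes with the (percent-encoded) LUI. ``primary``
    marks the namespace's default provider; when no provider is flagged,
    the first listed one is the default.
    """

    code: str
    url_template: str
    title: str = ""
    primary: bool = False
    extra: dict = field(default_factory=dict)


@dataclass
class PrefixRecord:
    """One registered namespace prefix and its hosting providers."""

    namespace: str
    title: str
    homepage: str | None = None
    aliases: list[str] = field(default_factory=list)
    pattern: str | None = None
    display_prefix: str | None = None
    providers: list[ProviderRecord] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    @property
    def display(self) -> str:
        """Case form used when rendering compact identifiers."""
        return self.display_prefix if self.display_prefix else self.namespace

    def default_provider(self) -> ProviderRecord:
        """The provider flagged ``primary``, else the first listed."""
        for p in self.providers:
            if p.primary:
                return p
        if not self.providers:
            raise NotFoundError(
                f"namespace {self.namespace!r} has no providers", self.namespace
            )
        return self.providers[0]


@dataclass
class Violation:
    """One breached registry constraint, reported by the validator."""

    rule_id: str
    severity: str  # "error" | "warning"
    message: str
    location: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.severity.upper()} {self.rule_id} at {self.location}: {self.message}"


class Registry:
    """A collection of prefix records plus case-folded lookup indices."""

    def __init__(self, records: list[PrefixRecord] | None = None):
        self.records: list[PrefixRecord] = list(records or [])
        self._reindex()

    def _reindex(self) -> None:
        # Last writer wins on duplicates; the validator reports them.
        self.namespace_index: dict[str, PrefixRecord] = {}
        self.alias_index: dict[str, PrefixRecord] = {}
        self.provider_index: dict[str, tuple[PrefixRecord, ProviderRecord]] = {}
        for rec in self.records:
            self.namespace_index[rec.namespace.casefold()] = rec
            for alias in rec.aliases:
                self.alias_index[alias.casefold()] = rec
            for prov in rec.providers:
                self.provider_index[prov.code.casefold()] = (rec, prov)

    def add(self, record: PrefixRecord) -> None:
        self.records.append(record)
        self._reindex()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, Registry) and self.records == other.records


def _require(mapping: dict, key: str, where: str):
    if key not in mapping or mapping[key] is None:
        raise SchemaError(f"missing required field {key!r} in {where}")
    return mapping[key]


def _load_provider(raw, where: str) -> ProviderRecord:
    if not isinstance(raw, dict):
        raise SchemaError(f"provider entry in {where} is not a mapping")
    code = _require(raw, "code", f"provider of {where}")
    template = _require(raw, "url_template", f"provider {code!r} of {where}")
    extra = {k: v for k, v in raw.items() if k not in _PROVIDER_KEYS}
    return ProviderRecord(
        code=str(code),
        url_template=str(template),
        title=str(raw.get("title", "") or ""),
        primary=bool(raw.get("primary", False)),
        extra=extra,
    )


def _load_record(raw, index: int) -> PrefixRecord:
    if not isinstance(raw, dict):
        raise SchemaError(f"record #{index} is not a mapping")
    where = f"record #{index}"
    namespace = str(_require(raw, "namespace", where))
    where = f"record {namespace!r}"
    title = str(_require(raw, "title", where))
    providers_raw = _require(raw, "providers", where)
    if not isinstance(providers_raw, list):
        raise SchemaError(f"'providers' of {where} is not a sequence")
    aliases = raw.get("aliases") or []
    if not isinstance(aliases, list):
        raise SchemaError(f"'aliases' of {where} is not a sequence")
    extra = {k: v for k, v in raw.items() if k not in _RECORD_KEYS}
    return PrefixRecord(
        namespace=namespace,
        title=title,
        homepage=raw.get("homepage"),
        aliases=[str(a) for a in aliases],
        pattern=raw.get("pattern"),
        display_prefix=raw.get("display_prefix"),
        providers=[_load_provider(p, where) for p in providers_raw],
        extra=extra,
    )


def load_registry(source) -> Registry:
    """Read a registry from YAML text, a file path, or an open stream.

    Structural problems (bad YAML, a missing required field) raise
    :class:`SchemaError`; constraint violations do not — run
    :func:`validate_registry` for those.
    """
    if isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and os.path.isfile(source)
    ):
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    elif isinstance(source, io.IOBase) or hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise RegistryParseError(f"malformed YAML{line}: {exc}") from exc
    if doc is None:
        return Registry([])
    if not isinstance(doc, dict) or "records" not in doc:
        raise SchemaError("registry document must be a mapping with a 'records' key")
    raw_records = doc["records"] or []
    if not isinstance(raw_records, list):
        raise SchemaError("'records' must be a sequence")
    return Registry([_load_record(r, i) for i, r in enumerate(raw_records)])


def validate_registry(reg: Registry) -> list[Violation]:
    """Check every registry/record/provider invariant; return violations.

    The list is empty iff the registry is valid. Order is deterministic:
    by record order, then rule_id, so a linter's output is stable. A
    duplicated token is reported once, at its second (later) occurrence.
    """
    violations: list[Violation] = []
    seen_ns: dict[str, str] = {}
    seen_alias: dict[str, str] = {}
    seen_provider: dict[str, str] = {}

    for rec in reg.records:
        per_record: list[Violation] = []
        loc = rec.namespace or "<unnamed>"
        ns_cf = rec.namespace.casefold()

        if not TOKEN_RE.fullmatch(rec.namespace):
            per_record.append(
                Violation("E_NAMESPACE_TOKEN", "error",
                          f"namespace {rec.namespace!r} is not a valid token", loc)
            )
        if ns_cf in seen_ns:
            per_record.append(
                Violation("E_NAMESPACE_DUP", "error",
                          f"namespace {rec.namespace!r} already registered", loc)
            )
        else:
            seen_ns[ns_cf] = loc

        if not rec.title.strip():
            per_record.append(Violation("E_TITLE_EMPTY", "error", "title is empty", loc))

        for alias in rec.aliases:
            a_cf = alias.casefold()
            if not TOKEN_RE.fullmatch(alias):
                per_record.append(
                    Violation("E_ALIAS_TOKEN", "error",
                              f"alias {alias!r} is not a valid token", loc)
                )
            if a_cf == ns_cf:
                per_record.append(
                    Violation("E_ALIAS_SELF", "error",
                              f"alias {alias!r} repeats the record's own namespace", loc)
                )
                continue
            if a_cf in seen_alias or a_cf in seen_ns:
                per_record.append(
                    Violation("E_ALIAS_DUP", "error",
                              f"alias {alias!r} already used as an alias or namespace", loc)
                )
            else:
                seen_alias[a_cf] = loc

        if not rec.providers:
            per_record.append(Violation("E_NO_PROVIDERS", "error", "no providers listed", loc))
        primaries = [p for p in rec.providers if p.primary]
        if len(primaries) > 1:
            per_record.append(
                Violation("E_MULTI_PRIMARY", "error",
                          f"{len(primaries)} providers flagged primary", loc)
            )
        for prov in rec.providers:
            c_cf = prov.code.casefold()
            if not TOKEN_RE.fullmatch(prov.code):
                per_record.append(
                    Violation("E_PROVIDER_TOKEN", "error",
                              f"provider code {prov.code!r} is not a valid token", loc)
                )
            if c_cf in seen_provider:
                per_record.append(
                    Violation("E_PROVIDER_DUP", "error",
                              f"provider code {prov.code!r} already registered "
                              f"(by {seen_provider[c_cf]!r})", loc)
                )
            else:
                seen_provider[c_cf] = loc
            if prov.url_template.count("{id}") != 1:
                per_record.append(
                    Violation("E_TEMPLATE_PLACEHOLDER", "error",
                              f"template {prov.url_template!r} must contain "
                              "'{id}' exactly once", loc)
                )
            if not prov.url_template.startswith(("http://", "https://")):
                per_record.append(
                    Violation("E_TEMPLATE_SCHEME", "error",
                              f"template {prov.url_template!r} must be http(s)", loc)
                )
            for key in prov.extra:
                per_record.append(
                    Violation("W_UNKNOWN_KEY", "warning",
                              f"unknown provider key {key!r}", loc)
                )

        if rec.display_prefix is not None and rec.display_prefix.casefold() != ns_cf:
            per_record.append(
                Violation("E_DISPLAY_PREFIX", "error",
                          f"display_prefix {rec.display_prefix!r} is not a case "
                          f"variant of {rec.namespace!r}", loc)
            )
        if rec.pattern is not None:
            try:
                re.compile(rec.pattern)
            except re.error as exc:
                per_record.append(
                    Violation("E_PATTERN_INVALID", "error",
                              f"pattern {rec.pattern!r}: {exc}", loc)
                )
        for key in rec.extra:
            per_record.append(
                Violation("W_UNKNOWN_KEY", "warning", f"unknown key {key!r}", loc)
            )

        violations.extend(sorted(per_record, key=lambda v: v.rule_id))
    return violations


def lookup_namespace(reg: Registry, token: str) -> PrefixRecord:
    """Resolve a prefix token case-insensitively: namespaces first, then
    aliases. Raises :class:`NotFoundError` for unregistered tokens."""
    if not token:
        raise NotFoundError("empty namespace token", token)
    cf = token.casefold()
    rec = reg.namespace_index.get(cf) or reg.alias_index.get(cf)
    if rec is None:
        raise NotFoundError(f"unknown namespace prefix {token!r}", token)
    return rec


def lookup_provider(reg: Registry, code: str) -> tuple[PrefixRecord, ProviderRecord]:
    """Resolve a provider code case-insensitively against the registry-wide
    provider index; returns ``(owning record, provider)``."""
    if not code:
        raise NotFoundError("empty provider code", code)
    hit = reg.provider_index.get(code.casefold())
    if hit is None:
        raise NotFoundError(f"unknown provider code {code!r}", code)
    return hit


def _provider_to_dict(p: ProviderRecord) -> dict:
    out: dict = {"code": p.code}
    if p.title:
        out["title"] = p.title
    out["url_template"] = p.url_template
    if p.primary:
        out["primary"] = True
    out.update(p.extra)
    return out


def _record_to_dict(r: PrefixRecord) -> dict:
    out: dict = {"namespace": r.namespace, "title": r.title}
    if r.homepage is not None:
        out["homepage"] = r.homepage
    if r.aliases:
        out["aliases"] = list(r.aliases)
    if r.pattern is not None:
        out["pattern"] = r.pattern
    if r.display_prefix is not None:
        out["display_prefix"] = r.display_prefix
    out["providers"] = [_provider_to_dict(p) for p in r.providers]
    out.update(r.extra)
    return out


def write_registry(reg: Registry) -> str:
    """Serialize to the canonical YAML dialect; ``load(write(r)) == r``."""
    doc = {"records": [_record_to_dict(r) for r in reg.records]}
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True, width=1000)
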