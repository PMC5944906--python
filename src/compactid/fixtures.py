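"""Built-in fixture registry and seeded random registries/identifiers.

The built-in registry covers the worked examples a resolver must handle:
namespaces whose accessions are bare numeric (``taxon:9606``),
alphanumeric (``pdb:2gc4``), authority-prefixed with a colon
(``MGI:80863``, ``GO:0003214``) and authority-prefixed without one
(``chembl.target:CHEMBL2842``), plus a multi-provider namespace (taxon)
for exercising provider codes. Templates whose real-world form is not
publicly pinned down use synthetic ``.example`` hosts so tests never
depend on live provider URL layouts.

The random generators exist for property testing: every registry they
emit satisfies all registry constraints by construction, and the
identifier sampler covers the four LUI shapes above.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field

from .curie import ParsedIdentifier, render
from .registry import (
    PrefixRecord,
    ProviderRecord,
    Registry,
    load_registry,
)
from .resolver import DEFAULT_RESOLVER_BASES, validate_lui

__all__ = [
    "FIXTURE_REGISTRY_YAML",
    "LUI_SHAPES",
    "GeneratorSpec",
    "builtin_fixture_registry",
    "random_registry",
    "random_identifiers",
]

# Templates on `.example` hosts are synthetic stand-ins; the pdbe, mgi
# (jax) and arrayexpress (ebiae) templates are the real published ones.
FIXTURE_REGISTRY_YAML = """\
records:
  - namespace: taxon
    title: NCBI Taxonomy
    homepage: https://www.ncbi.nlm.nih.gov/taxonomy
    aliases: [ncbitaxon]
    pattern: '\\d+'
    providers:
      - code: ncbi
        title: NCBI (primary source)
        url_template: https://ncbi.example/taxonomy/{id}
        primary: true
      - code: ols
        title: Ontology Lookup Service
        url_template: https://ols.example/ontologies/ncbitaxon/{id}
      - code: bptl
        title: NCBO BioPortal
        url_template: https://bioportal.example/ncbitaxon/{id}
      - code: ena
        title: European Nucleotide Archive
        url_template: https://ena.example/taxonomy/{id}
  - namespace: pdb
    title: Protein Data Bank
    homepage: https://www.wwpdb.org
    providers:
      - code: pdbe
        title: Protein Data Bank in Europe
        url_template: https://www.ebi.ac.uk/pdbe/entry/pdb/{id}
        primary: true
      - code: rcsb
        title: RCSB Protein Data Bank
        url_template: https://rcsb.example/structure/{id}
  - namespace: mgi
    title: Mouse Genome Informatics
    display_prefix: MGI
    pattern: '\\d+'
    providers:
      - code: jax
        title: Jackson Laboratory
        url_template: http://www.informatics.jax.org/reference/MGI:{id}
  - namespace: arrayexpress
    title: ArrayExpress
    providers:
      - code: ebiae
        title: EMBL-EBI ArrayExpress
        url_template: https://www.ebi.ac.uk/arrayexpress/experiments/{id}
  - namespace: go
    title: Gene Ontology
    homepage: http://geneontology.org
    display_prefix: GO
    pattern: '\\d{7}'
    providers:
      - code: amigo
        title: AmiGO
        url_template: https://amigo.example/term/GO:{id}
  - namespace: chembl.target
    title: ChEMBL Targets
    pattern: 'CHEMBL\\d+'
    providers:
      - code: ebichembl
        title: EMBL-EBI ChEMBL
        url_template: https://chembl.example/target/{id}
"""

#: The four LUI shapes the generators cover.
LUI_SHAPES = (
    "numeric",
    "alphanumeric",
    "prefix-embedded-with-colon",
    "prefix-embedded-no-colon",
)


def builtin_fixture_registry() -> Registry:
    """The six-namespace fixture registry (stable across releases)."""
    return load_registry(FIXTURE_REGISTRY_YAML)


@dataclass
class GeneratorSpec:
    """Parameters of the random-registry generator.

    The same seed always yields the same registry. Probabilities are
    per-namespace; ``providers_per_namespace`` is an inclusive range.
    """

    seed: int = 0
    n_namespaces: int = 20
    providers_per_namespace: tuple[int, int] = (1, 4)
    alias_probability: float = 0.3
    pattern_probability: float = 0.7
    lui_shapes: tuple[str, ...] = LUI_SHAPES

    def __post_init__(self):
        if self.n_namespaces <= 0:
            raise ValueError("n_namespaces must be positive")
        lo, hi = self.providers_per_namespace
        if lo < 1 or hi < lo:
            raise ValueError("providers_per_namespace must be a range >= 1")
        for p in (self.alias_probability, self.pattern_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        unknown = set(self.lui_shapes) - set(LUI_SHAPES)
        if unknown:
            raise ValueError(f"unknown LUI shapes: {sorted(unknown)}")
        if not self.lui_shapes:
            raise ValueError("lui_shapes must be nonempty")


def _token(rng: random.Random, idx: int, head: str) -> str:
    # Index suffix guarantees registry-wide uniqueness by construction.
    stem = "".join(rng.choices("abcdefghijklmnopqrstuvwxyz", k=rng.randint(3, 6)))
    tok = f"{head}{stem}{idx}"
    if head == "ns" and rng.random() < 0.2:  # dotted sub-collection, e.g. chembl.target
        tok += "." + "".join(rng.choices("abcdefghijklmnopqrstuvwxyz", k=3))
    return tok


def _shape_fields(shape: str, namespace: str, with_pattern: bool):
    """(pattern, template tail) for one namespace of the given shape."""
    stem = re.sub(r"[^a-z0-9]", "", namespace).upper()
    if shape == "numeric":
        return ("\\d{1,8}" if with_pattern else None), "{id}"
    if shape == "alphanumeric":
        return ("[a-z0-9]{1,12}" if with_pattern else None), "{id}"
    if shape == "prefix-embedded-with-colon":
        # Authority issues STEM:digits; the registry stores the bare
        # digits and the template restores the issued head.
        return ("\\d{1,8}" if with_pattern else None), stem + ":{id}"
    # prefix-embedded-no-colon: the stem is part of the accession itself.
    return (stem + "\\d{1,8}"), "{id}"


def random_registry(spec: GeneratorSpec) -> Registry:
    """Generate a registry satisfying every constraint by construction.

    All requested LUI shapes occur when ``n_namespaces`` is at least the
    number of shapes (shapes are dealt round-robin before randomizing).
    """
    rng = random.Random(spec.seed)
    records: list[PrefixRecord] = []
    prov_counter = 0
    for i in range(spec.n_namespaces):
        shape = (
            spec.lui_shapes[i % len(spec.lui_shapes)]
            if i < len(spec.lui_shapes)
            else rng.choice(spec.lui_shapes)
        )
        namespace = _token(rng, i, "ns")
        with_pattern = rng.random() < spec.pattern_probability
        pattern, tail = _shape_fields(shape, namespace, with_pattern)
        display_prefix = None
        if shape == "prefix-embedded-with-colon" and rng.random() < 0.8:
            # Render in the authority's uppercase form, like GO or MGI.
            display_prefix = namespace.upper()

        n_prov = rng.randint(*spec.providers_per_namespace)
        providers = []
        for j in range(n_prov):
            code = _token(rng, prov_counter, "p")
            prov_counter += 1
            providers.append(
                ProviderRecord(
                    code=code,
                    title=f"Provider {code}",
                    url_template=f"https://{code}.example/{namespace}/{tail}",
                    primary=(j == 0 and rng.random() < 0.5),
                )
            )
        aliases = []
        if rng.random() < spec.alias_probability:
            aliases.append(_token(rng, i, "al"))
        records.append(
            PrefixRecord(
                namespace=namespace,
                title=f"Collection {namespace}",
                homepage=f"https://{namespace.replace('.', '-')}.example"
                if rng.random() < 0.5
                else None,
                aliases=aliases,
                pattern=pattern,
                display_prefix=display_prefix,
                providers=providers,
            )
        )
    return Registry(records)


_DIGITS = "0123456789"
_ALNUM = "abcdefghijklmnopqrstuvwxyz0123456789"


def _sample_lui(rng: random.Random, rec: PrefixRecord) -> str:
    """Sample a LUI that full-matches the record's pattern.

    Understands the pattern vocabulary this package's registries use:
    an optional literal stem followed by ``\\d+``/``\\d{m}``/``\\d{m,n}``
    or a ``[a-z0-9]`` class; falls back to rejection sampling over
    simple candidates for anything else.
    """
    pat = rec.pattern
    if pat is None:
        return "".join(rng.choices(_ALNUM, k=rng.randint(1, 10)))
    m = re.fullmatch(
        r"(?P<stem>[A-Za-z0-9:._-]*?)"
        r"(?:\\d(?P<rep>\+|\{(?P<m>\d+)(?:,(?P<n>\d+))?\})"
        r"|\[a-z0-9\](?P<arep>\+|\{(?P<am>\d+)(?:,(?P<an>\d+))?\}))",
        pat,
    )
    if m:
        stem = m.group("stem")
        if m.group("rep") is not None:
            lo = int(m.group("m")) if m.group("m") else 1
            hi = int(m.group("n")) if m.group("n") else (lo if m.group("m") else 8)
            body = "".join(rng.choices(_DIGITS, k=rng.randint(lo, hi)))
        else:
            lo = int(m.group("am")) if m.group("am") else 1
            hi = int(m.group("an")) if m.group("an") else (lo if m.group("am") else 12)
            body = "".join(rng.choices(_ALNUM, k=rng.randint(lo, hi)))
        candidate = stem + body
        if validate_lui(rec, candidate):
            return candidate
    for _ in range(200):  # rejection fallback for unusual patterns
        candidate = "".join(rng.choices(_ALNUM, k=rng.randint(1, 12)))
        if validate_lui(rec, candidate):
            return candidate
    raise ValueError(f"cannot sample a LUI for pattern {pat!r}")


def random_identifiers(
    reg: Registry, k: int, seed: int, resolver_bases=DEFAULT_RESOLVER_BASES
) -> list[tuple[ParsedIdentifier, str, str]]:
    """Sample ``k`` triples (parsed identifier, rendered string, resolver
    URL) across the registry's namespaces and providers.

    Roughly half carry an explicit provider code; every LUI satisfies
    its namespace's pattern; deterministic for a given seed.
    """
    rng = random.Random(seed)
    out = []
    records = list(reg.records)
    if not records:
        raise ValueError("registry has no records")
    for _ in range(k):
        rec = rng.choice(records)
        lui = _sample_lui(rng, rec)
        # Re-apply the duplication rule: a sampled LUI must not start a
        # parsed identifier with its own '<ns>:' head.
        head = rec.namespace.casefold() + ":"
        for _ in range(100):
            if not lui.casefold().startswith(head):
                break
            lui = _sample_lui(rng, rec)
        provider_code = None
        if rec.providers and rng.random() < 0.5:
            provider_code = rng.choice(rec.providers).code
        p = ParsedIdentifier(namespace=rec.namespace, lui=lui, provider_code=provider_code)
        rendered = render(p, reg)
        base = rng.choice(list(resolver_bases))
        out.append((p, rendered, base.rstrip("/") + "/" + rendered))
    return out
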