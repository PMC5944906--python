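# Methods

## Model of identifier resolution

A compact identifier is `(<resolver>/)<provider>/<prefix>:<LUI>`. The
registry maps each namespace prefix to a title, optional homepage,
optional aliases, an optional LUI pattern, an optional display form, and
one or more providers, each with a registry-wide-unique code and a URL
template containing the literal placeholder `{id}` exactly once.
Resolution is a pure function of (registry, input string, resolver
bases):

1. **Parse.** If the input carries an `http(s)` scheme, the host must be
   a recognized resolver host (`identifiers.org`, `n2t.net`,
   `www.`-prefixed variants accepted, or any caller-supplied list); the
   path is percent-decoded and treated as a bare compact identifier.
   A provider segment is recognized before the *first* `/` only when
   that segment contains no `:`; the prefix is split from the LUI at the
   *first* `:` of the remainder. Everything after that colon is the LUI
   verbatim — embedded `:` and `/` survive, which is what disambiguates
   `rcsb/pdb:2gc4` (provider segment) from `pdb:2gc4/chain/A` (LUI with
   slashes).
2. **Normalize.** If the LUI begins with `<namespace>:` under case
   folding, that head is removed **exactly once**. One pass matches the
   way colon-delimited authorities (GO, MGI) issue accessions; a LUI
   still carrying such a head after one strip is taken as accession
   content. The LUI tail's case is never altered, because accessions
   are case-significant (`E-GEOD-2599`, `CHEMBL2842`). Prefixes embedded
   without a colon are untouched. Consequence: normalization is
   idempotent exactly on identifiers with at most one duplicated head,
   which is the class the grammar's canonical form (and the
   `ParsedIdentifier` invariant) permits.
3. **Validate.** If the namespace registers a pattern, the LUI must
   full-match it (common-intersection regex dialect; patterns are
   compiled with the standard `re` engine but the registry fixture and
   generators restrict themselves to portable constructs). A mismatch
   blocks resolution with an error rather than a warning, so no redirect
   is ever emitted for a malformed accession.
4. **Select a provider.** An explicit code must belong to the
   identifier's namespace (a code registered to a *different* namespace
   is a distinct mismatch error, since provider codes are globally
   unique and the conflict is diagnosable). With no explicit code the
   provider flagged `primary` wins, else the first listed. Production
   meta-resolvers choose defaults dynamically from uptime/reliability;
   encoding the default statically keeps desk-scale resolution
   deterministic and testable. A dynamic policy can be layered on by
   reordering `providers` before selection.
5. **Expand and cite.** The target URL is the template with `{id}`
   replaced once by the percent-encoded LUI; `:` and `/` inside LUIs are
   left literal, matching how published persistent URLs print accessions
   such as `MGI:80863`. Persistent URLs are `<base>/` + the rendered
   identifier, one per configured resolver base (defaults:
   `https://identifiers.org`, `https://n2t.net`), with the provider
   segment present iff it was explicit.

Rendering uses the namespace's `display_prefix` (`GO`, `MGI`) when
registered, else the lowercase namespace; prefix/alias/provider matching
is case-insensitive throughout (`GO:0003214` and `go:0003214` are the
same identifier).

## Registry format and validation

Loading and validation are deliberately separated: `load_registry`
rejects only structural problems (malformed YAML, a missing required
field), while `validate_registry` returns *all* constraint violations as
data, so the tool can be used as a registry linter. The rule set is
closed (`compactid.registry.RULE_IDS`); output order is deterministic
(record order, then rule id) and a duplicated token is reported once, at
its second occurrence, so injecting k distinct uniqueness violations
yields exactly k errors. Unknown keys are preserved on round-trip and
reported as warnings — forward compatibility without silent data loss.
Tokens are lowercase letters/digits with optional single internal dots
(accommodating subdivided collections like `chembl.target`).
Serialization omits absent optional fields, so `load(write(r)) == r`
field-for-field.

## Redirect service

`handle_request` is the pure core; the stdlib `http.server` wrapper adds
nothing but transport. Success is **302 Found**, not 301: provider
targets are explicitly non-persistent, and only the resolver URL should
be cached or cited. Unknown prefixes/providers map to 404, grammar and
pattern failures to 400, and `GET /` returns a plain-text usage page.
Equivalence with the library path (302 Location == `resolve(...).target_url`,
error classes ↔ status codes) is asserted property-wise in the tests.

## Synthetic data

The built-in fixture registry (6 namespaces: `taxon`, `pdb`, `mgi`,
`arrayexpress`, `go`, `chembl.target`) covers the four LUI shapes that
occur in the wild — bare numeric (`9606`), alphanumeric (`2gc4`),
authority-prefixed with colon (`MGI:80863`, `GO:0003214`), and
authority-prefixed without colon (`CHEMBL2842`) — plus a multi-provider
namespace (taxon: ncbi primary, ols, bptl, ena) for provider-code
behavior. Templates whose real-world layout is published (`pdbe`, `jax`,
`ebiae`) are reproduced verbatim; the rest use synthetic `.example`
hosts so tests never depend on live provider URL layouts.

`random_registry(GeneratorSpec)` generates constraint-valid registries
by construction (uniqueness is guaranteed by index-suffixed tokens); the
defaults — 20 namespaces, 1–4 providers each, alias probability 0.3,
pattern probability 0.7, all four LUI shapes dealt round-robin first —
are a plausible miniature of a curated prefix registry.
`random_identifiers` samples LUIs that satisfy each namespace's pattern
(a small sampler covering the pattern vocabulary these registries use,
with rejection-sampling fallback) and attaches an explicit provider code
to roughly half. Both are deterministic per seed.

What the generators do **not** emulate: provider uptime and geographic
load-balancing (defaults here are static), live registry content at the
production resolvers (the loader's YAML dialect is this package's own
canonical one), percent-encoded exotic Unicode in accessions, and
adversarially malformed YAML beyond what the structural loader rejects.
Passing tests therefore demonstrate grammar/registry/redirect
correctness, not behavioral identity with any production service.

## Numerical and sizing choices

There is no floating-point numerics here; "tolerances" are all exact
string equality. Property sweeps use 50 generated registries × 21
identifiers (~1050 cases), which exercises every shape/provider
combination many times over while keeping the whole suite under a
minute; the hypothesis grammar fuzzing is derandomized for
reproducibility. Seeds are explicit everywhere (`GeneratorSpec.seed`,
`random_identifiers(seed=...)`, the CLI's `--seed`, the acceptance
script's `--seed`).

## Known limitations

- Duplication stripping is single-pass by design; a pathological
  `GO:GO:GO:x` input normalizes to `GO:GO:x`, whose LUI retains one
  embedded head.
- Aliases are treated as resolvable on input (not documentation-only);
  rendering always uses the canonical namespace, so alias input
  canonicalizes.
- An explicit provider code does not bypass pattern validation.
- `doi:`/`ark:`/`urn:` schemes receive no special handling; they can
  appear only as ordinary registry namespaces.
- The service offers no TLS, caching, rate limiting, or replication —
  it is a reference endpoint, not production infrastructure.
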