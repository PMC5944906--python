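# compactid

Compact-identifier (CURIE) resolution for biomedical data: a prefix
registry with a linter, a parser/normalizer for the compact-identifier
grammar, URL-template redirection, a minimal HTTP redirect service, and
a CLI.

## The problem

Most biomedical repositories issue accessions that are unique only
locally — `2gc4` in the Protein Data Bank, `9606` in the NCBI Taxonomy,
`E-GEOD-2599` in ArrayExpress. Prefixing an accession with a registered
namespace makes it globally unique:

```
<prefix>:<LUI>                e.g.  pdb:2gc4
```

where the LUI (locally unique identifier) is the accession as issued.
Hosting the compact identifier on a meta-resolver URL makes it
persistent and machine-resolvable — the resolver redirects to whichever
provider currently hosts the record, so citations survive provider
relocation:

```
https://identifiers.org/pdb:2gc4   →   https://www.ebi.ac.uk/pdbe/entry/pdb/2gc4
https://n2t.net/pdb:2gc4           →   (same)
```

When several providers host the same collection (PDBe and RCSB both
serve PDB entries), an optional registry-wide-unique provider code
selects one explicitly; the full grammar is

```
(<resolver>/)<provider>/<prefix>:<LUI>      e.g.  rcsb/pdb:2gc4
```

Two normalization rules keep identifiers canonical: accessions issued
*with* an embedded prefix and colon (`GO:0003214`, `MGI:80863`) are not
doubled when the prefix is prepended (`GO:0003214`, never
`GO:GO:0003214`), while prefixes embedded *without* a colon are part of
the accession and are retained (`chembl.target:CHEMBL2842`).

This package implements the whole pipeline — registry file format with
registry-wide uniqueness constraints on namespaces, aliases, and
provider codes; grammar with the duplication rule; provider selection
(explicit code, else the primary, else the first listed); LUI pattern
validation; `{id}` template expansion; persistent-URL construction; and
a stateless 302-redirect endpoint — for anyone building or testing
identifier-resolution infrastructure, plus seeded generators for
property testing it.

## Worked example

```pycon
>>> import compactid as c
>>> reg = c.builtin_fixture_registry()        # 6 namespaces, no download
>>> res = c.resolve(reg, "rcsb/pdb:2gc4")
>>> res.target_url
'https://rcsb.example/structure/2gc4'
>>> res = c.resolve(reg, "https://identifiers.org/arrayexpress:E-GEOD-2599")
>>> res.target_url
'https://www.ebi.ac.uk/arrayexpress/experiments/E-GEOD-2599'
>>> res.persistent_urls
['https://identifiers.org/arrayexpress:E-GEOD-2599', 'https://n2t.net/arrayexpress:E-GEOD-2599']
>>> c.normalize("go", "GO:0003214", reg)
'GO:0003214'
```

The target URL is the provider's (non-persistent) location obtained by
substituting the LUI into the selected provider's URL template; the
persistent URLs are the resolver-hosted forms suitable for citation.

The same from the shell:

```sh
$ compactid resolve taxon:9606
provider:   ncbi (NCBI (primary source))
target:     https://ncbi.example/taxonomy/9606
persistent: https://identifiers.org/taxon:9606
persistent: https://n2t.net/taxon:9606

$ compactid normalize chembl.target CHEMBL2842
chembl.target:CHEMBL2842

$ compactid validate --registry my-registry.yaml   # registry linter
$ compactid serve --port 8080                      # 302-redirect service
```

`taxon:9606` with no provider code selects NCBI because the fixture
registry flags it `primary: true`; `ols/taxon:9606` or `bptl/taxon:9606`
override the default.

## Registry file format

YAML with a top-level `records:` sequence:

```yaml
records:
  - namespace: pdb            # required; lowercase letters/digits, internal dots ok
    title: Protein Data Bank  # required
    homepage: https://www.wwpdb.org
    aliases: []               # resolvable alternate names
    pattern: '[0-9][a-z0-9]{3}'   # optional full-match LUI pattern
    display_prefix: null      # case form for rendering (GO, MGI, ...)
    providers:                # required, nonempty
      - code: pdbe            # unique across the ENTIRE registry
        url_template: https://www.ebi.ac.uk/pdbe/entry/pdb/{id}
        primary: true
```

`compactid validate` reports every constraint violation at once with a
stable rule id (`E_NAMESPACE_DUP`, `E_PROVIDER_DUP`, `E_ALIAS_DUP`, ...).

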