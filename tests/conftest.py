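import pytest

from compactid import builtin_fixture_registry


@pytest.fixture()
def reg():
    """Fresh built-in fixture registry per test (records are mutable)."""
    return builtin_fixture_registry()


def brute_force_uniqueness_errors(registry):
    """Independent oracle: count uniqueness breaches by pairwise scan.

    Walks every namespace/alias/provider token (case-folded) and counts,
    for each token class, occurrences beyond the first — without using
    the registry's indices or the validator.
    """
    namespaces, aliases, providers = [], [], []
    for rec in registry.records:
        namespaces.append(rec.namespace.casefold())
        aliases.extend(a.casefold() for a in rec.aliases)
        providers.extend(p.code.casefold() for p in rec.providers)

    def surplus(tokens):
        count = 0
        for i, tok in enumerate(tokens):
            if any(tokens[j] == tok for j in range(i)):
                count += 1
        return count

    # Aliases must also be disjoint from the namespace set.
    alias_ns_clash = sum(
        1 for i, a in enumerate(aliases)
        if a in namespaces and a not in aliases[:i]
    )
    return {
        "namespace": surplus(namespaces),
        "alias": surplus(aliases) + alias_ns_clash,
        "provider": surplus(providers),
    }
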