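"""Registry loading, validation, lookup and round-trip serialization."""

import copy

import pytest
import yaml

from compactid import (
    GeneratorSpec,
    NotFoundError,
    PrefixRecord,
    ProviderRecord,
    Registry,
    SchemaError,
    load_registry,
    lookup_namespace,
    lookup_provider,
    random_registry,
    validate_registry,
    write_registry,
)
from compactid.errors import RegistryParseError

from conftest import brute_force_uniqueness_errors


class TestLoading:
    def test_fixture_has_six_namespaces(self, reg):
        assert sorted(r.namespace for r in reg) == [
            "arrayexpress", "chembl.target", "go", "mgi", "pdb", "taxon",
        ]

    def test_empty_document_gives_empty_registry(self):
        assert len(load_registry("")) == 0
        assert len(load_registry("records:\n")) == 0

    @pytest.mark.parametrize("missing", ["namespace", "title", "providers"])
    def test_missing_required_field_names_it(self, missing):
        record = {
            "namespace": "x",
            "title": "X",
            "providers": [{"code": "p", "url_template": "https://h/{id}"}],
        }
        del record[missing]
        text = yaml.safe_dump({"records": [record]})
        with pytest.raises(SchemaError, match=missing):
            load_registry(text)

    def test_missing_provider_url_template_is_schema_error(self):
        text = (
            "records:\n  - namespace: x\n    title: X\n"
            "    providers:\n      - code: p\n"
        )
        with pytest.raises(SchemaError, match="url_template"):
            load_registry(text)

    def test_malformed_yaml_reports_line(self):
        with pytest.raises(RegistryParseError, match="line"):
            load_registry("records:\n  - namespace: [unclosed\n  bad: :")

    def test_load_from_path(self, reg, tmp_path):
        p = tmp_path / "reg.yaml"
        p.write_text(write_registry(reg), encoding="utf-8")
        assert load_registry(p) == reg
        assert load_registry(str(p)) == reg


class TestValidation:
    def test_fixture_is_clean(self, reg):
        assert validate_registry(reg) == []
        assert brute_force_uniqueness_errors(reg) == {
            "namespace": 0, "alias": 0, "provider": 0,
        }

    def test_duplicate_namespace_yields_one_error(self, reg):
        reg.add(PrefixRecord(
            namespace="pdb", title="shadow", providers=[
                ProviderRecord(code="other1", url_template="https://h/{id}")],
        ))
        errors = [v for v in validate_registry(reg) if v.severity == "error"]
        assert [v.rule_id for v in errors] == ["E_NAMESPACE_DUP"]
        assert brute_force_uniqueness_errors(reg)["namespace"] == 1

    def test_duplicate_provider_code_across_namespaces(self, reg):
        reg.add(PrefixRecord(
            namespace="newns", title="N", providers=[
                ProviderRecord(code="ncbi", url_template="https://h/{id}")],
        ))
        errors = [v for v in validate_registry(reg) if v.severity == "error"]
        assert [v.rule_id for v in errors] == ["E_PROVIDER_DUP"]
        assert brute_force_uniqueness_errors(reg)["provider"] == 1

    def test_alias_colliding_with_namespace(self, reg):
        reg.add(PrefixRecord(
            namespace="newns", title="N", aliases=["taxon"], providers=[
                ProviderRecord(code="other2", url_template="https://h/{id}")],
        ))
        errors = [v for v in validate_registry(reg) if v.severity == "error"]
        assert [v.rule_id for v in errors] == ["E_ALIAS_DUP"]
        assert brute_force_uniqueness_errors(reg)["alias"] == 1

    def test_injected_violations_counted_exactly_by_oracle(self, reg):
        """k injected uniqueness breaches -> exactly k errors, matching
        the independent pairwise-scan oracle."""
        reg.add(PrefixRecord(
            namespace="go", title="dup ns", aliases=["ncbitaxon"], providers=[
                ProviderRecord(code="rcsb", url_template="https://h/{id}")],
        ))
        errors = [v for v in validate_registry(reg) if v.severity == "error"]
        oracle = brute_force_uniqueness_errors(reg)
        assert sorted(v.rule_id for v in errors) == [
            "E_ALIAS_DUP", "E_NAMESPACE_DUP", "E_PROVIDER_DUP",
        ]
        assert sum(oracle.values()) == len(errors) == 3

    def test_structural_invariants_flagged(self):
        rec = PrefixRecord(
            namespace="Bad Ns", title="  ", aliases=["bad ns", "x"],
            display_prefix="OTHER", pattern="([",
            providers=[
                ProviderRecord(code="P!", url_template="ftp://h/{id}{id}",
                               primary=True),
                ProviderRecord(code="q1", url_template="https://h/no-slot",
                               primary=True),
            ],
        )
        ids = {v.rule_id for v in validate_registry(Registry([rec]))}
        assert ids >= {
            "E_NAMESPACE_TOKEN", "E_TITLE_EMPTY", "E_ALIAS_TOKEN",
            "E_DISPLAY_PREFIX", "E_PATTERN_INVALID", "E_PROVIDER_TOKEN",
            "E_TEMPLATE_SCHEME", "E_TEMPLATE_PLACEHOLDER", "E_MULTI_PRIMARY",
        }

    def test_alias_repeating_own_namespace(self):
        rec = PrefixRecord(
            namespace="x", title="X", aliases=["x"],
            providers=[ProviderRecord(code="px", url_template="https://h/{id}")],
        )
        assert [v.rule_id for v in validate_registry(Registry([rec]))] == ["E_ALIAS_SELF"]

    def test_unknown_keys_warn_but_do_not_error(self):
        reg = load_registry(
            "records:\n  - namespace: x\n    title: X\n    color: blue\n"
            "    providers:\n      - code: px\n"
            "        url_template: https://h/{id}\n        weight: 3\n"
        )
        violations = validate_registry(reg)
        assert {v.severity for v in violations} == {"warning"}
        assert {v.rule_id for v in violations} == {"W_UNKNOWN_KEY"}
        assert len(violations) == 2

    def test_output_order_is_deterministic(self, reg):
        reg.records[0].title = ""
        reg.records[0].aliases.append("taxon")
        v1 = [ (v.rule_id, v.location) for v in validate_registry(reg)]
        v2 = [ (v.rule_id, v.location) for v in validate_registry(copy.deepcopy(reg))]
        assert v1 == v2
        assert v1 == [("E_ALIAS_SELF", "taxon"), ("E_TITLE_EMPTY", "taxon")]


class TestLookup:
    @pytest.mark.parametrize("token,ns", [
        ("GO", "go"),            # uppercase display form resolves
        ("taxon", "taxon"),
        ("ncbitaxon", "taxon"),  # alias
        ("MGI", "mgi"),
        ("CHEMBL.TARGET", "chembl.target"),
    ])
    def test_namespace_and_alias_casefold(self, reg, token, ns):
        assert lookup_namespace(reg, token).namespace == ns

    def test_unknown_namespace(self, reg):
        with pytest.raises(NotFoundError):
            lookup_namespace(reg, "nosuchprefix")

    @pytest.mark.parametrize("code,ns", [
        ("rcsb", "pdb"), ("bptl", "taxon"), ("NCBI", "taxon"),
    ])
    def test_provider_lookup(self, reg, code, ns):
        rec, prov = lookup_provider(reg, code)
        assert rec.namespace == ns
        assert prov.code == code.lower()

    def test_unknown_provider(self, reg):
        with pytest.raises(NotFoundError):
            lookup_provider(reg, "zzzz")

    def test_index_consistency(self, reg):
        """Every token reachable by iteration is findable via lookup, and
        the indices contain nothing else."""
        ns_tokens, alias_tokens, prov_tokens = set(), set(), set()
        for rec in reg:
            ns_tokens.add(rec.namespace)
            assert lookup_namespace(reg, rec.namespace) is rec
            for a in rec.aliases:
                alias_tokens.add(a)
                assert lookup_namespace(reg, a) is rec
            for p in rec.providers:
                prov_tokens.add(p.code)
                assert lookup_provider(reg, p.code) == (rec, p)
        assert set(reg.namespace_index) == {t.casefold() for t in ns_tokens}
        assert set(reg.alias_index) == {t.casefold() for t in alias_tokens}
        assert set(reg.provider_index) == {t.casefold() for t in prov_tokens}


class TestRoundTrip:
    def test_fixture_round_trips(self, reg):
        assert load_registry(write_registry(reg)) == reg

    def test_empty_registry_round_trips(self):
        empty = Registry([])
        assert load_registry(write_registry(empty)) == empty

    @pytest.mark.parametrize("seed", [42, 7, 123])
    def test_random_registries_round_trip(self, seed):
        r = random_registry(GeneratorSpec(seed=seed, n_namespaces=30))
        assert load_registry(write_registry(r)) == r

    def test_unknown_keys_preserved(self):
        text = (
            "records:\n  - namespace: x\n    title: X\n    color: blue\n"
            "    providers:\n      - code: px\n"
            "        url_template: https://h/{id}\n"
        )
        reg = load_registry(text)
        again = load_registry(write_registry(reg))
        assert again.records[0].extra == {"color": "blue"}
        assert again == reg
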