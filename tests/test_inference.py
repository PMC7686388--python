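"""Tests for SPARQL rendering, query execution, the native-join oracle,
and the inference invariants (oracle equivalence, monotonicity, filter
containment, DISTINCT, language contract)."""

import pytest

from gutbrainkg.curation_io import RelationshipTableRow, StatementTableRow
from gutbrainkg.inference import (
    QueryMode,
    QuerySpec,
    QuerySpecError,
    infer_microbe_disorder_pairs,
    native_join,
    render_sparql,
    run_query,
)
from gutbrainkg.kg_builder import build_abox, merge_graphs
from gutbrainkg.schema_model import Direction, EvidenceLevel, KnowledgeBase

from conftest import synthetic_kb


class TestQuerySpecValidation:
    def test_by_microbe_requires_microbe(self):
        with pytest.raises(QuerySpecError):
            QuerySpec(mode="by_microbe")

    def test_by_ntm_requires_exactly_one(self):
        with pytest.raises(QuerySpecError):
            QuerySpec(mode="by_neurotransmitter", neurotransmitters=("GABA", "Dopamine"))

    def test_by_disorder_requires_ntms(self):
        with pytest.raises(QuerySpecError):
            QuerySpec(mode="by_disorder", disorders=("Bipolar disorder",))


class TestSparqlRendering:
    def test_two_disorders_emit_one_union(self, microbe_query_spec):
        text = render_sparql(microbe_query_spec)
        assert text.count("UNION") == 1
        assert "SELECT DISTINCT" in text

    def test_single_disorder_no_union(self):
        spec = QuerySpec(mode="by_microbe", microbe="Clostridium", disorders=("Bipolar disorder",))
        assert "UNION" not in render_sparql(spec)

    def test_level_filter_clause_present(self, ntm_query_spec):
        text = render_sparql(ntm_query_spec)
        assert 'FILTER ( ?level = "C" )' in text

    def test_level_set_filter_uses_in(self):
        spec = QuerySpec(
            mode="by_neurotransmitter",
            neurotransmitters=("GABA",),
            level_filter=frozenset({"A", "B"}),
        )
        assert 'FILTER ( ?level IN ("A", "B") )' in render_sparql(spec)

    def test_intersection_uses_filter_exists(self, disorder_query_spec):
        text = render_sparql(disorder_query_spec)
        assert text.count("FILTER EXISTS") == 1  # one per extra neurotransmitter

    def test_language_filters_present(self, microbe_query_spec):
        text = render_sparql(microbe_query_spec)
        assert 'LANG(?mdLabel) = "en"' in text


class TestSeedQueries:
    """The three canonical queries against the seed knowledge base."""

    def test_microbe_query_rows(self, seed_kb, microbe_query_spec):
        rows = run_query(seed_kb, microbe_query_spec)
        assert len(rows) == 3
        assert {r.neurotransmitter_labels for r in rows} == {("GABA",)}
        assert {r.pmid for r in rows} == {29866843, 27458085, 22612585}
        assert sorted(r.level.value for r in rows) == ["B", "B", "C"]
        assert all(
            r.disorder_labels == ("Anxiety disorders", "Depressive disorder") for r in rows
        )

    def test_ntm_query_rows(self, seed_kb, ntm_query_spec):
        rows = run_query(seed_kb, ntm_query_spec)
        assert len(rows) == 6
        assert {r.microbe_label for r in rows} == {"Lactobacillus plantarum"}
        assert {r.direction for r in rows} == {Direction.INCREASE}
        assert {r.pmid for r in rows} == {907345}
        assert {r.disorder_labels[0] for r in rows} == {
            "Depressive disorder",
            "Sleep disorders",
            "Sex behavior disorder",
            "Bipolar disorder",
            "Cognition disorders",
            "Autistic disorder",
        }

    def test_disorder_query_rows(self, seed_kb, disorder_query_spec):
        rows = run_query(seed_kb, disorder_query_spec)
        assert len(rows) == 7
        observed = {(r.microbe_label, r.reference_label, r.pmid, r.level.value) for r in rows}
        assert observed == {
            ("Clostridium", "Asano 2012", 23064760, "B"),
            ("Escherichia coli", "Shishov 2009", 19845286, "C"),
            ("Bacillus mycoides", "Tsavkelova 2000", 10935181, "C"),
            ("Bacillus subtilis", "Tsavkelova 2000", 10935181, "C"),
            ("Escherichia coli", "Tsavkelova 2000", 10935181, "C"),
            ("Proteus vulgaris", "Tsavkelova 2000", 10935181, "C"),
            ("Serratia marcescens", "Tsavkelova 2000", 10935181, "C"),
        }

    def test_case_insensitive_entity_labels(self, seed_kb):
        spec = QuerySpec(
            mode="by_microbe",
            microbe="bifidobacterium DENTIUM",
            disorders=("anxiety disorders",),
        )
        assert len(run_query(seed_kb, spec)) == 3

    def test_empty_kb_returns_empty(self, microbe_query_spec, ntm_query_spec, disorder_query_spec):
        kb = KnowledgeBase()
        for spec in (microbe_query_spec, ntm_query_spec, disorder_query_spec):
            assert run_query(kb, spec) == []
            assert native_join(kb, spec) == []


def _specs_for(kb):
    """One spec per mode drawn from a knowledge base's own entities."""
    from gutbrainkg.schema_model import EntityKind

    microbes = kb.entities_of_kind(EntityKind.GUT_MICROBIOTA)
    ntms = kb.entities_of_kind(EntityKind.NEUROTRANSMITTER)
    disorders = kb.entities_of_kind(EntityKind.MENTAL_DISORDER)
    specs = []
    if microbes and disorders:
        specs.append(
            QuerySpec(
                mode="by_microbe",
                microbe=microbes[0].label(),
                disorders=tuple(d.label() for d in disorders[:2]),
            )
        )
    if ntms:
        specs.append(
            QuerySpec(mode="by_neurotransmitter", neurotransmitters=(ntms[0].label(),))
        )
    if ntms and disorders:
        specs.append(
            QuerySpec(
                mode="by_disorder",
                disorders=(disorders[0].label(),),
                neurotransmitters=(ntms[0].label(),),
            )
        )
        if len(ntms) >= 2:
            specs.append(
                QuerySpec(
                    mode="by_disorder",
                    disorders=(disorders[0].label(),),
                    neurotransmitters=tuple(n.label() for n in ntms[:2]),
                )
            )
    return specs


class TestOracleEquivalence:
    def test_seed_kb_all_modes(self, seed_kb, microbe_query_spec, ntm_query_spec, disorder_query_spec):
        for spec in (microbe_query_spec, ntm_query_spec, disorder_query_spec):
            assert run_query(seed_kb, spec) == native_join(seed_kb, spec)

    def test_random_fixtures_all_modes(self, random_kbs):
        """SPARQL execution and the relational join agree on twenty
        random tripartite graphs in all three query modes."""
        checked = 0
        for kb in random_kbs:
            for spec in _specs_for(kb):
                assert run_query(kb, spec) == native_join(kb, spec)
                checked += 1
        assert checked >= 60

    def test_with_level_filters(self, random_kbs):
        for kb in random_kbs[:5]:
            for spec in _specs_for(kb):
                filtered = QuerySpec(
                    mode=spec.mode,
                    microbe=spec.microbe,
                    neurotransmitters=spec.neurotransmitters,
                    disorders=spec.disorders,
                    level_filter=frozenset({"B", "C"}),
                )
                assert run_query(kb, filtered) == native_join(kb, filtered)


class TestInvariants:
    def test_filter_containment(self, seed_kb, random_kbs):
        """Results under a smaller admissible-level set are a subset of
        results under a superset."""
        small = frozenset({"C"})
        large = frozenset({"B", "C"})
        for kb in [seed_kb] + random_kbs[:5]:
            for spec in _specs_for(kb):
                rows_small = set(
                    native_join(kb, QuerySpec(
                        mode=spec.mode, microbe=spec.microbe,
                        neurotransmitters=spec.neurotransmitters,
                        disorders=spec.disorders, level_filter=small,
                    ))
                )
                rows_large = set(
                    native_join(kb, QuerySpec(
                        mode=spec.mode, microbe=spec.microbe,
                        neurotransmitters=spec.neurotransmitters,
                        disorders=spec.disorders, level_filter=large,
                    ))
                )
                assert rows_small <= rows_large

    def test_monotonicity_under_growth(self, random_kbs):
        """Adding statements/relationships never removes result rows
        (the query patterns contain no negation)."""
        for i in range(4):
            kb_small = random_kbs[i]
            kb_grown = merge_graphs(kb_small, random_kbs[i + 10])
            for spec in _specs_for(kb_small):
                before = set(native_join(kb_small, spec))
                after = set(native_join(kb_grown, spec))
                if spec.mode is QueryMode.BY_MICROBE:
                    # disorder labels regroup as coverage grows; compare
                    # at (row minus grouped-disorder) granularity
                    flatten = lambda rows: {
                        (r.microbe_label, r.neurotransmitter_labels, r.pmid, d)
                        for r in rows
                        for d in r.disorder_labels
                    }
                    assert flatten(before) <= flatten(after)
                else:
                    assert before <= after

    def test_distinct_rows(self, seed_kb, random_kbs):
        for kb in [seed_kb] + random_kbs[:5]:
            for spec in _specs_for(kb):
                rows = run_query(kb, spec)
                assert len(rows) == len(set(rows))

    def test_language_contract(self, seed_kb):
        """Returned labels are the requested-language labels."""
        spec = QuerySpec(
            mode="by_neurotransmitter", neurotransmitters=("Acetylcholine",), language="en"
        )
        for row in run_query(seed_kb, spec):
            assert row.microbe_label and row.disorder_labels
        # a language with no labels in the graph yields nothing
        spec_nl = QuerySpec(
            mode="by_neurotransmitter", neurotransmitters=("Acetylcholine",), language="nl"
        )
        assert run_query(seed_kb, spec_nl) == []

    def test_deterministic_ordering(self, seed_kb, disorder_query_spec):
        rows = run_query(seed_kb, disorder_query_spec)
        keys = [r.sort_key for r in rows]
        assert keys == sorted(keys)
        assert rows[0].level is EvidenceLevel.B  # strongest evidence first


class TestImplicitPairs:
    def test_seed_pairs_include_known_links(self, seed_kb):
        pairs = {(p.microbe_label, p.disorder_label) for p in infer_microbe_disorder_pairs(seed_kb)}
        assert ("Bifidobacterium dentium", "Anxiety disorders") in pairs
        assert ("Lactobacillus plantarum", "Bipolar disorder") in pairs

    def test_best_level_is_strongest_chain(self, seed_kb):
        pairs = {
            (p.microbe_label, p.disorder_label): p
            for p in infer_microbe_disorder_pairs(seed_kb)
        }
        p = pairs[("Bifidobacterium dentium", "Anxiety disorders")]
        assert p.best_level is EvidenceLevel.B
        assert p.n_chains == 3  # three references for the GABA statement

    def test_no_relationships_no_pairs(self):
        kb = build_abox(
            [StatementTableRow("Clostridium", "GABA", Direction.MODULATE, "A 2020", 101, EvidenceLevel.B)],
            [],
        )
        assert infer_microbe_disorder_pairs(kb) == []

    def test_level_filter_restricts_chains(self, seed_kb):
        pairs = infer_microbe_disorder_pairs(seed_kb, level_filter={"B"})
        assert all(p.best_level is EvidenceLevel.B for p in pairs)
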