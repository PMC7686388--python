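"""Shared fixtures: the seed knowledge base, the three canonical query
specifications, and randomly generated synthetic knowledge bases."""

from __future__ import annotations

import pytest

from gutbrainkg.fixtures import FixtureConfig, build_seed_kb, generate_synthetic
from gutbrainkg.inference import QuerySpec
from gutbrainkg.kg_builder import build_abox
from gutbrainkg.schema_model import KnowledgeBase


@pytest.fixture(scope="session")
def seed_kb() -> KnowledgeBase:
    return build_seed_kb()


@pytest.fixture(scope="session")
def microbe_query_spec() -> QuerySpec:
    """Microbe-based query: B. dentium against anxiety + depression."""
    return QuerySpec(
        mode="by_microbe",
        microbe="Bifidobacterium dentium",
        disorders=("Anxiety disorders", "Depressive disorder"),
    )


@pytest.fixture(scope="session")
def ntm_query_spec() -> QuerySpec:
    """Neurotransmitter-based query: acetylcholine, level C only."""
    return QuerySpec(
        mode="by_neurotransmitter",
        neurotransmitters=("Acetylcholine",),
        level_filter=frozenset({"C"}),
    )


@pytest.fixture(scope="session")
def disorder_query_spec() -> QuerySpec:
    """Disorder-based query: bipolar via dopamine AND norepinephrine."""
    return QuerySpec(
        mode="by_disorder",
        disorders=("Bipolar disorder",),
        neurotransmitters=("Dopamine", "Norepinephrine"),
    )


def synthetic_kb(seed: int, **overrides) -> KnowledgeBase:
    """A small random tripartite KB; dense enough that queries usually
    return rows."""
    params = dict(
        n_microbes=6,
        n_ntms=4,
        n_disorders=5,
        statement_density=0.35,
        relationship_density=0.45,
        seed=seed,
    )
    params.update(overrides)
    stmt_rows, rel_rows = generate_synthetic(FixtureConfig(**params))
    return build_abox(stmt_rows, rel_rows)


@pytest.fixture(scope="session")
def random_kbs() -> list[KnowledgeBase]:
    """Twenty random fixtures shared by the property suites."""
    return [synthetic_kb(seed) for seed in range(20)]
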