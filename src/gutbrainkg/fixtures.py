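"""Seed dataset and synthetic curation-file generator.

The seed dataset is the small, fully desk-checkable inventory of curated
facts shipped with the package: microbe -> neurotransmitter modulation
statements with their PubMed references and evidence levels, the
neurotransmitter -> mental-disorder associations they connect to, and
the six-neurotransmitter / ten-disorder entity rosters. Facts taken from
narrative sources without a printed PMID carry flagged placeholder
references (level E, PMID in the reserved sentinel range) so that
evidence-level filters have something real to exclude; placeholder
references are excluded from citable-reference counts.

The synthetic generator emulates the same shape at arbitrary scale:
a sparse tripartite evidence graph with per-reference evidence levels
drawn from a configurable A-E distribution. It is used for
property-based testing of the round-trip, merge, and query-equivalence
contracts.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import NamedTuple

from .curation_io import (
    EntityTableRow,
    MappingTableRow,
    RelationshipTableRow,
    StatementTableRow,
    read_entity_table,
    read_mapping_table,
    read_relationship_table,
    read_statement_table,
)
from .kg_builder import attach_mappings, build_abox
from .schema_model import (
    Direction,
    EvidenceLevel,
    KnowledgeBase,
    PLACEHOLDER_PMID_FLOOR,
)

__all__ = [
    "SeedDataset",
    "seed_dataset",
    "seed_mapping_rows",
    "build_seed_kb",
    "FixtureConfig",
    "generate_synthetic",
]

_SYNTH_PMID_BASE = 10_000_000  # below the placeholder sentinel range


class SeedDataset(NamedTuple):
    statement_rows: list[StatementTableRow]
    relationship_rows: list[RelationshipTableRow]
    entity_rows: list[EntityTableRow]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("gutbrainkg").joinpath("data", name)))


def seed_dataset() -> SeedDataset:
    """The bundled curated inventory, loaded through the same validated
    readers user files go through.

    Contents: 20 modulation statements (18 backed by the 7 citable PMIDs,
    2 by a flagged placeholder), 12 neurotransmitter-disorder
    relationships, and the full 6-neurotransmitter / 10-disorder rosters.
    """
    return SeedDataset(
        statement_rows=read_statement_table(_data_path("seed_statements.tsv")),
        relationship_rows=read_relationship_table(_data_path("seed_relationships.tsv")),
        entity_rows=read_entity_table(_data_path("seed_entities.tsv")),
    )


def seed_mapping_rows() -> list[MappingTableRow]:
    """KEGG compound numbers for the six neurotransmitters."""
    return read_mapping_table(_data_path("seed_mappings.tsv"))


def build_seed_kb(*, with_mappings: bool = False) -> KnowledgeBase:
    """Build the seed knowledge base in one call."""
    seed = seed_dataset()
    kb = build_abox(seed.statement_rows, seed.relationship_rows, seed.entity_rows)
    if with_mappings:
        attach_mappings(kb, seed_mapping_rows())
    return kb


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the synthetic tripartite evidence graph.

    Defaults mirror the scale of the curated corpus the seed data was
    drawn from: ~45 microbe taxa, 6 neurotransmitters, 10 disorders,
    sparse statement coverage, and evidence levels concentrated in the
    B-D range (randomized controlled designs are rare in this
    literature, so A is uncommon).
    """

    n_microbes: int = 45
    n_ntms: int = 6
    n_disorders: int = 10
    statement_density: float = 0.08
    relationship_density: float = 0.3
    level_weights: tuple[float, float, float, float, float] = (0.05, 0.25, 0.40, 0.20, 0.10)
    max_refs_per_relationship: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_microbes, self.n_ntms, self.n_disorders) < 1:
            raise ValueError("entity counts must be positive")
        for name in ("statement_density", "relationship_density"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if len(self.level_weights) != 5 or min(self.level_weights) < 0:
            raise ValueError("level_weights must be 5 non-negative values")
        total = sum(self.level_weights)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"level_weights must sum to 1, got {total}")
        if not 1 <= self.max_refs_per_relationship <= 5:
            raise ValueError("max_refs_per_relationship must lie in [1, 5]")


def generate_synthetic(
    config: FixtureConfig,
) -> tuple[list[StatementTableRow], list[RelationshipTableRow]]:
    """Generate a random sparse tripartite curation dataset.

    Entities are named deterministically (gm_001..., ntm_001...,
    md_001...). Each (microbe, neurotransmitter) pair yields a statement
    with probability ``statement_density`` (direction uniform over the
    vocabulary, level drawn from ``level_weights``, fresh unique PMID);
    each (neurotransmitter, disorder) pair yields a relationship with
    probability ``relationship_density`` carrying 1..max_refs fresh
    references. The same seed reproduces the same rows exactly.
    """
    rng = random.Random(config.seed)
    levels = list(EvidenceLevel)
    directions = list(Direction)
    # each seed gets its own PMID block so fixtures from different seeds
    # stay mergeable without identifier collisions
    next_pmid = _SYNTH_PMID_BASE + (config.seed % 10_000) * 50_000 + 1

    microbes = [f"gm_{i:03d}" for i in range(1, config.n_microbes + 1)]
    ntms = [f"ntm_{i:03d}" for i in range(1, config.n_ntms + 1)]
    disorders = [f"md_{i:03d}" for i in range(1, config.n_disorders + 1)]

    statement_rows: list[StatementTableRow] = []
    for gm in microbes:
        for ntm in ntms:
            if rng.random() < config.statement_density:
                level = rng.choices(levels, weights=config.level_weights)[0]
                statement_rows.append(
                    StatementTableRow(
                        microbe_label=gm,
                        ntm_label=ntm,
                        direction=rng.choice(directions),
                        ref_label=f"Synth {next_pmid}",
                        pmid=next_pmid,
                        level=level,
                    )
                )
                next_pmid += 1

    relationship_rows: list[RelationshipTableRow] = []
    for ntm in ntms:
        for md in disorders:
            if rng.random() < config.relationship_density:
                n_refs = rng.randint(1, config.max_refs_per_relationship)
                labels, pmids, ref_levels = [], [], []
                for _ in range(n_refs):
                    labels.append(f"Synth {next_pmid}")
                    pmids.append(next_pmid)
                    ref_levels.append(rng.choices(levels, weights=config.level_weights)[0])
                    next_pmid += 1
                relationship_rows.append(
                    RelationshipTableRow(
                        ntm_label=ntm,
                        disorder_label=md,
                        ref_labels=tuple(labels),
                        pmids=tuple(pmids),
                        levels=tuple(ref_levels),
                    )
                )

    assert next_pmid < PLACEHOLDER_PMID_FLOOR
    return statement_rows, relationship_rows
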