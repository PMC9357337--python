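"""Reading, validating and writing pathway networks in UCSC Pathway Tab Format.

A pathway file is UTF-8, tab-separated. Lines starting with ``#`` are
comments. Two-field lines declare entities (``<class>\\t<id>``), three-field
lines declare directed interactions (``<source>\\t<target>\\t<code>``). One
pathway per file; a directory of files forms a pathway collection.

The in-memory model distinguishes three entity classes:

``gene``
    a leaf node standing for a gene or its protein product; the only class
    that carries experimental expression status and the only knockout
    candidate.
``complex``
    a molecular complex: active iff *all* of its component parents are
    active (AND semantics).
``abstract``
    a biological process or family node (e.g. "Wnt receptor signaling
    pathway"); complexes and abstracts together form the *active set* A of
    entities whose activation can be demanded of the cell.

Four interaction kinds are supported: ``component`` (AND parentage),
``member`` (OR parentage), ``activation`` and ``inhibition`` (a signed
balance resolved by the ILP layer). Raw file codes are normalised through a
dialect table (see :data:`RELATION_CODES`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Entity",
    "Interaction",
    "ParentSets",
    "PathwayNetwork",
    "PathwayParseError",
    "PathwayValidationError",
    "parse_pathway",
    "write_pathway",
    "read_pathway_file",
    "read_pathway_dir",
]

GENE = "gene"
COMPLEX = "complex"
ABSTRACT = "abstract"

#: normalisation of raw entity-class tokens to the three model classes
ENTITY_CLASSES: Mapping[str, str] = {
    "gene": GENE,
    "protein": GENE,
    "rna": GENE,
    "complex": COMPLEX,
    "abstract": ABSTRACT,
    "family": ABSTRACT,
}

#: dialect table: raw interaction codes -> semantic relation.
#: ``-a>``/``-t>`` (protein- and transcription-level activation) are not
#: distinguished by the model, likewise for inhibition.
RELATION_CODES: Mapping[str, str] = {
    "component>": "component",
    "member>": "member",
    "-a>": "activation",
    "-t>": "activation",
    "-a|": "inhibition",
    "-t|": "inhibition",
}

#: codes accepted only in lenient mode (phosphorylation-qualified edges)
LENIENT_RELATION_CODES: Mapping[str, str] = {
    "-ap>": "activation",
    "-ap|": "inhibition",
}

#: canonical code emitted for each relation on write
CANONICAL_CODES: Mapping[str, str] = {
    "component": "component>",
    "member": "member>",
    "activation": "-a>",
    "inhibition": "-a|",
}

RELATIONS = frozenset(CANONICAL_CODES)


class PathwayParseError(ValueError):
    """A line of a pathway file is structurally malformed."""


class PathwayValidationError(ValueError):
    """A structurally well-formed pathway violates the model invariants."""


@dataclass(frozen=True)
class Entity:
    """A pathway vertex."""

    id: str
    entity_class: str

    def __post_init__(self) -> None:
        if not self.id:
            raise PathwayValidationError("entity id must be non-empty")
        if self.entity_class not in (GENE, COMPLEX, ABSTRACT):
            raise PathwayValidationError(
                f"unknown entity class {self.entity_class!r} for {self.id!r}"
            )


@dataclass(frozen=True)
class Interaction:
    """A typed directed edge ``source -> target``."""

    source: str
    target: str
    relation: str

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise PathwayValidationError(f"unknown relation {self.relation!r}")


@dataclass(frozen=True)
class ParentSets:
    """The parents of one entity, partitioned by interaction kind.

    ``activators``/``inhibitors`` are the sets J_i / I_i feeding the
    activation-balance constraint of the ILP layer.
    """

    component: frozenset[str]
    member: frozenset[str]
    activators: frozenset[str]
    inhibitors: frozenset[str]

    @property
    def all_parents(self) -> frozenset[str]:
        return self.component | self.member | self.activators | self.inhibitors

    @property
    def n(self) -> int:
        """Number of distinct parent entities (N^i)."""
        return len(self.all_parents)


_EMPTY = frozenset()


class PathwayNetwork:
    """A validated typed directed multigraph for one pathway.

    Parameters
    ----------
    name:
        Pathway name (conventionally the file stem).
    entities:
        Entity declarations; ids must be unique (case-sensitive).
    interactions:
        Typed edges; endpoints must be declared entities. Duplicate edges
        (same source, target and relation) are collapsed with a warning.
    """

    def __init__(
        self,
        name: str,
        entities: Iterable[Entity] = (),
        interactions: Iterable[Interaction] = (),
    ) -> None:
        self.name = name
        self._entities: dict[str, Entity] = {}
        for ent in entities:
            if ent.id in self._entities:
                raise PathwayValidationError(
                    f"{name}: duplicate entity id {ent.id!r}"
                )
            self._entities[ent.id] = ent
        seen: set[Interaction] = set()
        edges: list[Interaction] = []
        for ia in interactions:
            for endpoint in (ia.source, ia.target):
                if endpoint not in self._entities:
                    raise PathwayValidationError(
                        f"{name}: interaction references undeclared entity "
                        f"{endpoint!r}"
                    )
            if ia in seen:
                logger.warning("%s: duplicate interaction %s collapsed", name, ia)
                continue
            if ia.source == ia.target:
                logger.warning("%s: self-edge on %r", name, ia.source)
            seen.add(ia)
            edges.append(ia)
        self._interactions: tuple[Interaction, ...] = tuple(edges)
        self._parents: dict[str, ParentSets] | None = None

    # -- basic views -------------------------------------------------------

    @property
    def entities(self) -> Mapping[str, Entity]:
        return self._entities

    @property
    def interactions(self) -> tuple[Interaction, ...]:
        return self._interactions

    @property
    def genes(self) -> list[str]:
        """Sorted ids of all gene-class entities."""
        return sorted(e.id for e in self._entities.values() if e.entity_class == GENE)

    @property
    def actives(self) -> list[str]:
        """The active set A: sorted ids of all complexes and abstracts."""
        return sorted(
            e.id
            for e in self._entities.values()
            if e.entity_class in (COMPLEX, ABSTRACT)
        )

    def __len__(self) -> int:
        return len(self._entities)

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._entities

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"PathwayNetwork({self.name!r}, {len(self._entities)} entities, "
            f"{len(self._interactions)} interactions)"
        )

    # -- derived structure -------------------------------------------------

    def parents(self, entity_id: str) -> ParentSets:
        """Partition the parents B^i of ``entity_id`` by interaction kind."""
        if entity_id not in self._entities:
            raise KeyError(f"{self.name}: unknown entity {entity_id!r}")
        if self._parents is None:
            buckets: dict[str, dict[str, set[str]]] = {
                e: {r: set() for r in RELATIONS} for e in self._entities
            }
            for ia in self._interactions:
                buckets[ia.target][ia.relation].add(ia.source)
            self._parents = {
                e: ParentSets(
                    component=frozenset(b["component"]),
                    member=frozenset(b["member"]),
                    activators=frozenset(b["activation"]),
                    inhibitors=frozenset(b["inhibition"]),
                )
                for e, b in buckets.items()
            }
        return self._parents[entity_id]

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph(name=self.name)
        for ent in self._entities.values():
            g.add_node(ent.id, entity_class=ent.entity_class)
        for ia in self._interactions:
            g.add_edge(ia.source, ia.target, relation=ia.relation)
        return g

    def has_cycles(self) -> bool:
        return not nx.is_directed_acyclic_graph(self.to_networkx())

    def same_topology(self, other: "PathwayNetwork") -> bool:
        """True if entity set (with classes) and interaction set coincide."""
        return (
            self._entities == other._entities
            and set(self._interactions) == set(other._interactions)
        )


def _normalise_relation(code: str, strict: bool) -> str | None:
    if code in RELATION_CODES:
        return RELATION_CODES[code]
    if not strict and code in LENIENT_RELATION_CODES:
        return LENIENT_RELATION_CODES[code]
    if strict:
        raise PathwayValidationError(f"unknown relation code {code!r}")
    logger.warning("skipping interaction with unknown relation code %r", code)
    return None


def parse_pathway(text: str, name: str = "pathway", strict: bool = True) -> PathwayNetwork:
    """Parse one pathway from raw pathway-tab content.

    Parameters
    ----------
    text:
        Raw file content (tab-separated; ``#`` comment lines ignored).
    name:
        Name to assign to the parsed pathway.
    strict:
        In strict mode unknown entity classes and relation codes raise
        :class:`PathwayValidationError`; in lenient mode unknown lines are
        skipped with a warning and phosphorylation-qualified codes map to
        activation/inhibition.
    """
    entities: list[Entity] = []
    raw_edges: list[tuple[int, str, str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip("\r\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 2:
            raw_class, entity_id = fields
            key = raw_class.strip().lower()
            if key not in ENTITY_CLASSES:
                if strict:
                    raise PathwayValidationError(
                        f"{name}:{lineno}: unknown entity class {raw_class!r}"
                    )
                logger.warning(
                    "%s:%d: skipping entity with unknown class %r",
                    name,
                    lineno,
                    raw_class,
                )
                continue
            entities.append(Entity(entity_id.strip(), ENTITY_CLASSES[key]))
        elif len(fields) == 3:
            source, target, code = (f.strip() for f in fields)
            raw_edges.append((lineno, source, target, code))
        else:
            raise PathwayParseError(
                f"{name}:{lineno}: expected 2 or 3 tab-separated fields, "
                f"got {len(fields)}"
            )
    interactions: list[Interaction] = []
    for lineno, source, target, code in raw_edges:
        try:
            relation = _normalise_relation(code, strict)
        except PathwayValidationError as exc:
            raise PathwayValidationError(f"{name}:{lineno}: {exc}") from None
        if relation is not None:
            interactions.append(Interaction(source, target, relation))
    return PathwayNetwork(name, entities, interactions)


def write_pathway(network: PathwayNetwork) -> str:
    """Serialise a network to canonical pathway-tab text.

    Entity lines precede interaction lines; both blocks are sorted
    lexicographically, so any two topologically identical networks
    serialise to byte-identical text.
    """
    entity_lines = sorted(
        f"{e.entity_class}\t{e.id}" for e in network.entities.values()
    )
    edge_lines = sorted(
        f"{ia.source}\t{ia.target}\t{CANONICAL_CODES[ia.relation]}"
        for ia in network.interactions
    )
    return "\n".join(entity_lines + edge_lines) + "\n"


def read_pathway_file(path: str | Path, strict: bool = True) -> PathwayNetwork:
    path = Path(path)
    return parse_pathway(path.read_text(), name=path.stem, strict=strict)


def read_pathway_dir(path: str | Path, strict: bool = True) -> list[PathwayNetwork]:
    """Load every ``*.tab`` (or ``*.txt``) file of a directory, sorted by name."""
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"not a directory: {path}")
    files = sorted(
        p for p in path.iterdir() if p.suffix in (".tab", ".txt") and p.is_file()
    )
    return [read_pathway_file(p, strict=strict) for p in files]
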