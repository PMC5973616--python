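"""Three-level disease hierarchy with MeSH-style dotted tree numbers.

A tree number like ``C19.246.300`` encodes the position of a concept in
the hierarchy: the dot-segment count is its level (1 = category,
2 = sub-category, 3 = disease).  A node may carry several tree numbers
(polyhierarchy), and numbers deeper than three segments are truncated to
their three-segment ancestor for all analyses here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

__all__ = ["OntologyNode", "DiseaseOntology", "tree_level", "truncate_tree_number"]


def tree_level(tree_number: str) -> int:
    """Hierarchy level of a dotted tree number (segment count)."""
    return tree_number.count(".") + 1


def truncate_tree_number(tree_number: str, max_level: int = 3) -> str:
    """Truncate a dotted tree number to at most ``max_level`` segments."""
    return ".".join(tree_number.split(".")[:max_level])


@dataclass(frozen=True)
class OntologyNode:
    node_id: str
    name: str
    tree_numbers: frozenset[str]


@dataclass
class DiseaseOntology:
    """Disease ontology: node id -> (name, set of dotted tree numbers).

    Provides the per-level denominators used by the spectrum scores:
    ``n_categories`` (D), ``subcategory_count(i)`` (d^i) and
    ``disease_count(k)`` (alpha^k).
    """

    nodes: dict[str, OntologyNode] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for node in self.nodes.values():
            for tn in node.tree_numbers:
                if tn in seen and seen[tn] != node.node_id:
                    raise ValueError(
                        f"tree number {tn} assigned to both "
                        f"{seen[tn]} and {node.node_id}"
                    )
                seen[tn] = node.node_id

    # -- construction -------------------------------------------------

    def add(self, node_id: str, name: str, tree_numbers: Iterable[str]) -> None:
        existing = self.nodes.get(node_id)
        numbers = frozenset(tree_numbers)
        if existing is not None:
            numbers = existing.tree_numbers | numbers
            name = existing.name
        self.nodes[node_id] = OntologyNode(node_id, name, numbers)

    # -- structure queries --------------------------------------------

    @property
    def all_tree_numbers(self) -> set[str]:
        out: set[str] = set()
        for node in self.nodes.values():
            out.update(node.tree_numbers)
        return out

    def categories(self) -> set[str]:
        """Level-1 prefixes present anywhere in the ontology."""
        return {tn.split(".")[0] for tn in self.all_tree_numbers}

    @property
    def n_categories(self) -> int:
        """D: total number of disease categories."""
        return len(self.categories())

    def subcategories_of(self, category: str) -> set[str]:
        """Level-2 tree numbers under a level-1 category prefix."""
        return {
            truncate_tree_number(tn, 2)
            for tn in self.all_tree_numbers
            if tree_level(tn) >= 2 and tn.split(".")[0] == category
        }

    def subcategory_count(self, category: str) -> int:
        """d^i: total sub-categories in category i."""
        return len(self.subcategories_of(category))

    def diseases_of(self, subcategory: str) -> set[str]:
        """Level-3 tree numbers under a level-2 prefix."""
        return {
            truncate_tree_number(tn, 3)
            for tn in self.all_tree_numbers
            if tree_level(tn) >= 3 and truncate_tree_number(tn, 2) == subcategory
        }

    def disease_count(self, subcategory: str) -> int:
        """alpha^k: total level-3 diseases in sub-category k."""
        return len(self.diseases_of(subcategory))

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    # -- name lookup for dictionary tagging ---------------------------

    def name_to_id(self) -> dict[str, str]:
        """Lowercased term name -> node id (ambiguous names dropped)."""
        mapping: dict[str, str] = {}
        ambiguous: set[str] = set()
        for node in self.nodes.values():
            key = node.name.lower()
            if key in mapping and mapping[key] != node.node_id:
                ambiguous.add(key)
            mapping[key] = node.node_id
        for key in ambiguous:
            logger.warning("ambiguous ontology term name dropped: %r", key)
            del mapping[key]
        return mapping

    # -- serialization ------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """One row per (id, name, tree_number)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id\tname\ttree_number\n")
            for node_id in sorted(self.nodes):
                node = self.nodes[node_id]
                for tn in sorted(node.tree_numbers):
                    fh.write(f"{node.node_id}\t{node.name}\t{tn}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DiseaseOntology":
        onto = cls()
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["id", "name", "tree_number"]:
                raise ValueError(f"unexpected ontology header: {header}")
            for line in fh:
                if not line.strip():
                    continue
                node_id, name, tn = line.rstrip("\n").split("\t")[:3]
                onto.add(node_id, name, [tn])
        return onto
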