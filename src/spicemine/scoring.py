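"""Hierarchy rollup, spectrum scores and culinary recommendations.

The spectrum score of a spice *s* at one polarity is

    Omega_s = Dhat_s * sum_i ( dhat_s_i / d_i )

where *Dhat_s* is the number of disease categories in which the spice is
associated with at least one sub-category, *d_i* the total sub-category
count of category *i* and *dhat_s_i* the number of distinct associated
sub-categories there.  Presence is binary: evidence counts never change
the score.  With *D* categories the score lies in [0, D^2] — 729 for
the 27 top-level disease categories.  Relative benevolence is
``delta = Omega+ - Omega-``; the category-restricted analogue

    Omega_s_i = dhat_s_i * sum_{k in i} ( alphahat_s_k / alpha_k )

(with alpha_k the level-3 disease count of sub-category k) yields the
therapeutic tradeoff score ``delta_i = Omega_i+ - Omega_i-`` used to
rank spices per disease category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from spicemine.candidates import CandidateInstance
from spicemine.ontology import DiseaseOntology, tree_level, truncate_tree_number
from spicemine.relation import NEGATIVE, POSITIVE

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationTable",
    "SpectrumReport",
    "rollup",
    "aggregate",
    "spectrum_score",
    "relative_benevolence",
    "category_spectrum",
    "recommend",
]


def rollup(
    disease_id: str, ontology: DiseaseOntology
) -> tuple[set[str], set[str], set[str]]:
    """Level-1/2/3 tree-number prefixes of a disease node.

    Tree numbers deeper than three segments are truncated to their
    three-segment ancestor; a node under several categories contributes
    all of them.
    """
    if disease_id not in ontology:
        raise KeyError(f"unknown disease id {disease_id!r}")
    cats: set[str] = set()
    subcats: set[str] = set()
    level3: set[str] = set()
    for tn in ontology.nodes[disease_id].tree_numbers:
        cats.add(truncate_tree_number(tn, 1))
        if tree_level(tn) >= 2:
            subcats.add(truncate_tree_number(tn, 2))
        if tree_level(tn) >= 3:
            level3.add(truncate_tree_number(tn, 3))
    return cats, subcats, level3


@dataclass
class AssociationTable:
    """Deduplicated (spice, disease, polarity) rows with evidence.

    ``rows`` maps each key to the supporting instance ids; a pair may
    carry both polarities as two distinct rows.
    """

    rows: dict[tuple[str, str, str], list[str]] = field(default_factory=dict)

    def add(
        self, spice_id: str, disease_id: str, polarity: str, evidence_id: str
    ) -> None:
        if polarity not in (POSITIVE, NEGATIVE):
            raise ValueError(f"polarity must be positive/negative, got {polarity!r}")
        self.rows.setdefault((spice_id, disease_id, polarity), []).append(evidence_id)

    def spices(self) -> set[str]:
        return {spice for spice, _, _ in self.rows}

    def diseases_for(self, spice_id: str, polarity: str) -> set[str]:
        return {
            disease
            for spice, disease, pol in self.rows
            if spice == spice_id and pol == polarity
        }

    def __len__(self) -> int:
        return len(self.rows)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("spice_id\tdisease_id\tpolarity\tn_evidence\tevidence\n")
            for (spice, disease, pol), ev in sorted(self.rows.items()):
                fh.write(f"{spice}\t{disease}\t{pol}\t{len(ev)}\t{','.join(ev)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AssociationTable":
        table = cls()
        with open(path, encoding="utf-8") as fh:
            fh.readline()
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                spice, disease, pol = parts[0], parts[1], parts[2]
                evidence = parts[4].split(",") if len(parts) > 4 and parts[4] else ["?"]
                for ev in evidence:
                    table.add(spice, disease, pol, ev)
        return table


def aggregate(
    classified: Iterable[tuple[CandidateInstance, str]],
    overrides: Iterable[tuple[str, str, str, str]] | None = None,
) -> AssociationTable:
    """Group classified instances into the association table.

    ``classified`` yields (instance, predicted label); no-association
    instances are discarded.  ``overrides`` rows
    (spice_id, disease_id, polarity, action) with action "drop" or
    "flip" implement the manual negative-cleaning hook at table level.
    """
    table = AssociationTable()
    for inst, label in classified:
        if label in (POSITIVE, NEGATIVE):
            table.add(inst.spice_id, inst.disease_id, label, inst.instance_id)
    for spice, disease, pol, action in overrides or []:
        key = (spice, disease, pol)
        if key not in table.rows:
            logger.warning("override for unknown association row %s ignored", key)
            continue
        evidence = table.rows.pop(key)
        if action == "flip":
            flipped = POSITIVE if pol == NEGATIVE else NEGATIVE
            table.rows.setdefault((spice, disease, flipped), []).extend(evidence)
        elif action != "drop":
            raise ValueError(f"unknown override action {action!r}")
    return table


def _presence(
    table: AssociationTable,
    ontology: DiseaseOntology,
    spice_id: str,
    polarity: str,
) -> tuple[set[str], set[str], set[str]]:
    """Union of category/subcategory/level-3 presence over associated diseases."""
    cats: set[str] = set()
    subcats: set[str] = set()
    level3: set[str] = set()
    for disease_id in table.diseases_for(spice_id, polarity):
        c, s, l3 = rollup(disease_id, ontology)
        cats |= c
        subcats |= s
        level3 |= l3
    return cats, subcats, level3


def spectrum_score(
    table: AssociationTable,
    ontology: DiseaseOntology,
    spice_id: str,
    polarity: str,
) -> float:
    """Omega = Dhat * sum_i dhat_i / d_i for one spice and polarity.

    Binary presence at the sub-category level; categories with zero
    sub-categories in the ontology contribute nothing and are excluded
    from Dhat (degenerate-ontology rule, logged).
    """
    _, subcats, _ = _presence(table, ontology, spice_id, polarity)
    covered: dict[str, int] = {}
    for sc in subcats:
        covered[sc.split(".")[0]] = covered.get(sc.split(".")[0], 0) + 1
    total = 0.0
    d_hat = 0
    for category, dhat_i in covered.items():
        d_i = ontology.subcategory_count(category)
        if d_i == 0:
            logger.warning("category %s has zero sub-categories; excluded", category)
            continue
        d_hat += 1
        total += dhat_i / d_i
    return d_hat * total


def relative_benevolence(omega_pos: float, omega_neg: float) -> float:
    """delta-Omega = Omega+ - Omega- (residual therapeutic benefit)."""
    return omega_pos - omega_neg


def category_spectrum(
    table: AssociationTable,
    ontology: DiseaseOntology,
    spice_id: str,
    category: str,
    polarity: str,
) -> float:
    """Omega_i = dhat_i * sum_{k in i} alphahat_k / alpha_k.

    ``alphahat_k`` counts distinct associated level-3 diseases within
    sub-category k; sub-categories with zero level-3 diseases in the
    ontology contribute nothing and are excluded from dhat_i (logged).
    A level-2-only association still counts toward sub-category presence
    but adds nothing to the level-3 sum.
    """
    if category not in ontology.categories():
        raise KeyError(f"unknown category {category!r}")
    _, subcats, level3 = _presence(table, ontology, spice_id, polarity)
    in_cat = {sc for sc in subcats if sc.split(".")[0] == category}
    total = 0.0
    d_hat = 0
    for sc in in_cat:
        alpha_k = ontology.disease_count(sc)
        if alpha_k == 0:
            logger.warning("sub-category %s has zero diseases; excluded", sc)
            continue
        d_hat += 1
        alphahat_k = sum(
            1 for l3 in level3 if truncate_tree_number(l3, 2) == sc
        )
        total += alphahat_k / alpha_k
    return d_hat * total


@dataclass
class SpectrumReport:
    """Per-spice spectrum scores and per-(spice, category) tradeoffs."""

    omega_pos: dict[str, float]
    omega_neg: dict[str, float]
    delta_omega: dict[str, float]
    category_pos: dict[tuple[str, str], float]
    category_neg: dict[tuple[str, str], float]
    category_delta: dict[tuple[str, str], float]

    @classmethod
    def compute(
        cls, table: AssociationTable, ontology: DiseaseOntology
    ) -> "SpectrumReport":
        spices = sorted(table.spices())
        categories = sorted(ontology.categories())
        omega_pos = {
            s: spectrum_score(table, ontology, s, POSITIVE) for s in spices
        }
        omega_neg = {
            s: spectrum_score(table, ontology, s, NEGATIVE) for s in spices
        }
        cat_pos = {
            (s, c): category_spectrum(table, ontology, s, c, POSITIVE)
            for s in spices
            for c in categories
        }
        cat_neg = {
            (s, c): category_spectrum(table, ontology, s, c, NEGATIVE)
            for s in spices
            for c in categories
        }
        return cls(
            omega_pos=omega_pos,
            omega_neg=omega_neg,
            delta_omega={
                s: relative_benevolence(omega_pos[s], omega_neg[s]) for s in spices
            },
            category_pos=cat_pos,
            category_neg=cat_neg,
            category_delta={
                k: cat_pos[k] - cat_neg[k] for k in cat_pos
            },
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("spice_id\tomega_pos\tomega_neg\tdelta_omega\n")
            for s in sorted(self.omega_pos):
                fh.write(
                    f"{s}\t{self.omega_pos[s]:.6g}\t{self.omega_neg[s]:.6g}\t"
                    f"{self.delta_omega[s]:.6g}\n"
                )


def recommend(
    report: SpectrumReport, category: str
) -> list[tuple[str, float, bool]]:
    """Rank spices for one disease category by tradeoff score.

    Returns (spice_id, tradeoff, flagged) tuples sorted by tradeoff
    descending, ties broken by the benevolence category score then
    lexicographic spice id; spices with tradeoff <= 0 are flagged.
    """
    entries = [
        (spice, self_delta)
        for (spice, cat), self_delta in report.category_delta.items()
        if cat == category
    ]
    if not entries:
        raise KeyError(f"unknown category {category!r}")
    entries.sort(
        key=lambda e: (-e[1], -report.category_pos[(e[0], category)], e[0])
    )
    return [(spice, delta, delta <= 0) for spice, delta in entries]
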