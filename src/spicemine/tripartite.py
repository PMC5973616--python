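"""Explain positive spice-disease associations through phytochemicals.

A positive association (s, d) at level 3 of the disease hierarchy is
*explained* when the spice contains a bioactive compound that carries a
curated therapeutic link to the same disease identifier.  The module
filters compound tables down to bioactive compounds and therapeutic
links, performs the tripartite join, and reports the coverage fraction;
unexplained associations are emitted as mechanistic hypotheses together
with the spice's candidate compounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from spicemine.ontology import DiseaseOntology
from spicemine.relation import POSITIVE
from spicemine.scoring import AssociationTable, rollup

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "CompoundDiseaseLink",
    "ExplanationReport",
    "filter_bioactive",
    "therapeutic_links",
    "explain",
    "read_spice_compound_tsv",
    "read_compound_disease_tsv",
]

ASSOCIATION_TYPES = ("therapeutic", "marker", "inferred")


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    name: str
    bioactive: bool


@dataclass(frozen=True)
class CompoundDiseaseLink:
    compound_id: str
    disease_id: str
    association_type: str

    def __post_init__(self) -> None:
        if self.association_type not in ASSOCIATION_TYPES:
            raise ValueError(
                f"association_type must be one of {ASSOCIATION_TYPES}, "
                f"got {self.association_type!r}"
            )


def filter_bioactive(compounds: Sequence[CompoundRecord]) -> list[CompoundRecord]:
    """Keep only bioactive compounds; order preserved."""
    return [c for c in compounds if c.bioactive]


def therapeutic_links(
    links: Iterable[CompoundDiseaseLink],
) -> list[CompoundDiseaseLink]:
    """Keep only curated therapeutic compound-disease links."""
    return [ln for ln in links if ln.association_type == "therapeutic"]


@dataclass
class ExplanationReport:
    """Per-association explanation status plus overall coverage."""

    explained: dict[tuple[str, str], list[str]]  # (spice, disease) -> compounds
    hypotheses: dict[tuple[str, str], list[str]]  # unexplained -> candidates
    coverage: float

    @property
    def n_explained(self) -> int:
        return len(self.explained)

    @property
    def n_total(self) -> int:
        return len(self.explained) + len(self.hypotheses)


def explain(
    positives: AssociationTable,
    spice_compound: Iterable[tuple[str, str]],
    compound_disease: Iterable[CompoundDiseaseLink],
    compounds: Sequence[CompoundRecord] | None = None,
    ontology: DiseaseOntology | None = None,
) -> ExplanationReport:
    """Tripartite join of positive associations with compound tables.

    ``spice_compound`` holds (spice_id, compound_id) pairs; tables are
    expected pre-filtered (bioactive compounds, therapeutic links), but
    when ``compounds`` is given the bioactive filter is applied here as
    a safety net.  When an ontology is supplied, rows whose disease id
    does not resolve are excluded (logged) and only level-3 rows enter
    the denominator.  Coverage counts distinct (spice, disease) pairs.
    """
    bioactive_ids = (
        {c.compound_id for c in filter_bioactive(compounds)}
        if compounds is not None
        else None
    )
    spice_to_compounds: dict[str, set[str]] = {}
    for spice_id, compound_id in spice_compound:
        if bioactive_ids is not None and compound_id not in bioactive_ids:
            continue
        spice_to_compounds.setdefault(spice_id, set()).add(compound_id)
    compound_to_diseases: dict[str, set[str]] = {}
    for link in therapeutic_links(compound_disease):
        compound_to_diseases.setdefault(link.compound_id, set()).add(link.disease_id)

    explained: dict[tuple[str, str], list[str]] = {}
    hypotheses: dict[tuple[str, str], list[str]] = {}
    seen: set[tuple[str, str]] = set()
    for spice_id, disease_id, polarity in positives.rows:
        if polarity != POSITIVE:
            continue
        pair = (spice_id, disease_id)
        if pair in seen:
            continue
        seen.add(pair)
        if ontology is not None:
            if disease_id not in ontology:
                logger.warning("disease id %r not in ontology; row excluded", disease_id)
                continue
            _, _, level3 = rollup(disease_id, ontology)
            if not level3:
                continue
        supporting = sorted(
            c
            for c in spice_to_compounds.get(spice_id, ())
            if disease_id in compound_to_diseases.get(c, ())
        )
        if supporting:
            explained[pair] = supporting
        else:
            hypotheses[pair] = sorted(spice_to_compounds.get(spice_id, ()))
    total = len(explained) + len(hypotheses)
    coverage = len(explained) / total if total else 0.0
    return ExplanationReport(
        explained=explained, hypotheses=hypotheses, coverage=coverage
    )


# ---------------------------------------------------------------------------
# TSV input formats
# ---------------------------------------------------------------------------


def read_spice_compound_tsv(
    path: str | Path,
) -> tuple[list[tuple[str, str]], list[CompoundRecord]]:
    """Read (spice_id, compound_id, bioactive) rows.

    Returns the pair list and the per-compound records (bioactive flag
    taken from the first row mentioning the compound).
    """
    pairs: list[tuple[str, str]] = []
    records: dict[str, CompoundRecord] = {}
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            spice_id, compound_id, bioactive = parts[0], parts[1], parts[2]
            pairs.append((spice_id, compound_id))
            if compound_id not in records:
                records[compound_id] = CompoundRecord(
                    compound_id=compound_id,
                    name=parts[3] if len(parts) > 3 else compound_id,
                    bioactive=bioactive.strip().lower() in ("1", "true", "yes"),
                )
    return pairs, list(records.values())


def read_compound_disease_tsv(path: str | Path) -> list[CompoundDiseaseLink]:
    """Read (compound_id, disease_id, association_type) rows; rows with
    an unknown type are skipped with a warning."""
    links: list[CompoundDiseaseLink] = []
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                links.append(CompoundDiseaseLink(parts[0], parts[1], parts[2]))
            except ValueError as exc:
                logger.warning("skipping link row: %s", exc)
    return links
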