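"""Spice/herb dictionary construction and MEDLINE-dialect XML ingest.

The lexicon maps common-name and scientific-name surfaces to species
identifiers.  Surfaces are lowercased at build time, plural forms are
added by rule, infraspecific qualifiers are stripped from scientific
names, and common names shared by several species are removed so the
surface -> species map is a function.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "LexiconEntry",
    "SpiceLexicon",
    "AbstractRecord",
    "standardize_variety",
    "expand_plurals",
    "pluralize",
    "dedupe_ambiguous",
    "parse_medline",
    "write_medline",
]

# trailing infraspecific qualifier: " var. pendulum", " subsp. orientalis", ...
_VARIETY_RE = re.compile(r"\s+(?:var|subsp|ssp|cv|f)\.\s+\S.*$")


def standardize_variety(name: str) -> str:
    """Strip a trailing infraspecific qualifier from a scientific name.

    ``Capsicum baccatum var. pendulum`` -> ``Capsicum baccatum``; names
    without a recognized qualifier are returned unchanged.  Idempotent.
    """
    if not name:
        raise ValueError("empty scientific name")
    return _VARIETY_RE.sub("", name)


def pluralize(name: str) -> str:
    """English plural of a single name by rule.

    +es after ss/x/z/ch/sh; -y -> -ies after a consonant; a name already
    ending in a lone ``s`` is treated as plural and returned unchanged;
    otherwise +s.  Multi-word names pluralize their last word.
    """
    lower = name.lower()
    if lower.endswith(("ss", "x", "z", "ch", "sh")):
        return name + "es"
    if lower.endswith("s"):
        return name
    if lower.endswith("y") and len(lower) >= 2 and lower[-2] not in "aeiou":
        return name[:-1] + "ies"
    return name + "s"


def expand_plurals(names: Iterable[str]) -> set[str]:
    """Add an English plural form for every name (superset of input)."""
    out = set(names)
    for name in list(out):
        if not name:
            raise ValueError("empty name in lexicon")
        out.add(pluralize(name))
    return out


@dataclass
class LexiconEntry:
    """One spice/herb species with its matchable surfaces."""

    species_id: str
    scientific_name: str
    common_names: set[str] = field(default_factory=set)
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.scientific_name:
            raise ValueError("scientific_name must be nonempty")
        self.common_names = {n.lower() for n in self.common_names}

    def surfaces(self) -> set[str]:
        """All matchable surfaces (common + scientific), lowercased."""
        return self.common_names | {self.scientific_name.lower()}


def dedupe_ambiguous(entries: list[LexiconEntry]) -> list[LexiconEntry]:
    """Remove common names that map to more than one species.

    A species whose common-name set empties out stays in the lexicon:
    its scientific name remains a matchable surface.
    """
    owners: dict[str, set[str]] = {}
    for entry in entries:
        for name in entry.common_names:
            owners.setdefault(name, set()).add(entry.species_id)
    shared = {name for name, ids in owners.items() if len(ids) > 1}
    if shared:
        logger.info("removing %d ambiguous common names", len(shared))
    return [
        LexiconEntry(
            species_id=e.species_id,
            scientific_name=e.scientific_name,
            common_names=e.common_names - shared,
            provenance=e.provenance,
        )
        for e in entries
    ]


@dataclass
class SpiceLexicon:
    """Deduplicated collection of species entries."""

    entries: list[LexiconEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.species_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate species_id in lexicon")

    def __len__(self) -> int:
        return len(self.entries)

    def surface_map(self) -> dict[str, str]:
        """Lowercased surface -> species_id (requires prior dedup)."""
        mapping: dict[str, str] = {}
        for entry in self.entries:
            for surface in entry.surfaces():
                prev = mapping.get(surface)
                if prev is not None and prev != entry.species_id:
                    raise ValueError(
                        f"surface {surface!r} maps to both {prev} and "
                        f"{entry.species_id}; run dedupe_ambiguous first"
                    )
                mapping[surface] = entry.species_id
        return mapping

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("species_id\tscientific_name\tcommon_name\tprovenance\n")
            for entry in self.entries:
                if not entry.common_names:
                    fh.write(
                        f"{entry.species_id}\t{entry.scientific_name}\t\t"
                        f"{entry.provenance}\n"
                    )
                for name in sorted(entry.common_names):
                    fh.write(
                        f"{entry.species_id}\t{entry.scientific_name}\t{name}\t"
                        f"{entry.provenance}\n"
                    )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpiceLexicon":
        by_id: dict[str, LexiconEntry] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["species_id", "scientific_name", "common_name"]:
                raise ValueError(f"unexpected lexicon header: {header}")
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                species_id, sci, common = parts[0], parts[1], parts[2]
                prov = parts[3] if len(parts) > 3 else "file"
                entry = by_id.get(species_id)
                if entry is None:
                    entry = LexiconEntry(species_id, sci, set(), prov)
                    by_id[species_id] = entry
                if common:
                    entry.common_names.add(common.lower())
        return cls(entries=list(by_id.values()))


# ---------------------------------------------------------------------------
# MEDLINE-dialect XML
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AbstractRecord:
    """One literature record; records without abstract text are dropped
    at parse time, so ``abstract_text`` is always nonempty here."""

    pmid: str
    date: str
    title: str
    abstract_text: str
    journal: str = ""
    authors: tuple[str, ...] = ()


def parse_medline(source: str | Path | IO[bytes]) -> list[AbstractRecord]:
    """Parse PubMed-dialect XML into abstract records.

    Citations without abstract text are silently dropped (count logged);
    citations without a PMID are skipped with a record-level warning.
    Multi-part AbstractText sections are concatenated with single spaces.
    Malformed XML raises :class:`lxml.etree.XMLSyntaxError`, which names
    the offending position.
    """
    tree = etree.parse(source)
    records: list[AbstractRecord] = []
    dropped_no_abstract = 0
    for article in tree.iter("PubmedArticle"):
        citation = article.find("MedlineCitation")
        if citation is None:
            continue
        pmid = citation.findtext("PMID", default="").strip()
        art = citation.find("Article")
        if not pmid:
            logger.warning("citation without PMID skipped")
            continue
        if art is None:
            dropped_no_abstract += 1
            continue
        abstract_el = art.find("Abstract")
        parts = (
            [t.text or "" for t in abstract_el.findall("AbstractText")]
            if abstract_el is not None
            else []
        )
        abstract_text = " ".join(p.strip() for p in parts if p.strip())
        if not abstract_text:
            dropped_no_abstract += 1
            continue
        title = art.findtext("ArticleTitle", default="").strip()
        journal = art.findtext("Journal/Title", default="").strip()
        year = citation.findtext("DateCompleted/Year", default="")
        if not year:
            year = art.findtext("Journal/JournalIssue/PubDate/Year", default="")
        authors = tuple(
            " ".join(
                x
                for x in (a.findtext("ForeName"), a.findtext("LastName"))
                if x
            )
            for a in art.findall("AuthorList/Author")
        )
        records.append(
            AbstractRecord(
                pmid=pmid,
                date=year.strip(),
                title=title,
                abstract_text=abstract_text,
                journal=journal,
                authors=authors,
            )
        )
    if dropped_no_abstract:
        logger.info("dropped %d citations without abstract text", dropped_no_abstract)
    return records


def write_medline(records: Iterable[AbstractRecord], path: str | Path) -> None:
    """Serialize records to the PubMed XML dialect read by parse_medline."""
    root = etree.Element("PubmedArticleSet")
    for rec in records:
        article = etree.SubElement(root, "PubmedArticle")
        citation = etree.SubElement(article, "MedlineCitation")
        etree.SubElement(citation, "PMID").text = rec.pmid
        if rec.date:
            date_el = etree.SubElement(citation, "DateCompleted")
            etree.SubElement(date_el, "Year").text = rec.date
        art = etree.SubElement(citation, "Article")
        journal_el = etree.SubElement(art, "Journal")
        etree.SubElement(journal_el, "Title").text = rec.journal
        etree.SubElement(art, "ArticleTitle").text = rec.title
        abstract_el = etree.SubElement(art, "Abstract")
        etree.SubElement(abstract_el, "AbstractText").text = rec.abstract_text
        if rec.authors:
            authors_el = etree.SubElement(art, "AuthorList")
            for author in rec.authors:
                author_el = etree.SubElement(authors_el, "Author")
                parts = author.rsplit(" ", 1)
                if len(parts) == 2:
                    etree.SubElement(author_el, "ForeName").text = parts[0]
                    etree.SubElement(author_el, "LastName").text = parts[1]
                else:
                    etree.SubElement(author_el, "LastName").text = parts[0]
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
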