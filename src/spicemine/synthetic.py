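"""Synthetic corpora with planted ground truth for the full pipeline.

The generator emulates every pipeline input: a three-level disease
ontology with dotted tree numbers, a spice lexicon with multi-word and
overlapping synonyms plus plural forms, abstracts whose sentences are
built from label-keyed template banks (distinct cue phrases for
positive / negative / neutral assertions, with controllable label
noise), and phytochemical tables in which an exact fraction of the
positive associations receives a supporting spice -> bioactive compound
-> therapeutic-link path.  Everything is deterministic in the seed:
identical configurations yield byte-identical outputs.

Default label priors follow the composition of a manually annotated
spice-disease corpus of 6712 pairs (2669 positive, 301 negative, 3742
neutral); the default bioactive fraction follows a curated phytochemical
table in which 570 of 866 compounds are bioactive, and the default
explainable fraction is 0.37.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from random import Random

from spicemine.lexicon import AbstractRecord, LexiconEntry, SpiceLexicon, pluralize
from spicemine.ontology import DiseaseOntology, tree_level
from spicemine.relation import CLASSES, NEGATIVE, NO_ASSOCIATION, POSITIVE
from spicemine.scoring import AssociationTable
from spicemine.tripartite import CompoundDiseaseLink, CompoundRecord

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "PlantedProfile",
    "generate_ontology",
    "generate_lexicon",
    "generate_corpus",
    "generate_phytochem_tables",
    "load_templates",
]

# disjoint syllable pools so disease, spice and compound pseudo-words can
# never collide across entity types
_DISEASE_SYLLABLES = (
    "var", "zen", "kol", "mir", "tas", "vor", "nel", "dru", "fay", "gos",
)
_SPICE_SYLLABLES = (
    "hul", "jin", "lom", "pex", "qui", "rov", "syl", "tib", "wun", "yar",
)
_DISEASE_SUFFIXES = ("itis", "osis", "emia", "oma", "pathy", "algia")
_DISEASE_HEADS = ("syndrome", "fever", "deficiency")
_GENUS_SUFFIXES = ("um", "a", "is", "ia")
_OVERLAP_MODIFIER = "wild"


def load_templates() -> dict[str, list[str]]:
    """Label-keyed sentence template banks shipped with the package."""
    text = resources.files("spicemine.data").joinpath("templates.json").read_text()
    raw = json.loads(text)
    return {
        POSITIVE: raw["positive"],
        NEGATIVE: raw["negative"],
        NO_ASSOCIATION: raw["neutral"],
    }


@dataclass(frozen=True)
class PlantedProfile:
    """Target coverage for one spice's planted spectrum profile."""

    spice_index: int
    category_fraction: float
    subcategory_fraction: float
    polarity: str

    def __post_init__(self) -> None:
        if not (0 <= self.category_fraction <= 1):
            raise ValueError("category_fraction must be in [0, 1]")
        if not (0 <= self.subcategory_fraction <= 1):
            raise ValueError("subcategory_fraction must be in [0, 1]")
        if self.polarity not in (POSITIVE, NEGATIVE):
            raise ValueError("profile polarity must be positive or negative")


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_categories: int = 27
    subcats_per_category: tuple[int, int] = (2, 6)
    diseases_per_subcat: tuple[int, int] = (2, 5)
    n_spices: int = 24
    synonyms_per_spice: tuple[int, int] = (1, 3)
    n_abstracts: int = 200
    sentences_per_abstract: tuple[int, int] = (3, 8)
    #: composition of the annotated pair corpus: 2669/301/3742 of 6712
    label_priors: tuple[float, float, float] = (
        2669 / 6712,
        301 / 6712,
        3742 / 6712,
    )
    label_noise_rate: float = 0.0
    planted_profiles: list[PlantedProfile] = field(default_factory=list)
    explainable_fraction: float = 0.37
    bioactive_fraction: float = 570 / 866

    def __post_init__(self) -> None:
        if abs(sum(self.label_priors) - 1.0) > 1e-9:
            raise ValueError("label_priors must sum to 1")
        for frac in (
            self.label_noise_rate,
            self.explainable_fraction,
            self.bioactive_fraction,
            *self.label_priors,
        ):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"fraction {frac} outside [0, 1]")
        for count in (self.n_categories, self.n_spices, self.n_abstracts):
            if count < 1:
                raise ValueError("all counts must be >= 1")
        for lo, hi in (
            self.subcats_per_category,
            self.diseases_per_subcat,
            self.synonyms_per_spice,
            self.sentences_per_abstract,
        ):
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid integer range ({lo}, {hi})")
        self.planted_profiles = [
            p if isinstance(p, PlantedProfile) else PlantedProfile(*p)
            for p in self.planted_profiles
        ]
        for profile in self.planted_profiles:
            if not (0 <= profile.spice_index < self.n_spices):
                raise ValueError("planted profile spice_index out of range")


@dataclass
class GroundTruth:
    """Planted truth: gold pair labels, spectrum coverage, explainable triples."""

    #: (doc_id, sentence_index, spice_id, disease_id) -> gold class
    labels: dict[tuple[str, int, str, str], str] = field(default_factory=dict)
    #: (spice_id, polarity) -> set of covered level-2 tree numbers
    profile_coverage: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    #: (spice_id, disease_id, compound_id) planted explanation paths
    explainable_triples: set[tuple[str, str, str]] = field(default_factory=set)


def _stage_rng(cfg: SyntheticConfig, stage: int) -> Random:
    return Random(cfg.seed * 1_000_003 + stage)


def _word(rng: Random, used: set[str], syllables: tuple[str, ...]) -> str:
    while True:
        word = "".join(rng.choice(syllables) for _ in range(rng.randint(2, 3)))
        if word not in used:
            used.add(word)
            return word


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------


def generate_ontology(cfg: SyntheticConfig) -> DiseaseOntology:
    """Three-level disease ontology with dotted tree numbers.

    Node ids are sequential; every node carries exactly one tree number
    (C01, C01.050, C01.050.100, ...); leaf names are unique strings
    usable as dictionary entries (suffixed pseudo-words, some with a
    two-word ``<head> syndrome`` form to exercise multi-token matching).
    """
    rng = _stage_rng(cfg, 1)
    used: set[str] = set()
    onto = DiseaseOntology()
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"M{counter:05d}"

    for i in range(1, cfg.n_categories + 1):
        cat_tn = f"C{i:02d}"
        onto.add(next_id(), f"{_word(rng, used, _DISEASE_SYLLABLES)} disorders", [cat_tn])
        n_sub = rng.randint(*cfg.subcats_per_category)
        for j in range(1, n_sub + 1):
            sub_tn = f"{cat_tn}.{j * 50:03d}"
            onto.add(next_id(), f"{_word(rng, used, _DISEASE_SYLLABLES)} conditions", [sub_tn])
            n_dis = rng.randint(*cfg.diseases_per_subcat)
            for k in range(1, n_dis + 1):
                leaf_tn = f"{sub_tn}.{k * 100:03d}"
                head = _word(rng, used, _DISEASE_SYLLABLES)
                if rng.random() < 0.3:
                    name = f"{head} {rng.choice(_DISEASE_HEADS)}"
                else:
                    name = head + rng.choice(_DISEASE_SUFFIXES)
                onto.add(next_id(), name, [leaf_tn])
    return onto


def leaf_nodes(ontology: DiseaseOntology) -> list:
    """Ontology nodes carrying a level-3 tree number, sorted by id."""
    return [
        node
        for node_id, node in sorted(ontology.nodes.items())
        if any(tree_level(tn) == 3 for tn in node.tree_numbers)
    ]


# ---------------------------------------------------------------------------
# lexicon
# ---------------------------------------------------------------------------


def generate_lexicon(cfg: SyntheticConfig) -> SpiceLexicon:
    """Spice lexicon with planted longest-match and plural cases.

    Every species has at least one common name plus the plural of its
    first name; with two or more species, the second species receives a
    multi-word synonym ("wild <name>") containing the first species'
    single-word synonym as a token, to exercise longest-match tagging.
    """
    rng = _stage_rng(cfg, 2)
    used: set[str] = set()
    entries: list[LexiconEntry] = []
    for i in range(cfg.n_spices):
        genus = (_word(rng, used, _SPICE_SYLLABLES) + rng.choice(_GENUS_SUFFIXES)).capitalize()
        species = _word(rng, used, _SPICE_SYLLABLES) + rng.choice(_GENUS_SUFFIXES)
        n_syn = rng.randint(*cfg.synonyms_per_spice)
        names = {_word(rng, used, _SPICE_SYLLABLES) for _ in range(n_syn)}
        first = sorted(names)[0]
        names.add(pluralize(first))
        entries.append(
            LexiconEntry(
                species_id=f"SPC{i:03d}",
                scientific_name=f"{genus} {species}",
                common_names=names,
                provenance="synthetic",
            )
        )
    if cfg.n_spices >= 2:
        overlap_base = sorted(entries[0].common_names)[0]
        entries[1].common_names.add(f"{_OVERLAP_MODIFIER} {overlap_base}")
    return SpiceLexicon(entries=entries)


# ---------------------------------------------------------------------------
# corpus
# ---------------------------------------------------------------------------


def _draw_class(rng: Random, priors: tuple[float, float, float]) -> str:
    u = rng.random()
    order = (POSITIVE, NEGATIVE, NO_ASSOCIATION)
    cum = 0.0
    for cls, p in zip(order, priors):
        cum += p
        if u < cum:
            return cls
    return NO_ASSOCIATION


def generate_corpus(
    cfg: SyntheticConfig,
    ontology: DiseaseOntology,
    lexicon: SpiceLexicon,
) -> tuple[list[AbstractRecord], GroundTruth]:
    """Generate abstracts with planted sentence-level pair labels.

    Each sentence embeds one spice surface and one disease leaf name in
    a template keyed to its gold class; with probability
    ``label_noise_rate`` the recorded gold label is flipped uniformly to
    a different class (the sentence text keeps its original template).
    Planted spectrum-profile sentences are appended as dedicated
    abstracts and are exempt from label noise so coverage is exact.
    """
    if len(ontology) == 0 or len(lexicon) == 0:
        raise ValueError("ontology and lexicon must be nonempty")
    rng = _stage_rng(cfg, 3)
    templates = load_templates()
    leaves = leaf_nodes(ontology)
    if not leaves:
        raise ValueError("ontology has no level-3 diseases")
    truth = GroundTruth()
    records: list[AbstractRecord] = []

    def make_sentence(cls: str, spice_entry: LexiconEntry, leaf) -> str:
        template = rng.choice(templates[cls])
        surface = rng.choice(sorted(spice_entry.surfaces()))
        return template.format(spice=surface, disease=leaf.name)

    for a in range(cfg.n_abstracts):
        pmid = str(100000 + a)
        sentences: list[str] = []
        n_sent = rng.randint(*cfg.sentences_per_abstract)
        for s in range(n_sent):
            cls = _draw_class(rng, cfg.label_priors)
            entry = rng.choice(lexicon.entries)
            leaf = rng.choice(leaves)
            sentences.append(make_sentence(cls, entry, leaf))
            recorded = cls
            if cfg.label_noise_rate > 0 and rng.random() < cfg.label_noise_rate:
                recorded = rng.choice([c for c in CLASSES if c != cls])
            truth.labels[(pmid, s, entry.species_id, leaf.node_id)] = recorded
        records.append(
            AbstractRecord(
                pmid=pmid,
                date=str(1990 + a % 35),
                title="Dietary factors and health outcomes in an observational cohort.",
                abstract_text=" ".join(sentences),
                journal="Journal of Synthetic Nutrition",
                authors=("Ada Example", "Ben Sample"),
            )
        )

    # planted spectrum profiles: dedicated noise-free abstracts
    for p_idx, profile in enumerate(cfg.planted_profiles):
        entry = lexicon.entries[profile.spice_index]
        categories = sorted(ontology.categories())
        n_cat = max(1, round(profile.category_fraction * len(categories)))
        chosen_cats = categories[:n_cat]
        covered: set[str] = set()
        sentences = []
        sent_meta = []
        for cat in chosen_cats:
            subcats = sorted(ontology.subcategories_of(cat))
            n_sub = max(1, round(profile.subcategory_fraction * len(subcats)))
            for sc in subcats[:n_sub]:
                leaf = next(
                    node
                    for node in leaves
                    if any(tn.startswith(sc + ".") for tn in node.tree_numbers)
                )
                label = (
                    POSITIVE if profile.polarity == POSITIVE else NEGATIVE
                )
                sentences.append(make_sentence(label, entry, leaf))
                sent_meta.append((leaf, label))
                covered.add(sc)
        pmid = str(900000 + p_idx)
        for s, (leaf, label) in enumerate(sent_meta):
            truth.labels[(pmid, s, entry.species_id, leaf.node_id)] = label
        key = (entry.species_id, profile.polarity)
        truth.profile_coverage[key] = truth.profile_coverage.get(key, set()) | covered
        records.append(
            AbstractRecord(
                pmid=pmid,
                date="2000",
                title="Spectrum of reported effects for a single culinary species.",
                abstract_text=" ".join(sentences),
                journal="Journal of Synthetic Nutrition",
                authors=("Ada Example",),
            )
        )
    return records, truth


# ---------------------------------------------------------------------------
# phytochemical tables
# ---------------------------------------------------------------------------


def generate_phytochem_tables(
    cfg: SyntheticConfig,
    lexicon: SpiceLexicon,
    ontology: DiseaseOntology,
    positives: AssociationTable,
    ground_truth: GroundTruth | None = None,
) -> tuple[
    tuple[list[tuple[str, str]], list[CompoundRecord]],
    list[CompoundDiseaseLink],
    GroundTruth,
]:
    """Plant supporting compound paths for an exact positive fraction.

    Exactly ``round(explainable_fraction * n_pairs)`` distinct positive
    (spice, disease) pairs receive a spice -> bioactive compound ->
    therapeutic link path; every remaining pair receives a decoy
    compound whose path is broken in exactly one place (non-bioactive
    compound, or a marker/inferred link), so filters are exercised but
    no unplanned explanation exists.
    """
    pairs = sorted(
        {(s, d) for (s, d, pol) in positives.rows if pol == POSITIVE}
    )
    if not pairs:
        raise ValueError("positives table is empty")
    rng = _stage_rng(cfg, 4)
    n_explained = round(cfg.explainable_fraction * len(pairs))
    chosen = set(rng.sample(range(len(pairs)), n_explained))
    truth = ground_truth if ground_truth is not None else GroundTruth()
    used: set[str] = set()
    spice_compound: list[tuple[str, str]] = []
    compounds: list[CompoundRecord] = []
    links: list[CompoundDiseaseLink] = []
    for i, (spice_id, disease_id) in enumerate(pairs):
        compound_id = f"CMP{i:04d}"
        name = _word(rng, used, _SPICE_SYLLABLES) + "in"
        if i in chosen:
            compounds.append(CompoundRecord(compound_id, name, bioactive=True))
            spice_compound.append((spice_id, compound_id))
            links.append(
                CompoundDiseaseLink(compound_id, disease_id, "therapeutic")
            )
            truth.explainable_triples.add((spice_id, disease_id, compound_id))
        else:
            bioactive = rng.random() < cfg.bioactive_fraction
            if bioactive:
                link_type = rng.choice(["marker", "inferred"])
            else:
                link_type = rng.choice(["therapeutic", "marker", "inferred"])
            compounds.append(CompoundRecord(compound_id, name, bioactive=bioactive))
            spice_compound.append((spice_id, compound_id))
            links.append(CompoundDiseaseLink(compound_id, disease_id, link_type))
    return (spice_compound, compounds), links, truth
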