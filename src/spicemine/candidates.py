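"""Sentence segmentation, token normalization and candidate construction.

A candidate instance is one (spice, disease) pair in one sentence: the
sentence is duplicated per pair, the focal spice replaced by a reserved
SPICE token, the focal disease by DISEASE, every other entity mention by
MASKED.  Numbers become a reserved NUM token; of the punctuation only
``! , . : ;`` survive, each as its own token.  Per-token part-of-speech
and chunk tags come from a pluggable linguistic tagger (a rule-based
default is bundled), and signed token distances to the focal pair are
attached as position features.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence

__all__ = [
    "RESERVED",
    "CandidateInstance",
    "LinguisticTagger",
    "RuleTagger",
    "segment_sentences",
    "normalize_tokens",
    "select_candidates",
    "enumerate_pairs",
    "attach_features",
]

#: Reserved placeholder tokens; chosen to be disjoint from the lowercase
#: vocabulary the normalizer produces.
RESERVED = {
    "num": "NUM",
    "spice": "SPICE",
    "disease": "DISEASE",
    "masked": "MASKED",
}

_RESERVED_SET = frozenset(RESERVED.values())

# abbreviations that do not end a sentence
_ABBREVIATIONS = (
    "i.e",
    "e.g",
    "etc",
    "vs",
    "cf",
    "al",
    "fig",
    "dr",
    "no",
    "approx",
    "resp",
)
_SENT_BOUNDARY = re.compile(r"(?<=[.!?])\s+")

_KEEP_PUNCT = "!,.:;"
_STRIP_RE = re.compile(rf"[^\w\s{re.escape(_KEEP_PUNCT)}]|_")
_TOKEN_RE = re.compile(rf"\d+\.\d+|[^\W_]+|[{re.escape(_KEEP_PUNCT)}]")
_NUMERIC_RE = re.compile(r"^\d+(\.\d+)?$")


def segment_sentences(text: str) -> list[str]:
    """Split abstract text into sentences.

    Rule-based: a sentence ends at ``. ! ?`` followed by whitespace,
    except after a known abbreviation.  The concatenation of the output
    equals the input modulo inter-sentence whitespace, and no sentence
    is empty.
    """
    if not text.strip():
        raise ValueError("empty abstract text")
    pieces = _SENT_BOUNDARY.split(text.strip())
    sentences: list[str] = []
    for piece in pieces:
        if not piece:
            continue
        if sentences and _ends_with_abbreviation(sentences[-1]):
            sentences[-1] = sentences[-1] + " " + piece
        else:
            sentences.append(piece)
    return sentences


def _ends_with_abbreviation(sentence: str) -> bool:
    stripped = sentence.rstrip()
    if not stripped.endswith("."):
        return False
    word = stripped[:-1].rsplit(None, 1)[-1].lower() if stripped[:-1].strip() else ""
    word = word.lstrip("(")
    return word in _ABBREVIATIONS


def normalize_tokens(sentence: str) -> list[str]:
    """Normalize and tokenize one sentence.

    Characters outside letters/digits/whitespace/``!,.:;`` are removed,
    retained punctuation becomes its own token, numeric tokens (integers
    and decimals) are replaced by NUM, everything else is lowercased.
    Reserved placeholder tokens pass through unchanged, which makes the
    operation idempotent.
    """
    cleaned = _STRIP_RE.sub("", sentence)
    tokens: list[str] = []
    for raw in _TOKEN_RE.findall(cleaned):
        if raw in _RESERVED_SET:
            tokens.append(raw)
        elif _NUMERIC_RE.match(raw):
            tokens.append(RESERVED["num"])
        else:
            tokens.append(raw.lower())
    return tokens


@dataclass
class CandidateInstance:
    """One masked (spice, disease) pair instance ready for classification."""

    instance_id: str
    doc_id: str
    sentence_index: int
    spice_id: str
    disease_id: str
    tokens: list[str]
    pos_tags: list[str] = field(default_factory=list)
    chunk_tags: list[str] = field(default_factory=list)
    dist_spice: list[int] = field(default_factory=list)
    dist_disease: list[int] = field(default_factory=list)
    label: str | None = None

    def __post_init__(self) -> None:
        if self.tokens.count(RESERVED["spice"]) != 1:
            raise ValueError("instance must contain exactly one SPICE token")
        if self.tokens.count(RESERVED["disease"]) != 1:
            raise ValueError("instance must contain exactly one DISEASE token")


def select_candidates(mentions: Sequence) -> bool:
    """True iff the sentence has >=1 spice and >=1 disease mention."""
    types = {m.entity_type for m in mentions}
    return "spice" in types and "disease" in types


def enumerate_pairs(
    doc_id: str,
    sentence_index: int,
    tokens: Sequence[str],
    mentions: Sequence,
) -> list[CandidateInstance]:
    """Duplicate the sentence once per (spice, disease) mention pair.

    Each mention span collapses to a single placeholder token: SPICE and
    DISEASE for the focal pair, MASKED for every non-focal entity.  All
    instances from one sentence therefore share the same token count and
    the same positions for non-entity tokens.
    """
    spices = sorted(
        (m for m in mentions if m.entity_type == "spice"),
        key=lambda m: m.token_start,
    )
    diseases = sorted(
        (m for m in mentions if m.entity_type == "disease"),
        key=lambda m: m.token_start,
    )
    if not spices or not diseases:
        return []
    all_mentions = sorted(mentions, key=lambda m: m.token_start)
    instances: list[CandidateInstance] = []
    for si, spice in enumerate(spices):
        for di, disease in enumerate(diseases):
            masked: list[str] = []
            cursor = 0
            for m in all_mentions:
                masked.extend(tokens[cursor : m.token_start])
                if m is spice:
                    masked.append(RESERVED["spice"])
                elif m is disease:
                    masked.append(RESERVED["disease"])
                else:
                    masked.append(RESERVED["masked"])
                cursor = m.token_end
            masked.extend(tokens[cursor:])
            instances.append(
                CandidateInstance(
                    instance_id=f"{doc_id}:{sentence_index}:{si}:{di}",
                    doc_id=doc_id,
                    sentence_index=sentence_index,
                    spice_id=spice.normalized_id,
                    disease_id=disease.normalized_id,
                    tokens=masked,
                )
            )
    return instances


class LinguisticTagger(Protocol):
    """Contract for PoS/chunk taggers: one tag per token, both layers."""

    def tag(self, tokens: Sequence[str]) -> tuple[list[str], list[str]]: ...


class RuleTagger:
    """Bundled rule-based PoS and chunk tagger.

    Suffix heuristics plus small closed-class lists; chunking marks noun
    phrases (determiners/adjectives/nouns) and verb groups.  Crude by
    design — the contract, not the linguistics, is what downstream
    models depend on.
    """

    _DETERMINERS = {"the", "a", "an", "this", "that", "these", "those"}
    _PREPOSITIONS = {"of", "in", "on", "with", "by", "for", "to", "from", "against"}
    _CONJUNCTIONS = {"and", "or", "but"}
    _PRONOUNS = {"we", "it", "they", "its", "their", "our"}
    _VERB_SUFFIXES = ("ed", "ing", "ates", "ate", "ized", "izes")

    def _pos(self, token: str) -> str:
        if token in _RESERVED_SET:
            return "CD" if token == RESERVED["num"] else "NN"
        if token in _KEEP_PUNCT:
            return token
        if token in self._DETERMINERS:
            return "DT"
        if token in self._PREPOSITIONS:
            return "IN"
        if token in self._CONJUNCTIONS:
            return "CC"
        if token in self._PRONOUNS:
            return "PRP"
        if token.endswith("ly"):
            return "RB"
        if token.endswith(self._VERB_SUFFIXES):
            return "VBD" if token.endswith("ed") else "VBG"
        if token.endswith(("ous", "ive", "al", "ic")):
            return "JJ"
        return "NN"

    def tag(self, tokens: Sequence[str]) -> tuple[list[str], list[str]]:
        pos = [self._pos(t) for t in tokens]
        chunks: list[str] = []
        prev = "O"
        for p in pos:
            if p in ("NN", "JJ", "DT", "CD", "PRP"):
                chunks.append("I-NP" if prev == "NP" else "B-NP")
                prev = "NP"
            elif p.startswith("VB") or p == "RB":
                chunks.append("I-VP" if prev == "VP" else "B-VP")
                prev = "VP"
            else:
                chunks.append("O")
                prev = "O"
        return pos, chunks


def attach_features(
    instance: CandidateInstance, tagger: LinguisticTagger | None = None
) -> CandidateInstance:
    """Fill PoS/chunk tags and signed distances to the focal pair.

    ``dist_spice[i] = i - index(SPICE)`` and likewise for DISEASE, so
    the sign distinguishes left from right context.
    """
    tagger = tagger if tagger is not None else RuleTagger()
    pos, chunks = tagger.tag(instance.tokens)
    n = len(instance.tokens)
    if len(pos) != n or len(chunks) != n:
        raise ValueError(
            f"tagger contract violation: {len(pos)}/{len(chunks)} tags "
            f"for {n} tokens"
        )
    spice_idx = instance.tokens.index(RESERVED["spice"])
    disease_idx = instance.tokens.index(RESERVED["disease"])
    return replace(
        instance,
        pos_tags=list(pos),
        chunk_tags=list(chunks),
        dist_spice=[i - spice_idx for i in range(n)],
        dist_disease=[i - disease_idx for i in range(n)],
    )
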