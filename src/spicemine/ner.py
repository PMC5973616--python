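"""Dictionary-based named entity recognition over token sequences.

Spice and disease surfaces are matched at the token level with greedy
leftmost-longest semantics: at each position the longest dictionary
surface starting there is emitted and scanning resumes after its last
token, so mentions of one entity type never overlap.  The matcher is a
trie over token sequences (an Aho-Corasick-style automaton restricted to
the longest-match policy); construction is linear in the total number of
surface tokens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from spicemine.candidates import normalize_tokens
from spicemine.lexicon import SpiceLexicon
from spicemine.ontology import DiseaseOntology

logger = logging.getLogger(__name__)

__all__ = [
    "Mention",
    "TokenMatcher",
    "build_matcher",
    "tag_spices",
    "tag_diseases",
    "adapter_to_mentions",
]


@dataclass(frozen=True)
class Mention:
    """A located, normalized entity mention.

    Token offsets are 0-based, ``token_end`` exclusive, into the
    normalized token list of the sentence.
    """

    doc_id: str
    sentence_index: int
    token_start: int
    token_end: int
    surface: str
    entity_type: str  # "spice" | "disease"
    normalized_id: str

    def __post_init__(self) -> None:
        if not self.token_start < self.token_end:
            raise ValueError("token_start must be < token_end")
        if self.entity_type not in ("spice", "disease"):
            raise ValueError(f"unknown entity type {self.entity_type!r}")


class TokenMatcher:
    """Trie over token sequences supporting greedy longest-match scans."""

    def __init__(self) -> None:
        # each trie node: token -> child node; payload stored under None
        self._root: dict = {}
        self._n_surfaces = 0

    def add(self, surface_tokens: Sequence[str], payload: str) -> None:
        if not surface_tokens:
            return
        node = self._root
        for token in surface_tokens:
            node = node.setdefault(token, {})
        node[None] = payload
        self._n_surfaces += 1

    def __len__(self) -> int:
        return self._n_surfaces

    def longest_match_at(
        self, tokens: Sequence[str], start: int
    ) -> tuple[int, str] | None:
        """Longest surface starting at ``start``; (end, payload) or None."""
        node = self._root
        best: tuple[int, str] | None = None
        i = start
        n = len(tokens)
        while i < n:
            node = node.get(tokens[i])
            if node is None:
                break
            i += 1
            if None in node:
                best = (i, node[None])
        return best

    def scan(self, tokens: Sequence[str]) -> list[tuple[int, int, str]]:
        """Greedy leftmost-longest non-overlapping matches.

        Returns (token_start, token_end, payload) triples; after a match
        is emitted scanning resumes after its last token.
        """
        out: list[tuple[int, int, str]] = []
        i = 0
        n = len(tokens)
        while i < n:
            hit = self.longest_match_at(tokens, i)
            if hit is None:
                i += 1
            else:
                end, payload = hit
                out.append((i, end, payload))
                i = end
        return out


def build_matcher(lexicon: SpiceLexicon) -> TokenMatcher:
    """Build the token automaton from a deduplicated spice lexicon.

    Surfaces are normalized with the same tokenizer applied to sentences
    so multi-word surfaces align with sentence tokens.
    """
    if len(lexicon) == 0:
        raise ValueError("cannot build a matcher from an empty lexicon")
    matcher = TokenMatcher()
    # sorted for insensitivity to lexicon row order
    for surface, species_id in sorted(lexicon.surface_map().items()):
        matcher.add(normalize_tokens(surface), species_id)
    return matcher


def _matches_to_mentions(
    matches: Iterable[tuple[int, int, str]],
    tokens: Sequence[str],
    doc_id: str,
    sentence_index: int,
    entity_type: str,
) -> list[Mention]:
    return [
        Mention(
            doc_id=doc_id,
            sentence_index=sentence_index,
            token_start=start,
            token_end=end,
            surface=" ".join(tokens[start:end]),
            entity_type=entity_type,
            normalized_id=payload,
        )
        for start, end, payload in matches
    ]


def tag_spices(
    tokens: Sequence[str],
    matcher: TokenMatcher,
    doc_id: str = "",
    sentence_index: int = 0,
) -> list[Mention]:
    """Locate spice mentions in a normalized token list."""
    return _matches_to_mentions(
        matcher.scan(tokens), tokens, doc_id, sentence_index, "spice"
    )


def build_disease_matcher(ontology: DiseaseOntology) -> TokenMatcher:
    """Token automaton over ontology term names (the bundled fallback
    for an external disease tagger)."""
    if len(ontology) == 0:
        raise ValueError("cannot build a matcher from an empty ontology")
    matcher = TokenMatcher()
    for name, node_id in sorted(ontology.name_to_id().items()):
        matcher.add(normalize_tokens(name), node_id)
    return matcher


def tag_diseases(
    tokens: Sequence[str],
    disease_lexicon: DiseaseOntology | TokenMatcher,
    doc_id: str = "",
    sentence_index: int = 0,
) -> list[Mention]:
    """Locate disease mentions with the bundled dictionary fallback.

    Accepts either the ontology itself (a matcher is built on the fly)
    or a prebuilt matcher from :func:`build_disease_matcher`.  Output of
    an external tagger can instead be converted with
    :func:`adapter_to_mentions`.
    """
    matcher = (
        disease_lexicon
        if isinstance(disease_lexicon, TokenMatcher)
        else build_disease_matcher(disease_lexicon)
    )
    return _matches_to_mentions(
        matcher.scan(tokens), tokens, doc_id, sentence_index, "disease"
    )


def adapter_to_mentions(
    records: Iterable[tuple[str, int, int, str]],
    sentence_char_spans: dict[str, list[tuple[int, int]]],
    sentence_tokens: dict[tuple[str, int], list[str]],
    sentence_texts: dict[tuple[str, int], str],
    ontology: DiseaseOntology,
) -> list[Mention]:
    """Convert external-tagger records to token-offset mentions.

    Each record is (doc_id, char_start, char_end, normalized_id) with
    character offsets into the abstract text.  Records whose id does not
    resolve in the ontology are dropped with a warning; records whose
    span does not align to token boundaries of the containing sentence
    are likewise dropped.
    """
    mentions: list[Mention] = []
    for doc_id, char_start, char_end, node_id in records:
        if node_id not in ontology:
            logger.warning("adapter record with unresolvable id %r dropped", node_id)
            continue
        spans = sentence_char_spans.get(doc_id, [])
        sent_idx = next(
            (i for i, (s, e) in enumerate(spans) if s <= char_start and char_end <= e),
            None,
        )
        if sent_idx is None:
            logger.warning(
                "adapter record %s[%d:%d] crosses sentence boundaries; dropped",
                doc_id,
                char_start,
                char_end,
            )
            continue
        text = sentence_texts[(doc_id, sent_idx)]
        sent_off = spans[sent_idx][0]
        surface_tokens = normalize_tokens(
            text[char_start - sent_off : char_end - sent_off]
        )
        tokens = sentence_tokens[(doc_id, sent_idx)]
        # align the surface tokens to a token span of the sentence
        placed = None
        for i in range(len(tokens) - len(surface_tokens) + 1):
            if tokens[i : i + len(surface_tokens)] == surface_tokens:
                placed = (i, i + len(surface_tokens))
                break
        if placed is None or not surface_tokens:
            logger.warning(
                "adapter record %s[%d:%d] does not align to token boundaries",
                doc_id,
                char_start,
                char_end,
            )
            continue
        mentions.append(
            Mention(
                doc_id=doc_id,
                sentence_index=sent_idx,
                token_start=placed[0],
                token_end=placed[1],
                surface=" ".join(surface_tokens),
                entity_type="disease",
                normalized_id=node_id,
            )
        )
    return mentions


def assert_non_overlapping(mentions: Sequence[Mention]) -> None:
    """Raise if two same-type mentions in one sentence overlap."""
    by_key: dict[tuple[str, int, str], list[Mention]] = {}
    for m in mentions:
        by_key.setdefault((m.doc_id, m.sentence_index, m.entity_type), []).append(m)
    for group in by_key.values():
        group.sort(key=lambda m: m.token_start)
        for a, b in zip(group, group[1:]):
            if b.token_start < a.token_end:
                raise AssertionError(f"overlapping mentions: {a} / {b}")
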