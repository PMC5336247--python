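"""Linguistic annotation pipeline with pluggable stage adapters.

Five annotation stages run over each abstract: tokenization / sentence
splitting, POS tagging, lemmatization, named-entity recognition and
dependency parsing.  Each stage is an *adapter contract*: a named callable in
a registry, selected by configuration.  The package ships deterministic
rule-based baselines for all five stages so that the full feature pipeline
runs with no model downloads; heavier external tools can be plugged in by
registering an adapter with the same signature.

Baseline rules
--------------
* **Tokenizer** — regex word tokenizer: decimal numbers and hyphenated /
  apostrophe-internal words are kept as single tokens; all other punctuation
  becomes its own token.
* **Sentence splitter** — boundaries at ``. ! ?`` followed by whitespace,
  unless the preceding word is a known abbreviation (``e.g.``, ``et al.``,
  ``Fig.`` …) or a single letter.
* **POS tagger** — closed-class lexicon, then verb-lexicon inflection
  matching (``affects`` → VBZ), then suffix heuristics (``-ing`` VBG,
  ``-ed`` VBN, ``-ly`` RB, plural ``-s`` NNS …), default NN.
* **Lemmatizer** — irregular-form exception lexicon, then POS-aware suffix
  stripping with e-restoration against the known verb-lemma set.
* **NER** — longest-match, non-overlapping gazetteer matching over the five
  biomedical entity types (DNA, RNA, protein, cell_line, cell_type).
* **Parser** — finite-state subject–verb–object matcher: for every
  noun-group / verb / noun-group pattern it emits ``subject`` and ``object``
  arcs headed by the verb, plus ``modifier`` arcs inside noun groups.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from typing import Callable, Iterable, Sequence

from .corpus_io import DocumentRecord

__all__ = [
    "Token",
    "DependencyArc",
    "EntityMention",
    "AnnotatedDocument",
    "clean_text",
    "segment",
    "pos_tag",
    "lemmatize",
    "recognize_entities",
    "parse_dependencies",
    "TextAnnotator",
    "register_adapter",
    "get_adapter",
    "annotate_corpus",
]

ENTITY_TYPES = ("DNA", "RNA", "protein", "cell_line", "cell_type")


@dataclass
class Token:
    surface: str
    sentence_index: int
    position: int
    pos: str = ""
    lemma: str = ""


@dataclass(frozen=True)
class DependencyArc:
    """One grammatical-relation arc; ``head`` is the governing token."""

    relation: str
    head: Token
    dependent: Token


@dataclass(frozen=True)
class EntityMention:
    entity_type: str
    span_text: str

    def __post_init__(self) -> None:
        if self.entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type: {self.entity_type!r}")


@dataclass
class AnnotatedDocument:
    record: DocumentRecord
    sentences: list[list[Token]] = field(default_factory=list)
    arcs: list[DependencyArc] = field(default_factory=list)
    entities: list[EntityMention] = field(default_factory=list)


# ----------------------------------------------------------------------
# resource loading


def _resource_lines(name: str) -> Iterable[str]:
    text = (
        _importlib_resources.files("expotext.resources")
        .joinpath(name)
        .read_text(encoding="utf-8")
    )
    for line in text.splitlines():
        line = line.rstrip("\n")
        if line and not line.startswith("#"):
            yield line


def _load_tsv_map(name: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in _resource_lines(name):
        key, _, value = line.partition("\t")
        out[key] = value
    return out


def load_pos_lexicon() -> dict[str, str]:
    return _load_tsv_map("pos_lexicon.tsv")


def load_lemma_exceptions() -> dict[str, str]:
    return _load_tsv_map("lemma_exceptions.tsv")


def load_gazetteer(path: str | None = None) -> list[tuple[str, str]]:
    """(entity_type, phrase) pairs; *path* overrides the built-in gazetteer."""
    if path is None:
        lines: Iterable[str] = _resource_lines("gazetteer.tsv")
    else:
        with open(path, "r", encoding="utf-8") as fh:
            lines = [
                ln.rstrip("\n")
                for ln in fh
                if ln.strip() and not ln.startswith("#")
            ]
    out = []
    for line in lines:
        etype, _, phrase = line.partition("\t")
        out.append((etype, phrase))
    return out


def load_verb_lemmas() -> frozenset[str]:
    """Verb lemmas known to the baseline tagger/lemmatizer."""
    from .features import load_verb_cluster_lexicon

    lex = load_verb_cluster_lexicon()
    extra = {
        w
        for w, tag in load_pos_lexicon().items()
        if tag.startswith("VB")
    }
    return frozenset(set(lex.entries) | extra)


# ----------------------------------------------------------------------
# stage 1: cleaning


_WS_RE = re.compile(r"\s+")


def clean_text(raw: str) -> str:
    """Normalize unicode, strip control characters, collapse whitespace.

    Total and idempotent; this is the only mutation applied to raw abstract
    text before tokenization.
    """
    text = unicodedata.normalize("NFKC", raw)
    chars = []
    for ch in text:
        cat = unicodedata.category(ch)
        if cat in ("Cc", "Cf"):
            chars.append(" ")
        else:
            chars.append(ch)
    return _WS_RE.sub(" ", "".join(chars)).strip()


# ----------------------------------------------------------------------
# stage 2: tokenization + sentence splitting

_TOKEN_RE = re.compile(
    r"\d+\.\d+(?:[eE][+-]?\d+)?"  # decimal numbers
    r"|[A-Za-z0-9]+(?:['-][A-Za-z0-9]+)*"  # words incl. hyphen/apostrophe
    r"|[^\sA-Za-z0-9]"  # any other char is its own token
)

# words before a period that do NOT end a sentence
_ABBREVIATIONS = frozenset(
    {
        "e.g",
        "i.e",
        "al",
        "et",
        "fig",
        "figs",
        "vs",
        "ca",
        "cf",
        "approx",
        "dr",
        "mr",
        "mrs",
        "ms",
        "inc",
        "spp",
        "sp",
        "no",
        "ref",
    }
)

_BOUNDARY_RE = re.compile(r"([.!?]+)(\s+|$)")


def _split_sentences(text: str) -> list[str]:
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        prefix = text[start : m.start()]
        last = prefix.rsplit(None, 1)[-1] if prefix.split() else ""
        last = last.strip("()[]{}\"',;:").rstrip(".").lower()
        if last in _ABBREVIATIONS or (len(last) == 1 and last.isalpha()):
            continue
        sentences.append(text[start : m.end(1)].strip())
        start = m.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return [s for s in sentences if s]


def segment(text: str) -> list[list[Token]]:
    """Split cleaned text into sentences of position-indexed tokens."""
    out: list[list[Token]] = []
    for s_idx, sentence in enumerate(_split_sentences(text)):
        tokens = [
            Token(surface=m.group(0), sentence_index=s_idx, position=pos)
            for pos, m in enumerate(_TOKEN_RE.finditer(sentence))
        ]
        if tokens:
            out.append(tokens)
    return out


# ----------------------------------------------------------------------
# stage 4: POS tagging (Penn tagset)

_NUM_RE = re.compile(r"^\d+(\.\d+)?([eE][+-]?\d+)?$")


def _verb_base(word: str, verbs: frozenset[str]) -> tuple[str, str] | None:
    """If *word* is an inflection of a known verb lemma, return (tag, lemma)."""
    if word in verbs:
        return "VB", word
    if word.endswith("ies") and word[:-3] + "y" in verbs:
        return "VBZ", word[:-3] + "y"
    if word.endswith("es") and word[:-2] in verbs:
        return "VBZ", word[:-2]
    if word.endswith("s") and word[:-1] in verbs:
        return "VBZ", word[:-1]
    if word.endswith("ied") and word[:-3] + "y" in verbs:
        return "VBD", word[:-3] + "y"
    if word.endswith("ed"):
        for cand in (word[:-1], word[:-2], _undouble(word[:-2])):
            if cand in verbs:
                return "VBD", cand
    if word.endswith("ing"):
        for cand in (word[:-3] + "e", word[:-3], _undouble(word[:-3])):
            if cand in verbs:
                return "VBG", cand
    return None


def _undouble(stem: str) -> str:
    if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in "aeiou":
        return stem[:-1]
    return stem


_SUFFIX_TAGS = (
    ("ing", "VBG"),
    ("ed", "VBN"),
    ("ly", "RB"),
    ("ous", "JJ"),
    ("ive", "JJ"),
    ("ical", "JJ"),
    ("able", "JJ"),
)


def pos_tag(
    sentences: Sequence[list[Token]],
    lexicon: dict[str, str] | None = None,
    verbs: frozenset[str] | None = None,
) -> list[list[Token]]:
    """Fill ``token.pos`` in place (and return the sentences)."""
    if lexicon is None:
        lexicon = load_pos_lexicon()
    if verbs is None:
        verbs = load_verb_lemmas()
    for sentence in sentences:
        for tok in sentence:
            word = tok.surface.lower()
            if not any(ch.isalnum() for ch in word):
                tok.pos = "." if word in ".!?" else word
                continue
            if _NUM_RE.match(word):
                tok.pos = "CD"
                continue
            if word in lexicon:
                tok.pos = lexicon[word]
                continue
            vb = _verb_base(word, verbs)
            if vb is not None:
                tok.pos = vb[0]
                continue
            for suffix, tag in _SUFFIX_TAGS:
                if word.endswith(suffix) and len(word) > len(suffix) + 2:
                    tok.pos = tag
                    break
            else:
                if (
                    word.endswith("s")
                    and not word.endswith(("ss", "us", "is"))
                    and len(word) > 3
                ):
                    tok.pos = "NNS"
                else:
                    tok.pos = "NN"
        # contextual pass: a gerund directly before a noun acts as a
        # noun-compound modifier ("drinking water" stays a noun pair)
        for left, right in zip(sentence, sentence[1:]):
            if left.pos == "VBG" and right.pos.startswith("NN"):
                left.pos = "NN"
    return list(sentences)


# ----------------------------------------------------------------------
# stage 7 prerequisite: lemmatization


def _strip_plural(word: str) -> str:
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith(("ses", "xes", "zes", "ches", "shes")):
        return word[:-2]
    if word.endswith("s") and not word.endswith("ss") and len(word) > 3:
        return word[:-1]
    return word


def lemmatize(
    sentences: Sequence[list[Token]],
    exceptions: dict[str, str] | None = None,
    verbs: frozenset[str] | None = None,
) -> list[list[Token]]:
    """Fill ``token.lemma`` in place using exception lexicon then rules."""
    if exceptions is None:
        exceptions = load_lemma_exceptions()
    if verbs is None:
        verbs = load_verb_lemmas()
    for sentence in sentences:
        for tok in sentence:
            word = tok.surface.lower()
            if word in exceptions:
                tok.lemma = exceptions[word]
                continue
            pos = tok.pos
            if pos.startswith("VB"):
                vb = _verb_base(word, verbs)
                if vb is not None:
                    tok.lemma = vb[1]
                    continue
                if pos in ("VBD", "VBN") and word.endswith("ed"):
                    if word.endswith("ied"):
                        tok.lemma = word[:-3] + "y"
                    else:
                        tok.lemma = _undouble(word[:-2])
                    continue
                if pos == "VBG" and word.endswith("ing"):
                    tok.lemma = _undouble(word[:-3])
                    continue
                if pos == "VBZ":
                    tok.lemma = _strip_plural(word)
                    continue
            if pos == "NNS":
                tok.lemma = _strip_plural(word)
                continue
            tok.lemma = word
    return list(sentences)


# ----------------------------------------------------------------------
# stage 5: named-entity recognition (gazetteer baseline)


def recognize_entities(
    sentences: Sequence[list[Token]],
    gazetteer: Sequence[tuple[str, str]] | None = None,
) -> list[EntityMention]:
    """Longest-match, non-overlapping gazetteer matching, left to right."""
    if gazetteer is None:
        gazetteer = load_gazetteer()
    # phrase tokens (lowercased) -> entity type; longest phrase wins
    compiled: dict[tuple[str, ...], str] = {}
    max_len = 0
    for etype, phrase in gazetteer:
        toks = tuple(m.group(0) for m in _TOKEN_RE.finditer(phrase.lower()))
        if toks:
            compiled[toks] = etype
            max_len = max(max_len, len(toks))
    mentions: list[EntityMention] = []
    for sentence in sentences:
        lowered = [t.surface.lower() for t in sentence]
        i = 0
        while i < len(sentence):
            matched = False
            for width in range(min(max_len, len(sentence) - i), 0, -1):
                key = tuple(lowered[i : i + width])
                if key in compiled:
                    span = " ".join(t.surface for t in sentence[i : i + width])
                    mentions.append(EntityMention(compiled[key], span))
                    i += width
                    matched = True
                    break
            if not matched:
                i += 1
    return mentions


# ----------------------------------------------------------------------
# stage 6: dependency parsing (finite-state SVO baseline)

_NOUN_TAGS = {"NN", "NNS", "NNP", "NNPS"}
_GROUP_TAGS = _NOUN_TAGS | {"JJ", "CD"}
_VERB_TAGS = {"VB", "VBZ", "VBD", "VBP"}
_SKIP_TAGS = {"DT", "RB", "MD"}


def _noun_groups(sentence: Sequence[Token]) -> list[tuple[int, int, int]]:
    """Maximal (start, end, head_index) noun groups; head = last noun."""
    groups = []
    i = 0
    n = len(sentence)
    while i < n:
        if sentence[i].pos in _GROUP_TAGS:
            j = i
            while j + 1 < n and sentence[j + 1].pos in _GROUP_TAGS:
                j += 1
            head = None
            for k in range(j, i - 1, -1):
                if sentence[k].pos in _NOUN_TAGS:
                    head = k
                    break
            if head is not None:
                groups.append((i, j, head))
            i = j + 1
        else:
            i += 1
    return groups


def parse_dependencies(
    sentences: Sequence[list[Token]],
) -> list[DependencyArc]:
    """Emit subject/object arcs from noun-group–verb–noun-group patterns,
    plus modifier arcs for non-head tokens inside each noun group."""
    arcs: list[DependencyArc] = []
    for sentence in sentences:
        groups = _noun_groups(sentence)
        for start, end, head in groups:
            for k in range(start, end + 1):
                if k != head:
                    arcs.append(
                        DependencyArc("modifier", sentence[head], sentence[k])
                    )
        for v_idx, tok in enumerate(sentence):
            if tok.pos not in _VERB_TAGS:
                continue
            subj = None
            for start, end, head in groups:
                if end < v_idx:
                    subj = head
                else:
                    break
            # subject group must be adjacent to the verb (skip tags allowed)
            if subj is not None:
                between = sentence[subj + 1 : v_idx]
                if any(t.pos not in _SKIP_TAGS for t in between):
                    subj = None
            obj = None
            for start, end, head in groups:
                if start > v_idx:
                    between = sentence[v_idx + 1 : start]
                    if all(t.pos in _SKIP_TAGS for t in between):
                        obj = head
                    break
            if subj is not None:
                arcs.append(
                    DependencyArc("subject", sentence[v_idx], sentence[subj])
                )
            if obj is not None:
                arcs.append(
                    DependencyArc("object", sentence[v_idx], sentence[obj])
                )
    return arcs


# ----------------------------------------------------------------------
# adapter registry

_REGISTRY: dict[str, dict[str, Callable]] = {
    "tokenize": {"baseline": segment},
    "pos": {"baseline": pos_tag},
    "lemma": {"baseline": lemmatize},
    "ner": {"baseline": recognize_entities},
    "parse": {"baseline": parse_dependencies},
}

STAGES = tuple(_REGISTRY)


def register_adapter(stage: str, name: str, fn: Callable) -> None:
    """Register an external adapter for one pipeline stage."""
    if stage not in _REGISTRY:
        raise KeyError(f"unknown pipeline stage: {stage!r}")
    _REGISTRY[stage][name] = fn


def get_adapter(stage: str, name: str = "baseline") -> Callable:
    try:
        return _REGISTRY[stage][name]
    except KeyError:
        raise KeyError(f"no adapter {name!r} for stage {stage!r}") from None


class TextAnnotator:
    """Run the full annotation pipeline over document records.

    Parameters
    ----------
    adapters : mapping stage -> adapter name, optional
        Defaults to the built-in baseline for every stage.
    include_title : bool
        Whether the title is prepended to the abstract before annotation
        (off by default: classification text is the abstract).
    """

    def __init__(
        self,
        adapters: dict[str, str] | None = None,
        include_title: bool = False,
    ):
        adapters = adapters or {}
        self._fns = {
            stage: get_adapter(stage, adapters.get(stage, "baseline"))
            for stage in STAGES
        }
        self.include_title = include_title

    def annotate(self, record: DocumentRecord) -> AnnotatedDocument:
        text = record.abstract
        if self.include_title and record.title:
            text = record.title + ". " + text if text else record.title
        sentences = self._fns["tokenize"](clean_text(text))
        sentences = self._fns["pos"](sentences)
        sentences = self._fns["lemma"](sentences)
        entities = self._fns["ner"](sentences)
        arcs = []
        for sentence in sentences:
            try:
                arcs.extend(self._fns["parse"]([sentence]))
            except Exception:  # adapter failure -> empty arcs for sentence
                continue
        return AnnotatedDocument(
            record=record, sentences=sentences, arcs=arcs, entities=entities
        )


def annotate_corpus(
    records: Iterable[DocumentRecord],
    annotator: TextAnnotator | None = None,
) -> list[AnnotatedDocument]:
    annotator = annotator or TextAnnotator()
    return [annotator.annotate(r) for r in records]
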