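"""Baseline NLP stages: cleaning, segmentation, tagging, lemmas, NER, parsing."""

import pytest

import expotext as et
from expotext.nlp import (
    clean_text,
    lemmatize,
    parse_dependencies,
    pos_tag,
    recognize_entities,
    register_adapter,
    segment,
)


# hand-cleaned oracle pairs for the text cleaner
CLEANING_CASES = [
    ("lead\x00 exposure", "lead exposure"),
    ("already clean", "already clean"),
    ("tabs\tand\nnewlines", "tabs and newlines"),
    ("  leading and trailing  ", "leading and trailing"),
    ("zero​width", "zero width"),
    ("double  spaces   here", "double spaces here"),
    ("µg/L", "μg/L"),  # NFKC: micro sign -> greek mu
    ("", ""),
    ("ﬁne ligature", "fine ligature"),  # NFKC expands the fi ligature
    ("bell\x07char", "bell char"),
]


@pytest.mark.parametrize("raw, expected", CLEANING_CASES)
def test_clean_text_matches_hand_cleaned_oracle(raw, expected):
    assert clean_text(raw) == expected
    # idempotence on the cleaned output
    assert clean_text(expected) == expected


def test_segmentation_counts_and_boundaries():
    assert len(segment("Pb was measured. Levels rose.")) == 2
    assert segment("") == []
    one = segment("only one sentence without punctuation")
    assert len(one) == 1


@pytest.mark.parametrize(
    "text, n_sentences",
    [
        ("Samples (e.g. blood) were used. Results follow.", 2),
        ("Smith et al. reported levels. We agree.", 2),
        ("See Fig. 2 for details. It is clear.", 2),
        ("Exposure was 2.5 mg per day. It dropped.", 2),
        ("One. Two. Three.", 3),
    ],
)
def test_abbreviations_and_decimals_do_not_split(text, n_sentences):
    assert len(segment(text)) == n_sentences


def test_tokenizer_keeps_hyphenated_names_and_decimals():
    tokens = [t.surface for t in segment("MCF-7 cells held 2.5 mg.")[0]]
    assert "MCF-7" in tokens
    assert "2.5" in tokens


def test_segmentation_preserves_non_space_characters():
    text = "Lead affects hemoglobin, blood and urine."
    sentences = segment(text)
    joined = "".join(t.surface for s in sentences for t in s)
    assert joined == text.replace(" ", "")


def test_pos_tagging_baseline_rules():
    sents = pos_tag(segment("blood sample measured quickly 42"))
    tags = {t.surface: t.pos for t in sents[0]}
    assert tags["blood"] == "NN"
    assert tags["sample"] == "NN"
    assert tags["measured"] in ("VBD", "VBN")
    assert tags["quickly"] == "RB"
    assert tags["42"] == "CD"


def test_tagging_and_lemmatization_never_change_token_counts():
    sents = segment("Children were exposed. Levels were measured twice.")
    n = [len(s) for s in sents]
    sents = pos_tag(sents)
    assert [len(s) for s in sents] == n
    sents = lemmatize(sents)
    assert [len(s) for s in sents] == n


# (surface, pos, lemma) oracle built from exception lexicon + suffix rules
LEMMA_CASES = [
    ("measured", "VBD", "measure"),
    ("children", "NNS", "child"),
    ("levels", "NNS", "level"),
    ("measures", "VBZ", "measure"),
    ("affects", "VBZ", "affect"),
    ("studies", "NNS", "study"),
    ("was", "VBD", "be"),
    ("exposed", "VBN", "expose"),
    ("stopped", "VBD", "stop"),
    ("increasing", "VBG", "increase"),
    ("women", "NNS", "woman"),
    ("Blood", "NN", "blood"),
]


@pytest.mark.parametrize("surface, pos, expected", LEMMA_CASES)
def test_lemmatizer_matches_rule_oracle(surface, pos, expected):
    token = et.nlp.Token(surface=surface, sentence_index=0, position=0, pos=pos)
    lemmatize([[token]])
    assert token.lemma == expected


def test_gazetteer_ner_finds_protein_mention():
    sents = pos_tag(segment("Lead affects hemoglobin in lymphocytes."))
    mentions = recognize_entities(sents)
    types = {(m.entity_type, m.span_text.lower()) for m in mentions}
    assert ("protein", "hemoglobin") in types
    assert ("cell_type", "lymphocytes") in types


def test_ner_empty_gazetteer_and_longest_match():
    sents = segment("glutathione peroxidase rose")
    assert recognize_entities(sents, gazetteer=[]) == []
    gaz = [
        ("protein", "glutathione"),
        ("protein", "glutathione peroxidase"),
    ]
    mentions = recognize_entities(sents, gazetteer=gaz)
    # brute-force span enumeration: the 2-token span dominates the 1-token one
    assert [m.span_text for m in mentions] == ["glutathione peroxidase"]


def _brute_force_spans(tokens, gaz_phrases):
    """All non-overlapping matches, longest-first left-to-right."""
    lowered = [t.lower() for t in tokens]
    out = []
    i = 0
    while i < len(tokens):
        best = 0
        for phrase in gaz_phrases:
            words = phrase.split()
            if lowered[i : i + len(words)] == words:
                best = max(best, len(words))
        if best:
            out.append(" ".join(tokens[i : i + best]))
            i += best
        else:
            i += 1
    return out


def test_ner_agrees_with_exhaustive_span_oracle():
    text = "dna adducts and mitochondrial dna rose in hela erythrocytes"
    sents = segment(text)
    gaz = [
        ("DNA", "dna"),
        ("DNA", "dna adducts"),
        ("DNA", "mitochondrial dna"),
        ("cell_line", "hela"),
        ("cell_type", "erythrocytes"),
    ]
    mentions = recognize_entities(sents, gazetteer=gaz)
    tokens = [t.surface for t in sents[0]]
    assert [m.span_text for m in mentions] == _brute_force_spans(
        tokens, [p for _, p in gaz]
    )


SVO_CASES = [
    (
        "lead affects hemoglobin",
        {("subject", "affects", "lead"), ("object", "affects", "hemoglobin")},
    ),
    (
        "cadmium increases oxidative stress",
        {
            ("subject", "increases", "cadmium"),
            ("object", "increases", "stress"),
            ("modifier", "stress", "oxidative"),
        },
    ),
    ("no verb here", set()),  # verb-less: no subject/object arcs
    (
        "the metal alters the protein",
        {("subject", "alters", "metal"), ("object", "alters", "protein")},
    ),
]


@pytest.mark.parametrize("text, expected", SVO_CASES)
def test_finite_state_parser_emits_expected_arcs(text, expected):
    sents = pos_tag(segment(text))
    arcs = {
        (a.relation, a.head.surface, a.dependent.surface)
        for a in parse_dependencies(sents)
    }
    subject_object = {a for a in arcs if a[0] in ("subject", "object")}
    if any(rel == "modifier" for rel, _, _ in expected):
        assert arcs == expected
    else:
        assert subject_object == {
            a for a in expected if a[0] in ("subject", "object")
        }


def test_full_pipeline_is_deterministic(annotator):
    rec = et.DocumentRecord(
        pmid="1",
        abstract="Blood lead affects hemoglobin. Children were exposed via dust.",
    )
    d1 = annotator.annotate(rec)
    d2 = annotator.annotate(rec)
    assert d1.sentences == d2.sentences
    assert [
        (a.relation, a.head.surface, a.dependent.surface) for a in d1.arcs
    ] == [(a.relation, a.head.surface, a.dependent.surface) for a in d2.arcs]
    assert d1.entities == d2.entities


def test_entity_types_are_closed_set():
    with pytest.raises(ValueError):
        et.nlp.EntityMention("virus", "x")


def test_adapter_registry_selects_custom_stage():
    register_adapter("ner", "null", lambda sentences: [])
    annotator = et.TextAnnotator(adapters={"ner": "null"})
    doc = annotator.annotate(
        et.DocumentRecord(pmid="1", abstract="hemoglobin rose.")
    )
    assert doc.entities == []
    with pytest.raises(KeyError):
        et.TextAnnotator(adapters={"ner": "missing"})


def test_title_inclusion_flag(annotator):
    rec = et.DocumentRecord(pmid="1", title="Mercury in fish", abstract="")
    assert annotator.annotate(rec).sentences == []
    with_title = et.TextAnnotator(include_title=True)
    doc = with_title.annotate(rec)
    surfaces = [t.surface for s in doc.sentences for t in s]
    assert "Mercury" in surfaces
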