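"""Phi features, agreement methods, and the cumulative scoring function."""

import itertools
import random

import pytest

from biocoref import (
    AgreementSpec,
    Conjunction,
    MentionType,
    agree,
    compute_phi,
    parse_agreement_spec,
    score_candidate,
)
from biocoref.agreement import ConfigError, relaxed_stem_overlap
from biocoref.fixtures import build_document
from biocoref.mentions import detect_mentions
from biocoref.preprocessing import preprocess
from biocoref.resources import load_toy_taxonomy
from biocoref.stemmer import porter_stem
from biocoref.types import Mention, Span

import sentence_fixtures as sf


def build(sents, **kw):
    g = build_document(sents, **kw)
    doc = preprocess(g.doc)
    doc.mentions = detect_mentions(doc)
    return g, doc


def mention_by_text(doc, text):
    return next(m for m in doc.mentions if doc.slice(m.span) == text)


def entity_by_text(doc, text):
    return next(e for e in doc.entities if doc.slice(e.span) == text)


# ------------------------------------------------------------------ phi


def test_phi_for_pronouns():
    s = (
        [
            ("they", "PRP"), ("saw", "VBD", "see"), ("her", "PRP"),
            ("and", "CC"), ("it", "PRP"), (".", "."),
        ],
        [
            ("nsubj", 1, 0), ("dobj", 1, 2), ("cc", 2, 3), ("conj", 2, 4),
            ("punct", 1, 5),
        ],
    )
    _, doc = build([s])
    phi = compute_phi(mention_by_text(doc, "they"), doc)
    assert (phi.number, phi.gender, phi.animacy, phi.person) == (
        "plural", "Unknown", "MaybeAnimate", "Third",
    )
    phi = compute_phi(mention_by_text(doc, "her"), doc)
    assert (phi.gender, phi.animacy) == ("Female", "Animate")
    phi = compute_phi(mention_by_text(doc, "it"), doc)
    assert (phi.number, phi.animacy) == ("singular", "NotAnimate")


def test_phi_plural_for_conjunctions_and_collectives():
    s = (
        [
            ("aspirin", "NN"), ("and", "CC"), ("heparin", "NN"),
            ("helped", "VBD", "help"), ("the", "DT"),
            ("population", "NN"), (".", "."),
        ],
        [
            ("cc", 0, 1), ("conj", 0, 2), ("nsubj", 3, 0), ("dobj", 3, 5),
            ("det", 5, 4), ("punct", 3, 6),
        ],
    )
    g, doc = build(
        [s],
        entities=[(0, 0, 1, "drug"), (0, 2, 3, "drug"), (0, 5, 6, "population")],
    )
    conj = doc.conjunctions[0]
    assert compute_phi(conj, doc).number == "plural"
    pop = entity_by_text(doc, "population")
    phi = compute_phi(pop, doc)
    assert phi.number == "plural"  # collective noun
    assert phi.animacy == "Animate"  # population semantic group


def test_phi_is_total_on_arbitrary_mentions():
    s = ([("...", ":"), ("xyzzy", "NN"), (".", ".")], [("punct", 1, 0), ("punct", 1, 2)])
    g, doc = build([s])
    m = Mention(span=Span(4, 9), mtype=MentionType.ZeroArticleNP, head=(0, 1))
    phi = compute_phi(m, doc)
    assert (phi.number, phi.gender, phi.animacy, phi.person) == (
        "singular", "Unknown", "NotAnimate", "Third",
    )


# ----------------------------------------------------------- agreements


def test_number_requires_two_entity_coordination_for_distributives():
    g, doc = build(
        [
            (
                [
                    ("Patients", "NNS", "patient"), ("received", "VBD", "receive"),
                    ("aspirin", "NN"), (",", ","), ("warfarin", "NN"), (",", ","),
                    ("and", "CC"), ("heparin", "NN"), (".", "."),
                ],
                [
                    ("nsubj", 1, 0), ("dobj", 1, 2), ("punct", 2, 3),
                    ("conj", 2, 4), ("punct", 2, 5), ("cc", 2, 6),
                    ("conj", 2, 7), ("punct", 1, 8),
                ],
            ),
            (
                [("Both", "DT", "both"), ("helped", "VBD", "help"), (".", ".")],
                [("nsubjpass", 1, 0), ("punct", 1, 2)],
            ),
        ],
        entities=[(0, 2, 3, "drug"), (0, 4, 5, "drug"), (0, 7, 8, "drug")],
    )
    both = mention_by_text(doc, "Both")
    conj3 = doc.conjunctions[0]
    assert len(conj3.conjuncts) == 3
    assert agree("Number", both, conj3, doc) is False
    conj2 = Conjunction(conjuncts=conj3.conjuncts[:2], span=conj3.span, semgroup="drug_substance")
    assert agree("Number", both, conj2, doc) is True


def test_number_word_two_requires_pair():
    g, doc = build(
        [
            (
                [
                    ("Oral", "JJ"), ("amiodarone", "NN"),
                    ("inhibits", "VBZ", "inhibit"), ("CYP3A", "NN"),
                    ("and", "CC"), ("CYP2C8", "NN"), (".", "."),
                ],
                [
                    ("amod", 1, 0), ("nsubj", 2, 1), ("dobj", 2, 3),
                    ("cc", 3, 4), ("conj", 3, 5), ("punct", 2, 6),
                ],
            ),
            (
                [
                    ("These", "DT", "this"), ("two", "CD"),
                    ("enzymes", "NNS", "enzyme"), ("matter", "VBP"), (".", "."),
                ],
                [("det", 2, 0), ("num", 2, 1), ("nsubj", 3, 2), ("punct", 3, 4)],
            ),
        ],
        entities=[(0, 1, 2, "drug"), (0, 3, 4, "substance"), (0, 5, 6, "substance")],
    )
    m = mention_by_text(doc, "These two enzymes")
    conj = doc.conjunctions[0]
    assert agree("Number", m, conj, doc) is True
    amiodarone = entity_by_text(doc, "amiodarone")
    assert agree("Number", m, amiodarone, doc) is False


def test_number_singular_vs_plural_nominal():
    g = sf.definite_np_sentence()
    doc = preprocess(g.doc)
    doc.mentions = detect_mentions(doc)
    m = mention_by_text(doc, "the product")
    plavix = entity_by_text(doc, "Plavix")
    assert agree("Number", m, plavix, doc) is True


def test_hypernym_list_agreement():
    g = sf.definite_np_sentence()
    doc = preprocess(g.doc)
    doc.mentions = detect_mentions(doc)
    m = mention_by_text(doc, "the product")
    assert agree("HypernymList", m, entity_by_text(doc, "Plavix"), doc) is True


def test_discourse_connective_agreement():
    s, ents, ments = sf.connective_cataphora_sentence()
    g = build_document(s, entities=ents, mentions=ments)
    doc = preprocess(g.doc)
    doc.mentions = detect_mentions(doc)
    its = mention_by_text(doc, "its")
    zebeta = entity_by_text(doc, "ZEBETA")
    assert agree("DiscourseConnective", its, zebeta, doc) is True


def test_syntactic_appositive_by_edge_and_contiguity():
    toks = [
        ("the", "DT"), ("ACE", "NN"), ("inhibitor", "NN"),
        ("enalapril", "NN"), ("helped", "VBD", "help"), (".", "."),
    ]
    edges = [
        ("det", 2, 0), ("nn", 2, 1), ("nsubj", 4, 2), ("appos", 2, 3),
        ("punct", 4, 5),
    ]
    g, doc = build([(toks, edges)], entities=[(0, 3, 4, "drug")])
    m = mention_by_text(doc, "the ACE inhibitor")
    ena = entity_by_text(doc, "enalapril")
    assert agree("SyntacticAppositive", m, ena, doc) is True


def test_syntactic_predicate_nominative_and_negation():
    toks = [
        ("Clopidogrel", "NN"), ("is", "VBZ", "be"), ("a", "DT"),
        ("prodrug", "NN"), (".", "."),
    ]
    edges = [("nsubj", 3, 0), ("cop", 3, 1), ("det", 3, 2), ("punct", 3, 4)]
    g, doc = build([(toks, edges)], entities=[(0, 0, 1, "drug")])
    m = mention_by_text(doc, "a prodrug")
    clop = doc.entities[0]
    assert agree("SyntacticPredicateNominative", m, clop, doc) is True

    # negated copular construction does not agree
    toks2 = [
        ("Clopidogrel", "NN"), ("is", "VBZ", "be"), ("not", "RB"),
        ("a", "DT"), ("prodrug", "NN"), (".", "."),
    ]
    edges2 = [
        ("nsubj", 4, 0), ("cop", 4, 1), ("neg", 4, 2), ("det", 4, 3),
        ("punct", 4, 5),
    ]
    g2, doc2 = build([(toks2, edges2)], entities=[(0, 0, 1, "drug")])
    m2 = mention_by_text(doc2, "a prodrug")
    assert agree("SyntacticPredicateNominative", m2, doc2.entities[0], doc2) is False


def string_pair_doc(a_tokens, b_tokens, a_type="problem", b_type="problem"):
    def sent(tokens):
        toks = list(tokens) + [(".", ".")]
        n = len(toks)
        edges = [("dep", n - 2, i) for i in range(n - 2)] + [("punct", n - 2, n - 1)]
        return (toks, edges)

    g = build_document([sent(a_tokens), sent(b_tokens)])
    doc = preprocess(g.doc)
    a_span = Span(0, sum(len(t[0]) for t in a_tokens) + len(a_tokens) - 1)
    start_b = doc.sentences[1].span.start
    b_span = Span(start_b, start_b + sum(len(t[0]) for t in b_tokens) + len(b_tokens) - 1)
    ha = len(a_tokens) - 1
    hb = len(b_tokens) - 1
    ma = Mention(span=a_span, mtype=MentionType.ZeroArticleNP, head=(0, ha), semtype=a_type)
    mb = Mention(span=b_span, mtype=MentionType.ZeroArticleNP, head=(1, hb), semtype=b_type)
    return doc, ma, mb


def test_exact_string_ignores_case():
    doc, a, b = string_pair_doc([("PLAVIX", "NN")], [("plavix", "NN")])
    assert agree("ExactString", a, b, doc) is True


def test_premodifier_and_head_match():
    doc, a, b = string_pair_doc(
        [("a", "DT"), ("1", "CD"), ("cm", "NN"), ("cyst", "NN")],
        [("the", "DT"), ("1", "CD"), ("cm", "NN"), ("cyst", "NN")],
    )
    assert agree("PreModifierAndHead", a, b, doc) is True
    doc, a, b = string_pair_doc(
        [("a", "DT"), ("2", "CD"), ("cm", "NN"), ("cyst", "NN")],
        [("the", "DT"), ("1", "CD"), ("cm", "NN"), ("cyst", "NN")],
    )
    assert agree("PreModifierAndHead", a, b, doc) is False


def test_relaxed_stem_agreement_and_number_strictness():
    doc, a, b = string_pair_doc(
        [("Propofol", "NN"), ("drips", "NNS", "drip")],
        [("his", "PRP$"), ("propofol", "NN"), ("drip", "NN")],
    )
    assert agree("RelaxedStem", a, b, doc) is True
    doc, a, b = string_pair_doc(
        [("70", "CD"), ("white", "JJ"), ("blood", "NN"), ("cells", "NNS", "cell")],
        [("5-10", "CD"), ("white", "JJ"), ("blood", "NN"), ("cells", "NNS", "cell")],
    )
    assert agree("RelaxedStem", a, b, doc) is False


def test_relaxed_stem_boundary_is_strict():
    """Exactly half overlap does not agree; strictly above half does."""
    doc, a, b = string_pair_doc(
        [("alpha", "NN"), ("beta", "NN"), ("gamma", "NN"), ("delta", "NN")],
        [("alpha", "NN"), ("beta", "NN"), ("epsilon", "NN"), ("zeta", "NN")],
    )
    assert relaxed_stem_overlap(doc, a, b) == 0.5
    assert agree("RelaxedStem", a, b, doc) is False
    doc, a, b = string_pair_doc(
        [("alpha", "NN"), ("beta", "NN"), ("gamma", "NN"), ("delta", "NN")],
        [("alpha", "NN"), ("beta", "NN"), ("gamma", "NN"), ("zeta", "NN")],
    )
    assert relaxed_stem_overlap(doc, a, b) == 0.75
    assert agree("RelaxedStem", a, b, doc) is True


def test_key_value_pair_agreement():
    toks = [
        ("Attending", "NN"), (":", ":"), ("I", "NN"), ("BUN", "NN"),
        (",", ","), ("M.D.", "NN"), (".", "."),
    ]
    edges = [
        ("punct", 0, 1), ("dep", 0, 3), ("nn", 3, 2), ("punct", 3, 4),
        ("appos", 3, 5), ("punct", 0, 6),
    ]
    g = build_document([(toks, edges)])
    doc = preprocess(g.doc)
    key = Mention(span=Span(0, 9), mtype=MentionType.ZeroArticleNP, head=(0, 0), semtype="person")
    val = Mention(span=Span(12, 17), mtype=MentionType.ZeroArticleNP, head=(0, 3), semtype="person")
    assert agree("KeyValuePair", key, val, doc) is True
    val2 = Mention(span=Span(12, 17), mtype=MentionType.ZeroArticleNP, head=(0, 3), semtype="test")
    assert agree("KeyValuePair", key, val2, doc) is False


def test_semantic_coercion_for_possessives():
    toks = [
        ("Oral", "JJ"), ("amiodarone", "NN"), ("was", "VBD", "be"),
        ("given", "VBN", "give"), (";", ":"), ("its", "PRP$"),
        ("absorption", "NN"), ("was", "VBD", "be"), ("slow", "JJ"), (".", "."),
    ]
    edges = [
        ("amod", 1, 0), ("nsubjpass", 3, 1), ("auxpass", 3, 2), ("punct", 3, 4),
        ("poss", 6, 5), ("nsubj", 8, 6), ("cop", 8, 7), ("punct", 8, 9),
    ]
    g, doc = build([(toks, edges)], entities=[(0, 1, 2, "drug")])
    its = mention_by_text(doc, "its")
    assert agree("SemanticCoercion", its, doc.entities[0], doc) is True


def test_semantic_type_and_group():
    g = sf.definite_np_sentence()
    doc = preprocess(g.doc)
    m = Mention(
        span=doc.entities[0].span, mtype=MentionType.ZeroArticleNP,
        semtype="drug", semgroup="drug_substance",
    )
    assert agree("SemanticType", m, doc.entities[1], doc) is True
    assert agree("SemanticGroup", m, doc.entities[1], doc) is True


def test_taxonomy_agreement_with_toy_taxonomy():
    g = sf.definite_np_sentence()
    doc = preprocess(g.doc)
    doc.mentions = detect_mentions(doc)
    m = mention_by_text(doc, "the product")
    object.__setattr__ if False else setattr(m, "concept", "calcium_channel_blocker")
    ent = doc.entities[0]
    ent.concept = "diltiazem"
    res = {"taxonomy": load_toy_taxonomy()}
    assert agree("Taxonomy", m, ent, doc, res) is True
    ent.concept = "warfarin"
    assert agree("Taxonomy", m, ent, doc, res) is False
    with pytest.raises(ConfigError):
        agree("Taxonomy", m, ent, doc, {})


def test_adjacency_allows_punctuation_and_prepositions():
    toks = [
        ("p50", "NN"), (",", ","), ("which", "WDT"),
        ("dimerizes", "VBZ", "dimerize"), (".", "."),
    ]
    edges = [
        ("punct", 0, 1), ("nsubj", 3, 2), ("rcmod", 0, 3), ("punct", 3, 4),
    ]
    g, doc = build([(toks, edges)], entities=[(0, 0, 1, "Protein")])
    doc.mentions = detect_mentions(doc)
    which = mention_by_text(doc, "which")
    assert agree("Adjacency", which, doc.entities[0], doc) is True


# --------------------------------------------------------------- scoring


def test_spec_parsing_and_validation():
    spec = parse_agreement_spec("Number(1,1)")
    assert spec == AgreementSpec("Number", 1, 1)
    with pytest.raises(ConfigError):
        parse_agreement_spec("Treshold(4)")
    with pytest.raises(ConfigError):
        parse_agreement_spec("Number(1)")


def test_cumulative_score_examples(simple_fixture, spl_config):
    """All four phi agreements at (1,0) sum to 4; a reward/penalty mix sums
    accordingly."""
    from biocoref.strategy import resolve_document

    g = simple_fixture
    doc = preprocess(g.doc)
    doc.mentions = detect_mentions(doc)
    it = mention_by_text(doc, "It")
    ent = doc.entities[0]
    specs = [parse_agreement_spec(s) for s in
             ("Person(1,0)", "Gender(1,0)", "Animacy(1,0)", "Number(1,0)")]
    assert score_candidate(it, ent, specs, doc).score == 4

    # hypernym agrees (+3), number disagrees (-1)
    g2 = build_document(
        [
            (
                [
                    ("Patients", "NNS", "patient"), ("took", "VBD", "take"),
                    ("warfarin", "NN"), (".", "."),
                ],
                [("nsubj", 1, 0), ("dobj", 1, 2), ("punct", 1, 3)],
            ),
            (
                [
                    ("The", "DT"), ("drugs", "NNS", "drug"),
                    ("helped", "VBD", "help"), (".", "."),
                ],
                [("det", 1, 0), ("nsubj", 2, 1), ("punct", 2, 2 + 1)],
            ),
        ],
        entities=[(0, 2, 3, "drug")],
    )
    doc2 = preprocess(g2.doc)
    doc2.mentions = detect_mentions(doc2)
    m = mention_by_text(doc2, "The drugs")
    specs = [parse_agreement_spec("Number(1,1)"), parse_agreement_spec("HypernymList(3,0)")]
    assert score_candidate(m, g2.doc.entities[0], specs, doc2).score == 2


def test_score_bounds_and_permutation_invariance(simple_fixture):
    g = simple_fixture
    doc = preprocess(g.doc)
    doc.mentions = detect_mentions(doc)
    it = mention_by_text(doc, "It")
    ent = doc.entities[0]
    rng = random.Random(0)
    methods = ["Person", "Gender", "Animacy", "Number", "HypernymList", "ExactString"]
    for _ in range(25):
        specs = [
            AgreementSpec(m, rng.randint(0, 3), rng.randint(0, 3))
            for m in rng.sample(methods, rng.randint(1, len(methods)))
        ]
        score = score_candidate(it, ent, specs, doc).score
        assert -sum(s.penalty for s in specs) <= score <= sum(s.reward for s in specs)
        shuffled = specs[:]
        rng.shuffle(shuffled)
        assert score_candidate(it, ent, shuffled, doc).score == score


def test_string_measure_implication_chain():
    """An exact string match implies premodifier+head match implies relaxed
    stem match (determiner-free equal strings)."""
    doc, a, b = string_pair_doc(
        [("propofol", "NN"), ("drip", "NN")], [("propofol", "NN"), ("drip", "NN")]
    )
    assert agree("ExactString", a, b, doc)
    assert agree("PreModifierAndHead", a, b, doc)
    assert agree("RelaxedStem", a, b, doc)


def test_porter_stemmer_classic_forms():
    assert porter_stem("drips") == "drip"
    assert porter_stem("caresses") == "caress"
    assert porter_stem("ponies") == "poni"
    assert porter_stem("relational") == "relat"
    assert porter_stem("conditional") == "condit"
    assert porter_stem("hopping") == "hop"
    assert porter_stem("medications") == porter_stem("medication")
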