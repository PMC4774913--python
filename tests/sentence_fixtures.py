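"""Hand-built drug-label sentences with hand-written dependency parses.

Each fixture reproduces a construction the resolver must handle: set
membership over coordinated enzymes, definite-NP anaphora, pleonastic
*it*, appositive filtering, exemplification, connective-licensed
cataphora, anaphora/cataphora conflicts, semantic-group pruning, and
parse-tree salience.  They are used by the regression suite and by the
acceptance checks.
"""

from biocoref.fixtures import build_document
from biocoref.types import CoreferenceType, MentionType

A = CoreferenceType.anaphora
C = CoreferenceType.cataphora


def set_membership_sentence():
    """'Since X is a substrate for E1 and E2, drugs that inhibit these
    isoenzymes may decrease the metabolism' — a demonstrative NP referring
    to the members of a coordinated enzyme pair."""
    toks = [
        ("Since", "IN"), ("amiodarone", "NN"), ("is", "VBZ", "be"),
        ("a", "DT"), ("substrate", "NN"), ("for", "IN"), ("CYP3A", "NN"),
        ("and", "CC"), ("CYP2C8", "NN"), (",", ","), ("drugs", "NNS", "drug"),
        ("that", "WDT"), ("inhibit", "VBP"), ("these", "DT", "this"),
        ("isoenzymes", "NNS", "isoenzyme"), ("may", "MD"),
        ("decrease", "VB"), ("the", "DT"), ("metabolism", "NN"), (".", "."),
    ]
    edges = [
        ("mark", 4, 0), ("nsubj", 4, 1), ("cop", 4, 2), ("det", 4, 3),
        ("prep", 4, 5), ("pobj", 5, 6), ("cc", 6, 7), ("conj", 6, 8),
        ("advcl", 16, 4), ("punct", 16, 9), ("nsubj", 16, 10),
        ("rcmod", 10, 12), ("nsubj", 12, 10), ("dobj", 12, 14),
        ("det", 14, 13), ("aux", 16, 15), ("det", 18, 17), ("dobj", 16, 18),
        ("punct", 16, 19),
    ]
    return build_document(
        [(toks, edges)],
        entities=[(0, 1, 2, "drug"), (0, 6, 7, "substance"), (0, 8, 9, "substance")],
        mentions=[(0, 13, 15, MentionType.DemonstrativeNP)],
        links=[(A, 0, [1, 2])],
    )


def definite_np_sentence():
    """'Plavix is contraindicated ... any component of the product' — the
    definite NP 'the product' is a coreferential mention."""
    toks = [
        ("Plavix", "NN"), ("is", "VBZ", "be"),
        ("contraindicated", "VBN", "contraindicate"), ("in", "IN"),
        ("patients", "NNS", "patient"), ("with", "IN"),
        ("hypersensitivity", "NN"), ("to", "IN"), ("clopidogrel", "NN"),
        ("or", "CC"), ("any", "DT"), ("component", "NN"), ("of", "IN"),
        ("the", "DT"), ("product", "NN"), (".", "."),
    ]
    edges = [
        ("nsubjpass", 2, 0), ("auxpass", 2, 1), ("prep", 2, 3),
        ("pobj", 3, 4), ("prep", 4, 5), ("pobj", 5, 6), ("prep", 6, 7),
        ("pobj", 7, 8), ("cc", 8, 9), ("conj", 8, 11), ("det", 11, 10),
        ("prep", 11, 12), ("pobj", 12, 14), ("det", 14, 13), ("punct", 2, 15),
    ]
    return build_document(
        [(toks, edges)],
        entities=[(0, 0, 1, "drug"), (0, 8, 9, "drug")],
        mentions=[(0, 13, 15, MentionType.DefiniteNP)],
        links=[(A, 0, [0])],
    )


def pleonastic_sentence():
    """'It is not certain that these events were attributable to DEMADEX.'"""
    toks = [
        ("It", "PRP", "it"), ("is", "VBZ", "be"), ("not", "RB"),
        ("certain", "JJ"), ("that", "IN"), ("these", "DT", "this"),
        ("events", "NNS", "event"), ("were", "VBD", "be"),
        ("attributable", "JJ"), ("to", "IN"), ("DEMADEX", "NN"), (".", "."),
    ]
    edges = [
        ("nsubj", 3, 0), ("cop", 3, 1), ("neg", 3, 2), ("complm", 8, 4),
        ("det", 6, 5), ("nsubj", 8, 6), ("cop", 8, 7), ("ccomp", 3, 8),
        ("prep", 8, 9), ("pobj", 9, 10), ("punct", 3, 11),
    ]
    return build_document(
        [(toks, edges)], entities=[(0, 10, 11, "drug")]
    )


def referential_it_sentence():
    """'It inhibits CYP3A4.' — a referential subject *it* with no clausal
    complement under the governor."""
    toks = [
        ("It", "PRP", "it"), ("inhibits", "VBZ", "inhibit"),
        ("CYP3A4", "NN"), (".", "."),
    ]
    edges = [("nsubj", 1, 0), ("dobj", 1, 2), ("punct", 1, 3)]
    return build_document([(toks, edges)], entities=[(0, 2, 3, "substance")])


def appositive_filter_sentence():
    """'... compared with the monotherapies aliskiren and valsartan .' —
    'the monotherapies' sits in an appositive construction and must not be
    treated as an anaphor."""
    toks = [
        ("The", "DT"), ("incidence", "NN"), ("was", "VBD", "be"),
        ("higher", "JJR", "high"), ("compared", "VBN", "compare"),
        ("with", "IN"), ("the", "DT"), ("monotherapies", "NNS", "monotherapy"),
        ("aliskiren", "NN"), ("and", "CC"), ("valsartan", "NN"), (".", "."),
    ]
    edges = [
        ("det", 1, 0), ("nsubj", 3, 1), ("cop", 3, 2), ("vmod", 3, 4),
        ("prep", 4, 5), ("pobj", 5, 7), ("det", 7, 6), ("appos", 7, 8),
        ("cc", 8, 9), ("conj", 8, 10), ("punct", 3, 11),
    ]
    return build_document(
        [(toks, edges)],
        entities=[(0, 8, 9, "drug"), (0, 10, 11, "drug")],
    )


def rigid_designator_sentence():
    """'The nitric oxide pathway was studied .' — a definite NP whose head
    lies inside a named-entity annotation (a rigid designator)."""
    toks = [
        ("The", "DT"), ("nitric", "JJ"), ("oxide", "NN"), ("pathway", "NN"),
        ("was", "VBD", "be"), ("studied", "VBN", "study"), (".", "."),
    ]
    edges = [
        ("det", 3, 0), ("amod", 3, 1), ("nn", 3, 2), ("nsubjpass", 5, 3),
        ("auxpass", 5, 4), ("punct", 5, 6),
    ]
    return build_document(
        [(toks, edges)], entities=[(0, 1, 4, "substance")]
    )


def exemplification_sentence():
    """'Inhibitors of this isoenzyme (e.g., amiodarone, diltiazem,
    zafirlukast) should be co-administered with TIKOSYN as they can
    increase dofetilide levels.' — parenthesized drugs are
    exemplifications; the pronoun resolves to the class NP."""
    toks = [
        ("Inhibitors", "NNS", "inhibitor"), ("of", "IN"), ("this", "DT"),
        ("isoenzyme", "NN"), ("(", "-LRB-"), ("e.g.", "FW"), (",", ","),
        ("amiodarone", "NN"), (",", ","), ("diltiazem", "NN"), (",", ","),
        ("zafirlukast", "NN"), (")", "-RRB-"), ("should", "MD"),
        ("be", "VB", "be"), ("co-administered", "VBN", "co-administer"),
        ("with", "IN"), ("TIKOSYN", "NN"), ("as", "IN"),
        ("they", "PRP"), ("can", "MD"), ("increase", "VB"),
        ("dofetilide", "NN"), ("levels", "NNS", "level"), (".", "."),
    ]
    edges = [
        ("nsubjpass", 15, 0), ("prep", 0, 1), ("pobj", 1, 3), ("det", 3, 2),
        ("punct", 0, 4), ("dep", 0, 5), ("punct", 0, 6), ("dep", 0, 7),
        ("punct", 0, 8), ("dep", 0, 9), ("punct", 0, 10), ("dep", 0, 11),
        ("punct", 0, 12), ("aux", 15, 13), ("auxpass", 15, 14),
        ("prep", 15, 16), ("pobj", 16, 17), ("mark", 21, 18),
        ("nsubj", 21, 19), ("aux", 21, 20), ("advcl", 15, 21),
        ("nn", 23, 22), ("dobj", 21, 23), ("punct", 15, 24),
    ]
    return build_document(
        [(toks, edges)],
        entities=[
            (0, 7, 8, "drug"), (0, 9, 10, "drug"), (0, 11, 12, "drug"),
            (0, 17, 18, "drug"), (0, 22, 23, "drug"),
        ],
        mentions=[(0, 19, 20, MentionType.PersonalPronoun)],
    )


def connective_cataphora_sentence():
    """'Because of its beta1-selectivity, this is less likely with ZEBETA.'"""
    toks = [
        ("Because", "IN"), ("of", "IN"), ("its", "PRP$"),
        ("beta1-selectivity", "NN"), (",", ","), ("this", "DT"),
        ("is", "VBZ", "be"), ("less", "RBR"), ("likely", "JJ"),
        ("with", "IN"), ("ZEBETA", "NN"), (".", "."),
    ]
    edges = [
        ("prep", 8, 0), ("mwe", 0, 1), ("pobj", 0, 3), ("poss", 3, 2),
        ("punct", 8, 4), ("nsubj", 8, 5), ("cop", 8, 6), ("advmod", 8, 7),
        ("prep", 8, 9), ("pobj", 9, 10), ("punct", 8, 11),
    ]
    return (
        [(toks, edges)],
        [(0, 10, 11, "drug")],
        [(0, 2, 3, MentionType.PossessivePronoun)],
    )


def cataphora_conflict_document():
    """Two sentences in which the possessive pronoun licenses both an
    anaphoric pair (with insulin) and a cataphoric pair (with ZEBETA);
    the anaphoric one must be pruned."""
    s1_toks = [
        ("Nonselective", "JJ"), ("beta-blockers", "NNS", "beta-blocker"),
        ("may", "MD"), ("potentiate", "VB"), ("insulin", "NN"),
        ("hypoglycemia", "NN"), (".", "."),
    ]
    s1_edges = [
        ("amod", 1, 0), ("nsubj", 3, 1), ("aux", 3, 2), ("nn", 5, 4),
        ("dobj", 3, 5), ("punct", 3, 6),
    ]
    s2_toks, s2_entities, s2_mentions = connective_cataphora_sentence()
    (toks2, edges2) = s2_toks[0]
    return build_document(
        [(s1_toks, s1_edges), (toks2, edges2)],
        entities=[
            (0, 1, 2, "drug_class"), (0, 4, 5, "substance"),
            (1, 10, 11, "drug"),
        ],
        mentions=[(1, 2, 3, MentionType.PossessivePronoun)],
        links=[(C, 0, [2])],
    )


def out_of_scope_group_document():
    """'Discuss with patients the appropriate action.' / 'They may
    experience chest pain.' — a correct person-group link that the
    drug-substance whitelist must prune."""
    s1 = (
        [
            ("Discuss", "VB"), ("with", "IN"), ("patients", "NNS", "patient"),
            ("the", "DT"), ("appropriate", "JJ"), ("action", "NN"), (".", "."),
        ],
        [
            ("prep", 0, 1), ("pobj", 1, 2), ("dobj", 0, 5), ("det", 5, 3),
            ("amod", 5, 4), ("punct", 0, 6),
        ],
    )
    s2 = (
        [
            ("They", "PRP", "they"), ("may", "MD"), ("experience", "VB"),
            ("chest", "NN"), ("pain", "NN"), (".", "."),
        ],
        [
            ("nsubj", 2, 0), ("aux", 2, 1), ("nn", 4, 3), ("dobj", 2, 4),
            ("punct", 2, 5),
        ],
    )
    return build_document(
        [s1, s2],
        entities=[(0, 2, 3, "Person")],
        mentions=[(1, 0, 1, MentionType.PersonalPronoun)],
    )


def class_exemplification_sentences():
    """'Potassium-sparing diuretics (spironolactone, amiloride, triamterene)
    can increase hyperkalemia risk.' / 'If concomitant use of such agents
    is indicated, monitor potassium.' — the demonstrative NP resolves to
    the class, not the parenthesized instantiations."""
    s1 = (
        [
            ("Potassium-sparing", "JJ"), ("diuretics", "NNS", "diuretic"),
            ("(", "-LRB-"), ("spironolactone", "NN"), (",", ","),
            ("amiloride", "NN"), (",", ","), ("triamterene", "NN"),
            (")", "-RRB-"), ("can", "MD"), ("increase", "VB"),
            ("hyperkalemia", "NN"), ("risk", "NN"), (".", "."),
        ],
        [
            ("amod", 1, 0), ("nsubj", 10, 1), ("punct", 1, 2), ("dep", 1, 3),
            ("punct", 1, 4), ("dep", 1, 5), ("punct", 1, 6), ("dep", 1, 7),
            ("punct", 1, 8), ("aux", 10, 9), ("nn", 12, 11), ("dobj", 10, 12),
            ("punct", 10, 13),
        ],
    )
    s2 = (
        [
            ("If", "IN"), ("concomitant", "JJ"), ("use", "NN"), ("of", "IN"),
            ("such", "JJ"), ("agents", "NNS", "agent"), ("is", "VBZ", "be"),
            ("indicated", "VBN", "indicate"), (",", ","), ("monitor", "VB"),
            ("potassium", "NN"), (".", "."),
        ],
        [
            ("mark", 7, 0), ("amod", 2, 1), ("nsubjpass", 7, 2),
            ("prep", 2, 3), ("pobj", 3, 5), ("amod", 5, 4), ("auxpass", 7, 6),
            ("advcl", 9, 7), ("punct", 9, 8), ("dobj", 9, 10), ("punct", 9, 11),
        ],
    )
    return build_document(
        [s1, s2],
        entities=[
            (0, 0, 2, "drug_class"), (0, 3, 4, "drug"), (0, 5, 6, "drug"),
            (0, 7, 8, "drug"),
        ],
        mentions=[(1, 4, 6, MentionType.DemonstrativeNP)],
        links=[(A, 0, [0])],
    )


def discourse_semantics_sentence():
    """'For patients for whom aspirin is indicated, the aspirin in this
    product may not provide protection.' — the resolver links 'this
    product' to the sentence's first aspirin mention (a documented
    limitation: the ingredient relation is not modelled)."""
    toks = [
        ("For", "IN"), ("patients", "NNS", "patient"), ("for", "IN"),
        ("whom", "WP"), ("aspirin", "NN"), ("is", "VBZ", "be"),
        ("indicated", "VBN", "indicate"), (",", ","), ("the", "DT"),
        ("aspirin", "NN"), ("in", "IN"), ("this", "DT"), ("product", "NN"),
        ("may", "MD"), ("not", "RB"), ("provide", "VB"),
        ("protection", "NN"), (".", "."),
    ]
    edges = [
        ("prep", 15, 0), ("pobj", 0, 1), ("rcmod", 1, 6), ("prep", 6, 2),
        ("pobj", 2, 3), ("nsubjpass", 6, 4), ("auxpass", 6, 5),
        ("punct", 15, 7), ("nsubj", 15, 9), ("det", 9, 8), ("prep", 9, 10),
        ("pobj", 10, 12), ("det", 12, 11), ("aux", 15, 13), ("neg", 15, 14),
        ("dobj", 15, 16), ("punct", 15, 17),
    ]
    return build_document(
        [(toks, edges)],
        entities=[(0, 4, 5, "substance"), (0, 9, 10, "substance")],
        mentions=[(0, 11, 13, MentionType.DemonstrativeNP)],
        links=[(A, 0, [0])],
    )


def parse_salience_sentence():
    """'Start Lotrel therapy under supervision unless a diuretic is added
    or its dose is increased.' — Parse salience prefers the structurally
    closer 'Lotrel therapy'; Default proximity would prefer 'diuretic'."""
    toks = [
        ("Start", "VB"), ("Lotrel", "NN"), ("therapy", "NN"),
        ("under", "IN"), ("supervision", "NN"), ("unless", "IN"),
        ("a", "DT"), ("diuretic", "NN"), ("is", "VBZ", "be"),
        ("added", "VBN", "add"), ("or", "CC"), ("its", "PRP$"),
        ("dose", "NN"), ("is", "VBZ", "be"), ("increased", "VBN", "increase"),
        (".", "."),
    ]
    edges = [
        ("dobj", 0, 2), ("nn", 2, 1), ("prep", 0, 3), ("pobj", 3, 4),
        ("mark", 9, 5), ("det", 7, 6), ("nsubjpass", 9, 7), ("auxpass", 9, 8),
        ("advcl", 0, 9), ("cc", 0, 10), ("conj", 0, 14),
        ("nsubjpass", 14, 12), ("poss", 12, 11), ("auxpass", 14, 13),
        ("punct", 0, 15),
    ]
    return build_document(
        [(toks, edges)],
        entities=[(0, 1, 3, "drug"), (0, 7, 8, "drug_class")],
        mentions=[(0, 11, 12, MentionType.PossessivePronoun)],
        links=[(A, 0, [0])],
    )
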