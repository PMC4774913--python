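"""Configuration loading and the end-to-end resolution engine, including
pruning, chain building and discharge-summary post-processing."""

import json

import pytest

from biocoref import (
    CoreferenceType,
    FixtureSpec,
    MentionType,
    build_chains,
    generate,
    load_configuration,
    postprocess_discharge,
    prune_links,
    resolve_document,
    run_pipeline,
    type_gold_mentions,
)
from biocoref.fixtures import build_document
from biocoref.preprocessing import preprocess
from biocoref.strategy import ConfigError, Configuration
from biocoref.types import Span

import sentence_fixtures as sf


# ------------------------------------------------------------- config


def test_bundled_spl_config_layout(spl_config):
    ctypes = {s.ctype.value for s in spl_config.strategies}
    assert ctypes == {"anaphora", "cataphora", "appositive", "predicate_nominative"}
    pp = next(
        s
        for s in spl_config.strategies
        if s.ctype is CoreferenceType.anaphora
        and MentionType.PersonalPronoun in s.mtypes
    )
    assert pp.mention_filters == ["ThirdPerson", "PleonasticIt"]
    assert [f.name for f in pp.candidate_filters] == [
        "PriorDiscourse", "WindowSize", "SyntacticConfiguration",
        "Default", "Exemplification",
    ]
    assert [str(s) for s in pp.scoring] == [
        "Person(1,0)", "Gender(1,0)", "Animacy(1,0)", "Number(1,0)",
    ]
    assert [s.name for s in pp.postscoring] == ["Threshold", "TopScore", "Salience"]
    assert pp.postscoring[0].parameter == 4
    assert pp.postscoring[2].parameter == "Parse"


def test_config_round_trip(spl_config, discharge_config, protein_config):
    for cfg in (spl_config, discharge_config, protein_config):
        again = load_configuration(cfg.to_dict())
        assert again.to_dict() == cfg.to_dict()


def test_config_typo_rejected(spl_config):
    d = spl_config.to_dict()
    d["strategies"][0]["postscoring"][0] = "Treshold(4)"
    with pytest.raises(ConfigError):
        load_configuration(d)


def test_duplicate_strategy_rejected(spl_config):
    d = spl_config.to_dict()
    d["strategies"].append(d["strategies"][0])
    with pytest.raises(ConfigError, match="duplicate"):
        load_configuration(d)


def test_missing_windowsize_parameter_rejected(spl_config):
    d = spl_config.to_dict()
    d["strategies"][0]["candidate_filters"][1] = "WindowSize"
    with pytest.raises(ConfigError):
        load_configuration(d)


# ------------------------------------------------------------ resolution


def test_document_without_mentions_yields_no_links(spl_config):
    g = build_document(
        [
            (
                [
                    ("Patients", "NNS", "patient"),
                    ("recovered", "VBD", "recover"), (".", "."),
                ],
                [("nsubj", 1, 0), ("punct", 1, 2)],
            )
        ]
    )
    assert resolve_document(g.doc, spl_config) == []


def test_resolution_is_deterministic(spl_config):
    g1 = generate(FixtureSpec(anaphora=4, cataphora=2, appositive=2, seed=17))
    g2 = generate(FixtureSpec(anaphora=4, cataphora=2, appositive=2, seed=17))
    l1 = [l.key() for l in resolve_document(g1.doc, spl_config)]
    l2 = [l.key() for l in resolve_document(g2.doc, spl_config)]
    assert l1 == l2


def test_threshold_failure_produces_no_link(spl_config):
    g = generate(FixtureSpec(anaphora=2, ambiguity="subthreshold", seed=5))
    links = prune_links(resolve_document(g.doc, spl_config), spl_config)
    assert build_chains(links, "pairwise", g.doc) == []


def test_pairwise_split_conserves_conjuncts(spl_config):
    g = generate(FixtureSpec(set_membership=1, seed=8))
    links = prune_links(resolve_document(g.doc, spl_config), spl_config)
    conj_links = [l for l in links if hasattr(l.referent, "conjuncts")]
    assert conj_links
    split = build_chains(conj_links, "pairwise", g.doc)
    assert {l.referent.span for l in split} == {
        c.span for c in conj_links[0].referent.conjuncts
    }


def test_anaphora_cataphora_conflict_pruning(spl_config):
    g = sf.cataphora_conflict_document()
    raw = resolve_document(g.doc, spl_config)
    its = {
        (l.ctype.value, g.doc.slice(l.referent.span))
        for l in raw
        if g.doc.slice(l.mention.span) == "its"
    }
    assert ("anaphora", "insulin") in its and ("cataphora", "ZEBETA") in its
    pruned = prune_links(raw, spl_config)
    its = {
        (l.ctype.value, g.doc.slice(l.referent.span))
        for l in pruned
        if g.doc.slice(l.mention.span) == "its"
    }
    assert its == {("cataphora", "ZEBETA")}


def test_semgroup_whitelist_pruning(spl_config):
    g = sf.out_of_scope_group_document()
    raw = resolve_document(g.doc, spl_config)
    assert any(g.doc.slice(l.referent.span) == "patients" for l in raw)
    assert not any(
        g.doc.slice(l.referent.span) == "patients"
        for l in prune_links(raw, spl_config)
    )


def test_empty_whitelist_disables_pruning(spl_config):
    g = sf.out_of_scope_group_document()
    raw = resolve_document(g.doc, spl_config)
    cfg = load_configuration(spl_config.to_dict())
    cfg.semgroup_whitelist = []
    assert {l.key() for l in prune_links(raw, cfg)} == {
        l.key() for l in raw if not (
            l.ctype is CoreferenceType.anaphora
            and any(
                c.ctype is CoreferenceType.cataphora
                and c.mention.span == l.mention.span
                for c in raw
            )
        )
    }


# --------------------------------------------------------------- chains


def test_cluster_mode_merges_transitively(mixed_fixture, spl_config):
    from biocoref.types import CoreferenceLink, Entity, Mention

    doc = mixed_fixture.doc
    a = Entity(span=Span(0, 8), semtype="drug")
    b = Entity(span=Span(9, 17), semtype="drug")
    c = Entity(span=Span(18, 26), semtype="drug")
    links = [
        CoreferenceLink(CoreferenceType.anaphora, a, b),
        CoreferenceLink(CoreferenceType.anaphora, b, c),
    ]
    doc2 = build_document(
        [
            (
                [("aaaaaaaa", "NN"), ("bbbbbbbb", "NN"), ("cccccccc", "NN"), (".", ".")],
                [("dep", 0, 1), ("dep", 0, 2), ("punct", 0, 3)],
            )
        ]
    ).doc
    chains = build_chains(links, "cluster", doc2)
    assert len(chains) == 1
    assert {m.span for m in chains[0].members} == {a.span, b.span, c.span}


def test_cluster_mode_output_is_a_partition(spl_config):
    g = generate(FixtureSpec(anaphora=5, set_membership=2, seed=23))
    links = prune_links(resolve_document(g.doc, spl_config), spl_config)
    chains = build_chains(links, "cluster", g.doc)
    seen = set()
    for chain in chains:
        for m in chain.members:
            assert m.span not in seen
            seen.add(m.span)


def test_interleaved_mention_absorbed_into_cluster():
    from biocoref.types import CoreferenceLink, Mention

    s = (
        [
            ("propofol", "NN"), ("drip", "NN"), (";", ":"),
            ("drip", "NN"), ("rate", "NN"), (";", ":"),
            ("his", "PRP$"), ("propofol", "NN"), ("drip", "NN"), (".", "."),
        ],
        [
            ("nn", 1, 0), ("punct", 1, 2), ("dep", 1, 3), ("nn", 4, 3),
            ("punct", 1, 5), ("dep", 1, 8), ("poss", 8, 6), ("nn", 8, 7),
            ("punct", 1, 9),
        ],
    )
    g = build_document([s])
    doc = g.doc
    text = doc.text
    m1 = Mention(span=Span(0, 13), mtype=MentionType.ZeroArticleNP, head=(0, 1), semtype="treatment")
    mid = Mention(span=Span(text.index("drip rate"), text.index("drip rate") + 4), mtype=MentionType.ZeroArticleNP, head=(0, 3), semtype="treatment")
    m2 = Mention(span=Span(text.index("his"), len(text.rstrip(" ."))), mtype=MentionType.DefiniteNP, head=(0, 8), semtype="treatment")
    doc.mentions = [m1, mid, m2]
    chains = build_chains(
        [type("L", (), {"ctype": CoreferenceType.anaphora, "mention": m2, "referent": m1})()],
        "cluster",
        doc,
    )
    assert len(chains) == 1
    assert mid.span in {m.span for m in chains[0].members}


# ------------------------------------------------- discharge pipeline


def discharge_doc():
    sents = [
        (
            [("ADMISSION", "NN"), ("MEDICATIONS", "NNS", "medication"), (":", ":")],
            [("nn", 1, 0), ("punct", 1, 2)],
        ),
        (
            [
                ("The", "DT"), ("patient", "NN"), ("was", "VBD", "be"),
                ("started", "VBN", "start"), ("on", "IN"), ("coumadin", "NN"),
                (".", "."),
            ],
            [
                ("det", 1, 0), ("nsubjpass", 3, 1), ("auxpass", 3, 2),
                ("prep", 3, 4), ("pobj", 4, 5), ("punct", 3, 6),
            ],
        ),
        (
            [("DISCHARGE", "NN"), ("MEDICATIONS", "NNS", "medication"), (":", ":")],
            [("nn", 1, 0), ("punct", 1, 2)],
        ),
        (
            [
                ("Continue", "VB"), ("coumadin", "NN"), ("daily", "RB"),
                (".", "."),
            ],
            [("dobj", 0, 1), ("advmod", 0, 2), ("punct", 0, 3)],
        ),
        (
            [
                ("The", "DT"), ("patient", "NN"), ("will", "MD"),
                ("follow", "VB"), ("up", "RP"), (".", "."),
            ],
            [
                ("det", 1, 0), ("nsubj", 3, 1), ("aux", 3, 2), ("prt", 3, 4),
                ("punct", 3, 5),
            ],
        ),
        (
            [
                ("A", "DT"), ("chest", "NN"), ("x-ray", "NN"),
                ("was", "VBD", "be"), ("done", "VBN", "do"), (".", "."),
            ],
            [
                ("det", 2, 0), ("nn", 2, 1), ("nsubjpass", 4, 2),
                ("auxpass", 4, 3), ("punct", 4, 5),
            ],
        ),
    ]
    g = build_document(sents)
    doc = g.doc
    text = doc.text

    def span(sub, start=0):
        i = text.index(sub, start)
        return Span(i, i + len(sub))

    spans = [
        span("The patient"),
        span("coumadin"),
        span("coumadin", text.index("Continue")),
        span("The patient", text.index("DISCHARGE")),
        span("chest x-ray"),
    ]
    semtypes = ["person", "treatment", "treatment", "person", "test"]
    return doc, spans, semtypes


def test_discharge_pipeline_merges_sections_and_drops_singletons(discharge_config):
    doc, spans, semtypes = discharge_doc()
    preprocess(doc, section_mode="discharge")
    mentions = type_gold_mentions(spans, doc, semtypes)
    chains = run_pipeline(doc, discharge_config, mentions=mentions)
    texts = [
        tuple(sorted(doc.slice(m.span) for m in chain.members)) for chain in chains
    ]
    assert ("The patient", "The patient") in texts  # cross-section merge
    assert ("coumadin", "coumadin") in texts
    # the chest x-ray singleton is discarded
    assert all("chest x-ray" not in t for t in texts)


def test_patient_cluster_absorbs_second_person():
    from biocoref.types import Mention

    sents = [
        (
            [
                ("The", "DT"), ("patient", "NN"), ("and", "CC"),
                ("the", "DT"), ("patient", "NN"), ("improved", "VBD", "improve"),
                (".", "."),
            ],
            [
                ("det", 1, 0), ("nsubj", 5, 1), ("cc", 1, 2), ("conj", 1, 4),
                ("det", 4, 3), ("punct", 5, 6),
            ],
        ),
        (
            [
                ("You", "PRP", "you"), ("should", "MD"), ("rest", "VB"),
                (".", "."),
            ],
            [("nsubj", 2, 0), ("aux", 2, 1), ("punct", 2, 3)],
        ),
    ]
    doc = build_document(sents).doc
    text = doc.text
    p1 = Span(text.index("patient"), text.index("patient") + 7)
    p2_start = text.index("patient", p1.end)
    p2 = Span(p2_start, p2_start + 7)
    you = Span(text.index("You"), text.index("You") + 3)
    m1 = Mention(span=p1, mtype=MentionType.ZeroArticleNP, head=(0, 1), semtype="person")
    m2 = Mention(span=p2, mtype=MentionType.ZeroArticleNP, head=(0, 4), semtype="person")
    m3 = Mention(span=you, mtype=MentionType.PersonalPronoun, head=(1, 0), semtype="person")
    from biocoref.types import Chain

    chains = [Chain(members=[m1, m2])]
    out = postprocess_discharge(chains, doc, mentions=[m1, m2, m3])
    assert len(out) == 1
    assert you in {m.span for m in out[0].members}


def test_missing_patient_chain_warns_and_skips():
    from biocoref.types import Mention

    doc = build_document(
        [
            (
                [("You", "PRP", "you"), ("rest", "VBP"), (".", ".")],
                [("nsubj", 1, 0), ("punct", 1, 2)],
            )
        ]
    ).doc
    m = Mention(span=Span(0, 3), mtype=MentionType.PersonalPronoun, head=(0, 0))
    with pytest.warns(UserWarning, match="patient"):
        out = postprocess_discharge([], doc, mentions=[m])
    assert out == []


# ------------------------------------------------------ protein pipeline


def test_relative_pronoun_adjacency_resolution(protein_config):
    s = (
        [
            ("p50", "NN"), (",", ","), ("which", "WDT"),
            ("dimerizes", "VBZ", "dimerize"), (",", ","),
            ("binds", "VBZ", "bind"), ("p65", "NN"), (".", "."),
        ],
        [
            ("punct", 0, 1), ("nsubj", 3, 2), ("rcmod", 0, 3), ("punct", 0, 4),
            ("nsubj", 5, 0), ("dobj", 5, 6), ("punct", 5, 7),
        ],
    )
    g = build_document(
        [s], entities=[(0, 0, 1, "Protein"), (0, 6, 7, "Protein")]
    )
    links = run_pipeline(g.doc, protein_config)
    rel = [
        (g.doc.slice(l.mention.span), g.doc.slice(l.referent.span)) for l in links
    ]
    assert ("which", "p50") in rel


def test_semantic_coercion_resolves_possessive(protein_config):
    sents = [
        (
            [
                ("Nuclear", "JJ"), ("NF-kappaB", "NN"),
                ("was", "VBD", "be"), ("cloned", "VBN", "clone"), (".", "."),
            ],
            [
                ("amod", 1, 0), ("nsubjpass", 3, 1), ("auxpass", 3, 2),
                ("punct", 3, 4),
            ],
        ),
        (
            [
                ("Its", "PRP$", "its"), ("expression", "NN"),
                ("increased", "VBD", "increase"), (".", "."),
            ],
            [("poss", 1, 0), ("nsubj", 2, 1), ("punct", 2, 3)],
        ),
    ]
    g = build_document(sents, entities=[(0, 1, 2, "Protein")])
    links = run_pipeline(g.doc, protein_config)
    pairs = [
        (g.doc.slice(l.mention.span), g.doc.slice(l.referent.span)) for l in links
    ]
    assert ("Its", "NF-kappaB") in pairs
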