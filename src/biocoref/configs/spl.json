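{
  "name": "spl",
  "preprocessing": {
    "transformations": ["SemanticEnrichment", "PPAttachmentCorrection", "ModifierCoordination", "TermCoordination", "Coordination", "NPInternal"],
    "section_mode": "spl",
    "discourse_lists": true
  },
  "postprocessing": {
    "prune_anaphora_cataphora_conflict": true,
    "semgroup_whitelist": ["drug_substance"],
    "chain_mode": "pairwise"
  },
  "strategies": [
    {
      "ctype": "anaphora",
      "mtypes": ["PersonalPronoun"],
      "mention_filters": ["ThirdPerson", "PleonasticIt"],
      "candidate_filters": ["PriorDiscourse", "WindowSize(2)", "SyntacticConfiguration", "Default", "Exemplification"],
      "scoring": ["Person(1,0)", "Gender(1,0)", "Animacy(1,0)", "Number(1,0)"],
      "postscoring": ["Threshold(4)", "TopScore", "Salience(Parse)"]
    },
    {
      "ctype": "anaphora",
      "mtypes": ["PossessivePronoun"],
      "mention_filters": ["ThirdPerson"],
      "candidate_filters": ["PriorDiscourse", "WindowSize(2)", "Default", "Exemplification"],
      "scoring": ["Person(1,0)", "Gender(1,0)", "Animacy(1,0)", "Number(1,0)"],
      "postscoring": ["Threshold(4)", "TopScore", "Salience(Parse)"]
    },
    {
      "ctype": "anaphora",
      "mtypes": ["DistributivePronoun", "ReciprocalPronoun"],
      "mention_filters": [],
      "candidate_filters": ["PriorDiscourse", "WindowSize(2)", "SyntacticConfiguration", "Default", "Exemplification"],
      "scoring": ["Person(1,0)", "Gender(1,0)", "Animacy(1,0)", "Number(1,0)"],
      "postscoring": ["Threshold(4)", "TopScore", "Salience(Default)"]
    },
    {
      "ctype": "anaphora",
      "mtypes": ["DefiniteNP", "DemonstrativeNP", "DistributiveNP"],
      "mention_filters": ["Anaphoricity"],
      "candidate_filters": ["PriorDiscourse", "SyntacticConfiguration", "Default", "Exemplification"],
      "scoring": ["Number(1,1)", "HypernymList(3,0)"],
      "postscoring": ["Threshold(4)", "TopScore", "Salience(Default)"]
    },
    {
      "ctype": "cataphora",
      "mtypes": ["PersonalPronoun"],
      "mention_filters": ["ThirdPerson", "PleonasticIt"],
      "candidate_filters": ["SubsequentDiscourse", "WindowSize(Sentence)", "SyntacticConfiguration", "Default"],
      "scoring": ["Person(1,0)", "Gender(1,0)", "Animacy(1,0)", "Number(1,0)"],
      "postscoring": ["Threshold(4)", "TopScore", "Salience(Default)"]
    },
    {
      "ctype": "cataphora",
      "mtypes": ["PossessivePronoun"],
      "mention_filters": ["ThirdPerson"],
      "candidate_filters": ["SubsequentDiscourse", "WindowSize(Sentence)", "Default"],
      "scoring": ["Person(1,0)", "Gender(1,0)", "Animacy(1,0)", "Number(1,0)", "DiscourseConnective(1,2)"],
      "postscoring": ["Threshold(4)", "TopScore", "Salience(Default)"]
    },
    {
      "ctype": "cataphora",
      "mtypes": ["DefiniteNP"],
      "mention_filters": ["Cataphoricity"],
      "candidate_filters": ["SubsequentDiscourse", "SyntacticConfiguration", "WindowSize(2)", "Default"],
      "scoring": ["Number(1,1)", "HypernymList(3,0)"],
      "postscoring": ["Threshold(4)", "TopScore", "Salience(Default)"]
    },
    {
      "ctype": "appositive",
      "mtypes": ["DefiniteNP", "IndefiniteNP", "ZeroArticleNP"],
      "mention_filters": [],
      "candidate_filters": ["WindowSize(Sentence)", "Default"],
      "scoring": ["Number(1,1)", "SyntacticAppositive(3,2)", "HypernymList(1,1)"],
      "postscoring": ["Threshold(4)", "TopScore", "Salience(Default)"]
    },
    {
      "ctype": "predicate_nominative",
      "mtypes": ["IndefiniteNP", "ZeroArticleNP"],
      "mention_filters": [],
      "candidate_filters": ["PriorDiscourse", "WindowSize(Sentence)", "Default"],
      "scoring": ["Number(1,1)", "SyntacticPredicateNominative(3,2)", "HypernymList(1,1)"],
      "postscoring": ["Threshold(4)", "TopScore", "Salience(Default)"]
    }
  ]
}
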