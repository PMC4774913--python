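{
  "name": "protein",
  "preprocessing": {
    "transformations": ["SemanticEnrichment", "PPAttachmentCorrection", "ModifierCoordination", "TermCoordination", "Coordination", "NPInternal"],
    "section_mode": "none",
    "discourse_lists": false
  },
  "postprocessing": {
    "prune_anaphora_cataphora_conflict": false,
    "semgroup_whitelist": ["protein"],
    "chain_mode": "pairwise"
  },
  "strategies": [
    {
      "ctype": "anaphora",
      "mtypes": ["PersonalPronoun"],
      "mention_filters": ["ThirdPerson", "PleonasticIt"],
      "candidate_filters": ["PriorDiscourse", "WindowSize(2)", "SyntacticConfiguration", "Default"],
      "scoring": ["Person(1,0)", "Gender(1,0)", "Animacy(1,0)", "Number(1,0)"],
      "postscoring": ["Threshold(4)", "TopScore", "Salience(Parse)"]
    },
    {
      "ctype": "anaphora",
      "mtypes": ["PossessivePronoun"],
      "mention_filters": ["ThirdPerson"],
      "candidate_filters": ["PriorDiscourse", "WindowSize(2)", "Default"],
      "scoring": ["Person(1,0)", "Gender(1,0)", "Animacy(1,0)", "Number(1,0)", "SemanticCoercion(1,0)"],
      "postscoring": ["Threshold(4)", "TopScore", "Salience(Parse)"]
    },
    {
      "ctype": "anaphora",
      "mtypes": ["DistributivePronoun", "ReciprocalPronoun"],
      "mention_filters": [],
      "candidate_filters": ["PriorDiscourse", "WindowSize(2)", "SyntacticConfiguration", "Default"],
      "scoring": ["Person(1,0)", "Gender(1,0)", "Animacy(1,0)", "Number(1,0)"],
      "postscoring": ["Threshold(4)", "TopScore", "Salience(Default)"]
    },
    {
      "ctype": "anaphora",
      "mtypes": ["RelativePronoun"],
      "mention_filters": ["CoreferentialPronoun"],
      "candidate_filters": ["PriorDiscourse", "WindowSize(Sentence)", "Default"],
      "scoring": ["Adjacency(1,0)"],
      "postscoring": ["Threshold(1)", "Salience(Default)"]
    },
    {
      "ctype": "anaphora",
      "mtypes": ["DefiniteNP", "DemonstrativeNP", "DistributiveNP"],
      "mention_filters": ["Anaphoricity"],
      "candidate_filters": ["PriorDiscourse", "SyntacticConfiguration", "Default"],
      "scoring": ["Number(1,1)", "HypernymList(3,0)"],
      "postscoring": ["Threshold(4)", "TopScore", "Salience(Default)"]
    }
  ]
}
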