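{
  "name": "discharge",
  "preprocessing": {
    "transformations": ["SemanticEnrichment", "PPAttachmentCorrection", "ModifierCoordination", "TermCoordination", "Coordination", "NPInternal"],
    "section_mode": "discharge",
    "discourse_lists": false
  },
  "postprocessing": {
    "prune_anaphora_cataphora_conflict": false,
    "semgroup_whitelist": [],
    "chain_mode": "cluster",
    "discharge_merge": true
  },
  "strategies": [
    {
      "ctype": "anaphora",
      "mtypes": ["PersonalPronoun", "DistributivePronoun", "ReciprocalPronoun"],
      "mention_filters": [],
      "candidate_filters": ["PriorDiscourse", "WindowSize(Section)", "SyntacticConfiguration", "SemanticClass(entity,mention,conjunction)"],
      "scoring": ["Person(1,0)", "Gender(1,0)", "Animacy(1,0)", "Number(1,0)"],
      "postscoring": ["Threshold(4)", "TopScore", "Salience(Default)"]
    },
    {
      "ctype": "anaphora",
      "mtypes": ["PossessivePronoun"],
      "mention_filters": [],
      "candidate_filters": ["PriorDiscourse", "WindowSize(Section)", "SemanticClass(entity,mention,conjunction)"],
      "scoring": ["Person(1,0)", "Gender(1,0)", "Animacy(1,0)", "Number(1,0)"],
      "postscoring": ["Threshold(4)", "TopScore", "Salience(Default)"]
    },
    {
      "ctype": "anaphora",
      "mtypes": ["RelativePronoun"],
      "mention_filters": [],
      "candidate_filters": ["PriorDiscourse", "WindowSize(Sentence)", "SemanticClass(entity,mention,conjunction)"],
      "scoring": ["Person(1,0)"],
      "postscoring": ["Threshold(1)"]
    },
    {
      "ctype": "anaphora",
      "mtypes": ["DefiniteNP", "DemonstrativeNP", "DistributiveNP"],
      "mention_filters": ["Anaphoricity"],
      "candidate_filters": ["PriorDiscourse", "WindowSize(Section)", "SyntacticConfiguration", "SemanticClass(entity,mention,conjunction)"],
      "scoring": ["Number(1,1)", "SemanticType(2,2)", "HeadWord(2,0)", "ExactString(2,0)", "PreModifierAndHead(2,0)", "RelaxedStem(2,0)"],
      "postscoring": ["Threshold(4)", "TopScore", "Salience(Default)"]
    },
    {
      "ctype": "anaphora",
      "mtypes": ["ZeroArticleNP"],
      "mention_filters": [],
      "candidate_filters": ["PriorDiscourse", "WindowSize(Document)", "SyntacticConfiguration", "SemanticClass(entity,mention,conjunction)"],
      "scoring": ["Number(1,3)", "ExactString(4,0)", "PreModifierAndHead(4,0)", "KeyValuePair(4,0)", "RelaxedStem(3,0)"],
      "postscoring": ["Threshold(4)", "TopScore", "Salience(Default)"]
    },
    {
      "ctype": "appositive",
      "mtypes": ["DefiniteNP", "IndefiniteNP"],
      "mention_filters": [],
      "candidate_filters": ["WindowSize(Sentence)", "SemanticClass(entity,mention,conjunction)"],
      "scoring": ["Number(1,1)", "SyntacticAppositive(3,2)"],
      "postscoring": ["Threshold(4)", "TopScore", "Salience(Default)"]
    }
  ]
}
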