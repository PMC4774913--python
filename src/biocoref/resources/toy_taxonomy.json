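{
  "_comment": "Synthetic toy concept taxonomy (parent -> children) standing in for a full terminology; used by the Taxonomy agreement method in tests and examples.",
  "cardiovascular_agent": ["calcium_channel_blocker", "beta_blocker", "ace_inhibitor", "diuretic"],
  "calcium_channel_blocker": ["amlodipine", "clevidipine", "diltiazem", "verapamil"],
  "beta_blocker": ["metoprolol", "bisoprolol", "atenolol"],
  "ace_inhibitor": ["enalapril", "lisinopril", "benazepril"],
  "diuretic": ["furosemide", "hydrochlorothiazide", "spironolactone"],
  "anticoagulant": ["warfarin", "heparin"]
}
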