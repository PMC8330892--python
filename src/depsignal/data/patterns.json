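{
  "tweet_patterns": {
    "have": "\\bi have {x}depression\\b",
    "developed": "\\bi developed {x}depression\\b",
    "got": "\\bi got {x}depression\\b",
    "suffer": "\\bi suffer from {x}depression\\b",
    "suffered": "\\bi suffered from {x}depression\\b",
    "my": "\\bmy {x}depression\\b",
    "healing": "\\b(?:i['’]m|i am) healing from {x}depression\\b",
    "diagnosed": "\\b(?:i['’]m|i am) diagnosed with {x}depression\\b"
  },
  "description_patterns": {
    "fighter": "\\bdepression fighter\\b",
    "sufferer": "\\bdepression sufferer\\b",
    "survivor": "\\bdepression survivor\\b"
  },
  "modifier_vocabulary": ["severe", "major", "clinical", "chronic"],
  "profession_exclusions": ["practitioner", "counselor", "counsellor", "therapist", "psychiatrist"],
  "topic_exclusions": ["economic depression", "great depression"]
}
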