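{
  "i": ["i", "me", "my", "mine", "myself", "im", "ive"],
  "posemo": ["happy", "love*", "great", "good", "nice", "joy*", "glad", "fun", "amazing", "hope", "hopeful", "excited", "wonderful", "awesome"],
  "negemo": ["bad", "awful", "terrible", "hate*", "worthless", "lonely", "ashamed", "guilt*", "horrible", "worst"],
  "anx": ["anxious", "anxiety", "worri*", "nervous", "afraid", "fear*", "panic*", "scared", "stress*"],
  "anger": ["angry", "anger", "mad", "furious", "rage*", "annoy*", "irritat*", "outrage*"],
  "sad": ["sad*", "unhappy", "cry*", "grief", "gloomy", "hopeless", "miserable", "tear*", "sorrow*"],
  "swear": ["damn", "hell", "crap", "shit*", "fuck*", "bullshit", "wtf"],
  "bio": ["sleep*", "tired", "sick", "eat*", "pain*", "headache*", "body", "blood", "ill", "insomnia", "appetite"],
  "death": ["death", "dead", "die", "died", "dying", "suicid*", "grave", "funeral", "bury", "buried"],
  "power": ["power*", "boss", "control*", "lead", "leader*", "strong", "win", "wins", "winning", "dominat*", "authority"],
  "work": ["work*", "job*", "office", "meeting*", "project*", "deadline*", "salary", "hire*", "business", "career"]
}
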