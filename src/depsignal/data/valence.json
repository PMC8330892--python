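{
  "valences": {
    "happy": 2.7, "love": 3.2, "great": 3.1, "good": 1.9, "nice": 1.8,
    "glad": 2.0, "fun": 2.3, "amazing": 2.8, "hope": 1.9, "hopeful": 2.3,
    "excited": 2.2, "joy": 2.8, "wonderful": 2.7, "awesome": 3.1,
    "best": 3.2, "beautiful": 2.9, "smile": 2.1, "thanks": 1.9,
    "bad": -2.5, "awful": -2.0, "terrible": -2.1, "hate": -2.7,
    "worthless": -2.7, "lonely": -2.2, "ashamed": -2.1, "horrible": -2.5,
    "sad": -2.1, "sadness": -2.1, "unhappy": -1.8, "hopeless": -2.5,
    "miserable": -2.7, "grief": -2.2, "anxious": -1.9, "anxiety": -1.9,
    "worried": -1.7, "nervous": -1.4, "afraid": -2.0, "panic": -2.2,
    "scared": -1.9, "angry": -2.3, "anger": -2.2, "mad": -2.2,
    "furious": -2.6, "rage": -2.5, "annoyed": -1.6, "damn": -1.5,
    "hell": -1.8, "shit": -2.0, "fuck": -2.1, "crap": -1.6,
    "tired": -1.2, "sick": -1.7, "pain": -2.0, "death": -2.6,
    "dead": -2.7, "dying": -2.6, "crying": -1.9, "cry": -1.9,
    "guilty": -1.9, "worst": -3.1
  },
  "boosters": {
    "very": 0.3, "really": 0.3, "so": 0.3, "extremely": 0.4,
    "totally": 0.3, "absolutely": 0.4
  },
  "negators": ["not", "no", "never", "dont", "cant", "wont", "isnt",
               "arent", "didnt", "nothing", "hardly"]
}
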