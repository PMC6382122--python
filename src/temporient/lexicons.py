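"""Packaged word lists: temporal keywords, sentiment polarities, tagger word classes.

The temporal keyword list is a synthetic stand-in for a full temporal
knowledge-base: a compact set of everyday time expressions (deictic adverbs,
calendar units, planning/recollection vocabulary) sufficient to exercise the
keyword feature channel.  Any TSV lexicon with the same sense tags can be
loaded in its place.
"""

from __future__ import annotations

TEMPORAL_SENSES = ("past", "present", "future", "neutral")

# sense tag -> entries (single words or space-separated phrases, all lowercase)
_PAST = [
    "yesterday", "ago", "previously", "earlier", "formerly", "former",
    "once", "lately", "recently", "history", "historic", "memories",
    "memory", "remember", "nostalgia", "nostalgic", "childhood",
    "throwback", "yesteryear", "bygone", "aftermath", "retrospect",
    "last night", "last week", "last month", "last year", "last time",
    "back then", "used to", "the other day", "long ago", "in the past",
]
_PRESENT = [
    "today", "now", "currently", "current", "nowadays", "ongoing",
    "presently", "meanwhile", "live", "happening", "underway",
    "right now", "at the moment", "at present", "this morning",
    "this afternoon", "this evening", "this week", "these days", "as we speak",
]
_FUTURE = [
    "tomorrow", "soon", "upcoming", "later", "eventually", "someday",
    "shortly", "forthcoming", "future", "plan", "plans", "planning",
    "hope", "hopes", "hoping", "dream", "dreams", "goal", "goals",
    "anticipate", "anticipation", "await", "awaiting", "schedule",
    "scheduled", "forecast", "prospect", "intend", "intention", "gonna",
    "countdown", "imminent", "impending", "henceforth",
    "next week", "next month", "next year", "next time", "from now on",
    "in the future", "coming soon", "one day", "before long",
]
_NEUTRAL = [
    "monday", "tuesday", "wednesday", "thursday", "friday", "saturday",
    "sunday", "january", "february", "march", "april", "may", "june",
    "july", "august", "september", "october", "november", "december",
    "spring", "summer", "autumn", "fall", "winter", "morning",
    "afternoon", "evening", "night", "noon", "midnight", "dawn", "dusk",
    "day", "days", "week", "weeks", "month", "months", "year", "years",
    "hour", "hours", "minute", "minutes", "second", "seconds", "decade",
    "century", "era", "season", "weekend", "date", "time", "daily",
    "weekly", "monthly", "yearly", "annual", "anniversary", "birthday",
    "oclock", "midday", "fortnight",
]

DEFAULT_TEMPORAL_LEXICON: dict[str, str] = {}
for _sense, _words in (("past", _PAST), ("present", _PRESENT),
                       ("future", _FUTURE), ("neutral", _NEUTRAL)):
    for _w in _words:
        DEFAULT_TEMPORAL_LEXICON[_w] = _sense


# ---------------------------------------------------------------------------
# Sentiment polarity lexicon (word -> +1 / -1) and negators for the default
# lexicon-based sentiment scorer.
# ---------------------------------------------------------------------------
POSITIVE_WORDS = frozenset({
    "love", "loves", "good", "great", "happy", "happiness", "awesome",
    "amazing", "wonderful", "excellent", "best", "beautiful", "fantastic",
    "nice", "fun", "joy", "joyful", "excited", "exciting", "glad",
    "proud", "brilliant", "perfect", "cool", "sweet", "lovely",
    "favorite", "favourite", "thank", "thanks", "grateful", "blessed",
    "delighted", "pleasant", "superb", "smile", "smiling", "laugh",
    "cheerful", "fabulous",
})
NEGATIVE_WORDS = frozenset({
    "hate", "hates", "bad", "sad", "sadness", "awful", "terrible",
    "horrible", "worst", "angry", "anger", "mad", "upset", "annoyed",
    "annoying", "disappointed", "disappointing", "fear", "afraid",
    "scared", "worried", "worry", "sick", "tired", "hurts", "pain",
    "painful", "cry", "crying", "lonely", "miserable", "disgusting",
    "disgust", "gross", "failure", "sucks", "stupid", "ugly", "boring",
    "bored", "nasty", "dreadful",
})
NEGATORS = frozenset({
    "not", "no", "never", "none", "nothing", "nobody", "neither", "nor",
    "cannot", "cant", "can't", "dont", "don't", "didnt", "didn't",
    "doesnt", "doesn't", "wont", "won't", "isnt", "isn't", "wasnt",
    "wasn't", "werent", "weren't", "aint", "ain't", "hardly", "barely",
    "without",
})

SENTIMENT_POLARITY: dict[str, int] = {w: 1 for w in POSITIVE_WORDS}
SENTIMENT_POLARITY.update({w: -1 for w in NEGATIVE_WORDS})


# ---------------------------------------------------------------------------
# Word classes for the packaged rule-based tagger.
# ---------------------------------------------------------------------------
MODALS = frozenset({
    "will", "would", "can", "could", "shall", "should", "may", "might",
    "must", "wont", "won't", "cant", "can't", "ll", "'ll", "wanna",
})
AUX_BE = frozenset({"am", "is", "are", "was", "were", "be", "been", "being",
                    "isnt", "isn't", "arent", "aren't", "wasnt", "wasn't",
                    "werent", "weren't"})
AUX_HAVE = frozenset({"have", "has", "had", "having", "havent", "haven't",
                      "hasnt", "hasn't", "hadnt", "hadn't"})
AUX_DO = frozenset({"do", "does", "did", "dont", "don't", "doesnt",
                    "doesn't", "didnt", "didn't"})

PRONOUNS = frozenset({
    "i", "me", "my", "mine", "myself", "we", "us", "our", "ours",
    "ourselves", "you", "your", "yours", "yourself", "he", "him", "his",
    "himself", "she", "her", "hers", "herself", "it", "its", "itself",
    "they", "them", "their", "theirs", "themselves", "who", "whom",
    "whose", "which", "what", "someone", "anyone", "everyone", "nobody",
    "something", "anything", "everything",
})
DETERMINERS = frozenset({
    "the", "a", "an", "this", "that", "these", "those", "all", "both",
    "each", "every", "some", "any", "no", "another", "such",
})
PREPOSITIONS = frozenset({
    "of", "in", "on", "at", "by", "for", "with", "about", "against",
    "between", "into", "through", "during", "before", "after", "above",
    "below", "to", "from", "up", "down", "out", "off", "over", "under",
    "near", "since", "until", "till", "upon", "across", "behind",
    "beyond", "within", "without", "along", "around", "toward", "towards",
})
CONJUNCTIONS = frozenset({"and", "but", "or", "so", "yet", "because",
                          "although", "though", "while", "whereas", "if",
                          "unless", "whether", "than", "as", "when", "where"})
COMMON_ADVERBS = frozenset({
    "very", "really", "just", "too", "also", "not", "never", "always",
    "often", "sometimes", "usually", "again", "still", "almost", "quite",
    "rather", "here", "there", "then", "well", "only", "even", "maybe",
    "perhaps", "already", "hard", "fast", "everyday", "away", "legally",
})
INTERJECTIONS = frozenset({"oh", "wow", "hey", "yay", "ugh", "oops", "hmm",
                           "ah", "ha", "haha", "lol", "omg", "yeah", "yes",
                           "please"})

# Base forms of common verbs (used by the suffix rules and base-form rule).
VERB_STEMS = frozenset({
    "accept", "add", "agree", "allow", "announce", "answer", "appear",
    "arrive", "ask", "attend", "avoid", "bake", "be", "beat", "become",
    "begin", "believe", "belong", "bring", "build", "buy", "call",
    "care", "carry", "catch", "cause", "celebrate", "change", "check",
    "choose", "claim", "clean", "climb", "close", "come", "compare",
    "complete", "consider", "continue", "cook", "count", "cover",
    "create", "dance", "decide", "deliver", "describe", "design",
    "develop", "die", "discuss", "do", "draw", "dream", "drink",
    "drive", "drop", "eat", "educate", "end", "enjoy", "enter",
    "expect", "explain", "face", "fail", "fall", "feel", "fight",
    "fill", "find", "finish", "fly", "follow", "forget", "gather",
    "get", "give", "go", "grow", "guess", "handle", "happen", "have",
    "hear", "help", "hit", "hold", "hope", "imagine", "improve",
    "include", "increase", "invite", "join", "jump", "keep", "kick",
    "kill", "know", "land", "laugh", "launch", "lead", "learn",
    "leave", "let", "like", "listen", "live", "look", "lose", "make",
    "manage", "mean", "meet", "mention", "miss", "move", "need",
    "notice", "offer", "open", "order", "paint", "pass", "pay",
    "perform", "pick", "plan", "play", "practice", "prepare", "present",
    "produce", "promise", "protect", "prove", "provide", "pull", "push",
    "put", "raise", "reach", "read", "realize", "receive", "release",
    "remain", "remember", "remind", "remove", "repeat", "reply",
    "report", "rest", "return", "ride", "ring", "rise", "run", "save",
    "say", "see", "seem", "sell", "send", "serve", "set", "share",
    "shine", "shoot", "shop", "show", "sign", "sing", "sit", "sleep",
    "smile", "speak", "spend", "stand", "start", "stay", "stop",
    "study", "succeed", "suggest", "support", "suppose", "take", "talk",
    "teach", "tell", "thank", "think", "throw", "train", "travel",
    "try", "turn", "understand", "use", "visit", "vote", "wait", "wake",
    "walk", "want", "warn", "watch", "wear", "win", "wish", "wonder",
    "work", "worry", "write",
})

# Irregular simple-past forms -> tagged VBD (or VBN after have/be auxiliary).
IRREGULAR_VBD = frozenset({
    "was", "were", "went", "got", "gave", "saw", "came", "took", "told",
    "said", "did", "had", "made", "knew", "thought", "found", "left",
    "felt", "kept", "began", "brought", "bought", "heard", "held",
    "met", "paid", "ran", "rode", "rose", "sang", "sat", "slept",
    "sold", "sent", "shot", "spent", "stood", "spoke", "taught",
    "threw", "understood", "wore", "won", "wrote", "lost", "drove",
    "drank", "drew", "fell", "flew", "forgot", "grew", "hid", "became",
    "broke", "built", "caught", "chose", "dealt", "ate", "fought",
    "fed", "led", "lit", "meant", "rang", "shook", "swam", "swept",
    "tore", "woke",
})
# Irregular past participles distinct from the VBD form.
IRREGULAR_VBN = frozenset({
    "been", "done", "gone", "seen", "taken", "given", "known", "thrown",
    "written", "spoken", "broken", "chosen", "driven", "eaten",
    "fallen", "flown", "forgotten", "gotten", "grown", "hidden",
    "ridden", "risen", "shaken", "stolen", "sworn", "torn", "woken",
    "drunk", "sung", "swum", "begun",
})
# 3rd-person singular irregulars not derivable by stripping -s.
IRREGULAR_VBZ = frozenset({"goes", "does", "has", "is", "says", "flies",
                           "tries", "carries", "studies", "watches",
                           "catches", "teaches", "reaches", "wishes",
                           "misses", "passes", "fixes"})
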