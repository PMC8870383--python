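[
  {
    "id": "SVA_3SG_BASE",
    "pattern": "\\b(he|she|it) (go|want|see|take|wash|steal|fall|dry|do|run|stand|reach|look|make|eat|drink|sit|climb|grab)\\b",
    "description": "third-person singular pronoun followed by a base-form verb (subject-verb agreement)"
  },
  {
    "id": "ART_DUP",
    "pattern": "\\b(a|an|the) \\1\\b",
    "description": "immediately duplicated article"
  },
  {
    "id": "MISSING_DET",
    "pattern": "\\b(is|was) (boy|girl|woman|stool|sink|cookie|jar|plate|window|counter|curtain|faucet|floor|kitchen|cabinet)\\b",
    "description": "copula directly before a bare singular count noun (missing determiner)"
  }
]
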