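{
  "children stealing cookies": [
    "children stealing cookies",
    "the children are stealing the cookies",
    "the kids are taking cookies from the jar",
    "two children stealing some cookies"
  ],
  "woman doing dishes": [
    "woman doing dishes",
    "the woman is doing the dishes",
    "a mother washing dishes at the sink",
    "the lady is washing the dishes"
  ],
  "girl reaching for a cookie": [
    "girl reaching for a cookie",
    "the girl is reaching for a cookie",
    "the little girl reaches up for a cookie",
    "a girl asking for a cookie"
  ],
  "woman not noticing": [
    "woman not noticing",
    "the woman does not notice",
    "the mother is not paying attention",
    "she does not see the children"
  ],
  "boy on stool": [
    "boy on stool",
    "the boy is standing on a stool",
    "a boy climbs on the stool",
    "the boy is up on a wobbling stool"
  ],
  "sink overflowing": [
    "sink overflowing",
    "the sink is overflowing",
    "water is spilling over the sink",
    "the water is running over onto the floor"
  ],
  "stool falling": [
    "stool falling",
    "the stool is falling over",
    "the stool is tipping over",
    "the stool is about to fall"
  ]
}
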