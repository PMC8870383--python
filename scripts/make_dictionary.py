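"""One-off generator for src/cookietalk/data/dictionary.txt.

Builds a compact English lexicon: closed-class words, irregular forms,
regularly inflected common verb/noun/adjective stems, and the full
cookie-theft domain vocabulary. Asserts that every word used by the
package's bundled templates, filler lexicon, keyword list and main ideas
is covered.
"""
import json
import re
from pathlib import Path

DATA = Path(__file__).resolve().parents[1] / "src" / "cookietalk" / "data"

VOWELS = "aeiou"


def verb_forms(stem: str) -> set[str]:
    out = {stem}
    # 3sg -s
    if re.search(r"(s|x|z|ch|sh|o)$", stem):
        out.add(stem + "es")
    elif re.search(r"[^aeiou]y$", stem):
        out.add(stem[:-1] + "ies")
    else:
        out.add(stem + "s")
    # -ing / -ed
    if stem.endswith("e") and not stem.endswith("ee"):
        base = stem[:-1]
        out.add(base + "ing")
        out.add(stem + "d")
    elif re.search(r"[^aeiou][aeiou][^aeiouwxy]$", stem) and len(stem) <= 5:
        out.add(stem + stem[-1] + "ing")
        out.add(stem + stem[-1] + "ed")
    elif re.search(r"[^aeiou]y$", stem):
        out.add(stem + "ing")
        out.add(stem[:-1] + "ied")
    else:
        out.add(stem + "ing")
        out.add(stem + "ed")
    return out


def noun_forms(stem: str) -> set[str]:
    out = {stem}
    if re.search(r"(s|x|z|ch|sh)$", stem):
        out.add(stem + "es")
    elif re.search(r"[^aeiou]y$", stem):
        out.add(stem[:-1] + "ies")
    else:
        out.add(stem + "s")
    return out


CLOSED = """
a an the and or but if then than because so as of in on at by for with
without to from into onto over under above below behind beside near
around about across after before during between among up down out off
he she it they we you i me him her them us my your his its their our
mine yours hers theirs ours this that these those there here where when
while who whom whose which what why how not no nor all some any none
both each every either neither few many much more most other another
such only own same just also very too quite really almost always never
often sometimes usually perhaps maybe probably certainly apparently
again once twice first second third next last now soon yet still
is are was were be been being am do does did done doing have has had
having will would shall should can could may might must let
one two three four five six seven eight nine ten
yes okay oh well right
i'm it's that's there's he's she's they're we're you're don't doesn't
didn't can't couldn't won't wouldn't isn't aren't wasn't weren't
""".split()

IRREGULAR = """
child children man men woman women person people foot feet tooth teeth
mouse mice knife knives leaf leaves shelf shelves wife wives life lives
go goes went gone going get gets got gotten getting
take takes took taken taking see sees saw seen seeing
give gives gave given giving come comes came coming
run runs ran running stand stands stood standing
fall falls fell fallen falling make makes made making
say says said saying tell tells told telling
think thinks thought thinking know knows knew known knowing
find finds found finding put puts putting sit sits sat sitting
eat eats ate eaten eating drink drinks drank drunk drinking
begin begins began begun beginning break breaks broke broken breaking
bring brings brought bringing buy buys bought buying
catch catches caught catching hold holds held holding
keep keeps kept keeping leave leaves left leaving
lose loses lost losing mean means meant meaning
read reads reading say speak speaks spoke spoken speaking
teach teaches taught teaching wear wears wore worn wearing
write writes wrote written writing forget forgets forgot forgotten
forgetting grow grows grew grown growing hear hears heard hearing
hide hides hid hidden hiding rise rises rose risen rising
slip slips slipped slipping tip tips tipped tipping
""".split()

VERB_STEMS = """
steal reach wash dry notice look watch want ask talk walk play work
help open close start stop finish try use move turn pull push lift
carry clean cook bake pour spill drop pick hand point smile laugh cry
wobble tumble climb hurry worry seem appear happen stay wait live like
love need call answer wipe rinse scrub soak drain fill empty overflow
splash drip flow slide lean balance topple grab snatch pass share
remember describe explain show name count miss thank pay
""".split()

NOUN_STEMS = """
boy girl mother father sister brother kid lady baby family
kitchen window cabinet cookie counter curtain dish faucet floor jar
plate sink stool water cup glass bowl spoon towel apron sponge soap
table chair door wall room house home garden yard grass tree path road
day summer weather breeze air light shadow picture scene image action
story moment trouble mess noise care thought mind hand arm leg foot
head face eye ear mouth hair shoe dress shirt pocket step ladder
edge side front back top bottom middle corner part thing word sentence
task test score time year minute hour attention lady
""".split()

ADJ_STEMS = """
nice sunny busy quiet small big tall short old young little long wide
open closed full empty wet dry clean dirty happy sad calm upset hungry
tired careful careless unsteady steady unstable high low warm cool
left right near far good bad fine ready late early wrong whole
unconcerned indifferent oblivious unaware
""".split()

ADVERBS = """
outside inside upstairs downstairs away nearby meanwhile instead
quickly slowly quietly carefully suddenly finally actually obviously
something everything nothing anything someone everyone somebody
""".split()

KEYWORDS = (DATA / "keywords.txt").read_text().split()

words: set[str] = set(CLOSED) | set(IRREGULAR) | set(ADVERBS) | set(KEYWORDS)
for s in VERB_STEMS:
    words |= verb_forms(s)
for s in NOUN_STEMS:
    words |= noun_forms(s)
for s in ADJ_STEMS:
    words.add(s)
    words.add(s + "ly") if s.endswith("l") is False and len(s) > 4 else None

words = {w for w in words if w}

# coverage checks against the other bundled resources
used: set[str] = set(KEYWORDS)
used |= set((DATA / "ideas.txt").read_text().split())
used |= set((DATA / "ground_truth.txt").read_text().split())
used |= set((DATA / "filler_lexicon.txt").read_text().split())
templates = json.loads((DATA / "templates.json").read_text())
for variants in templates.values():
    for t in variants:
        used |= set(t.split())
used |= {"and", "he", "go"}  # grammar-error injection tokens
missing = sorted(used - words)
assert not missing, f"dictionary missing: {missing}"

out = DATA / "dictionary.txt"
out.write_text("\n".join(sorted(words)) + "\n")
print(f"{len(words)} words -> {out} ({out.stat().st_size} bytes)")
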