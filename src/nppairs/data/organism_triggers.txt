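# Trigger lexicon for the clean/dirty organism-field classifier.
# A raw organism string containing any of these tokens (case-insensitive,
# word-bounded) is classified "dirty": it carries text beyond a bare
# scientific name (organ words, isolation phrases, abbreviations, localities).
# One token per line; '#' starts a comment.
isolated from
obtained from
purified from
extract
extracts
leaf
leaves
bark
stem
stems
root
roots
rhizome
rhizomes
seed
seeds
fruit
fruits
flower
flowers
aerial
aerial parts
wood
heartwood
twig
twigs
branch
branches
tuber
tubers
bulb
whole plant
herb
peel
pericarp
husk
kernel
needle
needles
cone
mycelium
fruiting body
fruiting bodies
culture
culture broth
broth
fermentation
marine
soil
sponge
collected
fresh
dried
spp.
sp.
cf.
aff.
var.
ex
and
of
the
from
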