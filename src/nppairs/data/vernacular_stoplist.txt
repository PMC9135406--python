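# Unspecific vernacular / TCM names excluded from translation dictionaries.
# One name per line, case-insensitive; '#' starts a comment.
fish
tree
bush
herb
grass
berry
fern
moss
vine
weed
fungus
mushroom
seaweed
coral
worm
shell
algae
flower
fruit
root
bean
nut
corn
rice plant
medicinal herb
bitter herb
sweet herb
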