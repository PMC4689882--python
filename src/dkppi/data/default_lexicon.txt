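# Default interaction-keyword lexicon.
# One word per line; entries are Porter-stemmed and lowercased at load time,
# so inflected surface forms may be listed. Sections:
#   [keywords]     full trigger-word set (superset of iverb/inoun/second)
#   [iverb]        interaction verbs used by the structure patterns
#   [inoun]        interaction nouns used by the structure patterns
#   [second]       the seven high-salience second keywords
#   [negative]     negation cues
#   [conjunctive]  the sixteen conjunctive-relation words
#   [condition]    assumption/condition cues
#   [prepositions] closed preposition set

[keywords]
active
depend
drive
driven
dependence
known
crosstalk
affinity
ligand
substrate
effector
agonist
antagonist
cofactor
coactivator
corepressor
adaptor
anchor
assemble
assembly
abolish
accelerate
accumulate
acetylate
acetylation
activate
activation
adhere
adhesion
antagonize
associate
association
attach
attachment
attenuate
augment
bind
binding
block
blockade
catalyze
catalysis
cleave
cleavage
colocalize
colocalization
communicate
communication
compete
competition
complex
conjugate
conjugation
connect
connection
contact
control
cooperate
cooperation
coordinate
coprecipitate
coimmunoprecipitate
couple
coupling
crosslink
deacetylate
deacetylation
degrade
degradation
demethylate
dephosphorylate
dephosphorylation
destabilize
dimerize
dimerization
disassemble
displace
disrupt
disruption
dissociate
dissociation
downregulate
downregulation
elevate
eliminate
enhance
enhancement
facilitate
form
formation
fuse
fusion
glycosylate
glycosylation
heterodimerize
homodimerize
hydrolyze
hydrolysis
impair
inactivate
inactivation
induce
induces
induction
influence
inhibit
inhibition
initiate
interact
interaction
interfere
interference
ligate
ligation
link
linkage
localize
localization
mediate
mediation
methylate
methylation
modify
modification
modulate
modulation
multimerize
neutralize
oligomerize
oligomerization
overexpress
phosphorylate
phosphorylation
polymerize
polymerization
potentiate
precipitate
prevent
promote
promotion
react
reaction
recognize
recognition
recruit
recruitment
reduce
reduction
regulate
regulation
release
repress
repression
require
requirement
sequester
sequestration
stabilize
stabilization
stimulate
stimulation
substitute
sumoylate
sumoylation
suppress
suppression
synergize
synergy
target
tether
transactivate
transactivation
transduce
transduction
transform
transformation
translocate
translocation
transphosphorylate
trigger
ubiquitinate
ubiquitination
upregulate
upregulation

[iverb]
abolish
drive
driven
accelerate
acetylate
activate
adhere
antagonize
assemble
associate
attach
attenuate
augment
bind
block
catalyze
cleave
colocalize
communicate
compete
conjugate
connect
contact
control
cooperate
coordinate
coprecipitate
coimmunoprecipitate
couple
crosslink
deacetylate
degrade
demethylate
dephosphorylate
destabilize
dimerize
disassemble
displace
disrupt
dissociate
downregulate
elevate
eliminate
enhance
facilitate
form
fuse
glycosylate
heterodimerize
homodimerize
hydrolyze
impair
inactivate
induce
influence
inhibit
initiate
interact
interfere
ligate
link
localize
mediate
methylate
modify
modulate
multimerize
neutralize
oligomerize
overexpress
phosphorylate
polymerize
potentiate
precipitate
prevent
promote
react
recognize
recruit
reduce
regulate
release
repress
require
sequester
stabilize
stimulate
substitute
sumoylate
suppress
synergize
target
tether
transactivate
transduce
transform
translocate
transphosphorylate
trigger
ubiquitinate
upregulate

[inoun]
acetylation
activation
adhesion
assembly
association
attachment
binding
blockade
catalysis
cleavage
colocalization
communication
competition
complex
conjugation
connection
cooperation
coupling
crosstalk
deacetylation
degradation
dephosphorylation
dimerization
disruption
dissociation
downregulation
enhancement
formation
fusion
glycosylation
hydrolysis
inactivation
induction
inhibition
interaction
interference
ligation
linkage
localization
mediation
methylation
modification
modulation
oligomerization
phosphorylation
polymerization
promotion
reaction
recognition
recruitment
reduction
regulation
repression
requirement
sequestration
stabilization
stimulation
sumoylation
suppression
synergy
transactivation
transduction
transformation
translocation
ubiquitination
upregulation

[second]
bind
interact
regulate
induce
stimulate
associate
known

[negative]
not
no
never
neither
nor
cannot
unable
incapable
fail
fails
failed
lack
lacks
without
absence

[conjunctive]
where
when
what
why
how
as
though
although
because
so
therefore
hence
since
wherein
whereas
whereby

[condition]
if
whether

[prepositions]
about
above
across
after
against
along
among
around
at
before
behind
below
beneath
beside
between
beyond
by
despite
down
during
for
from
in
inside
into
near
of
off
on
onto
out
outside
over
past
per
since
through
throughout
to
toward
towards
under
underneath
until
upon
via
with
within
without
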