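a
about
above
across
action
actions
actually
after
again
air
airs
all
almost
also
always
am
among
an
and
another
answer
answered
answering
answers
any
anything
apparently
appear
appeared
appearing
appears
apron
aprons
are
aren't
arm
arms
around
as
ask
asked
asking
asks
at
ate
attention
attentions
away
babies
baby
back
backs
bad
bake
baked
bakes
baking
balance
balanced
balances
balancing
be
because
been
before
began
begin
beginning
begins
begun
behind
being
below
beside
between
big
both
bottom
bottoms
bought
bowl
bowls
boy
boys
break
breaking
breaks
breeze
breezes
bring
bringing
brings
broke
broken
brother
brothers
brought
busy
but
buy
buying
buys
by
cabinet
cabinets
call
called
calling
calls
calm
came
can
can't
care
careful
carefully
careless
carelessly
cares
carried
carries
carry
carrying
catch
catches
catching
caught
certainly
chair
chairs
child
children
clean
cleaned
cleaning
cleanly
cleans
climb
climbed
climbing
climbs
close
closed
closedly
closes
closing
come
comes
coming
cook
cooked
cookie
cookies
cooking
cooks
cool
corner
corners
could
couldn't
count
counted
counter
counters
counting
counts
cried
cries
cry
crying
cup
cups
curtain
curtains
day
days
describe
described
describes
describing
did
didn't
dirty
dirtyly
dish
dishes
do
does
doesn't
doing
don't
done
door
doors
down
downstairs
drain
drained
draining
drains
drank
dress
dresses
dried
dries
drink
drinking
drinks
drip
dripped
dripping
drips
drop
dropped
dropping
drops
drunk
dry
drying
during
each
ear
early
earlyly
ears
eat
eaten
eating
eats
edge
edges
eight
either
emptied
empties
empty
emptying
emptyly
every
everyone
everything
explain
explained
explaining
explains
eye
eyes
face
faces
fall
fallen
falling
falls
families
family
far
father
fathers
faucet
faucets
feet
fell
few
fill
filled
filling
fills
finally
find
finding
finds
fine
finish
finished
finishes
finishing
first
five
floor
floors
flow
flowed
flowing
flows
foot
foots
for
forget
forgets
forgetting
forgot
forgotten
found
four
from
front
fronts
full
garden
gardens
gave
get
gets
getting
girl
girls
give
given
gives
giving
glass
glasses
go
goes
going
gone
good
got
gotten
grab
grabbed
grabbing
grabs
grass
grasses
grew
grow
growing
grown
grows
had
hair
hairs
hand
handed
handing
hands
happen
happened
happening
happens
happy
happyly
has
have
having
he
he's
head
heads
hear
heard
hearing
hears
held
help
helped
helping
helps
her
here
hers
hid
hidden
hide
hides
hiding
high
him
his
hold
holding
holds
home
homes
hour
hours
house
houses
how
hungry
hungryly
hurried
hurries
hurry
hurrying
i
i'm
if
image
images
in
indifferent
indifferently
inside
instead
into
is
isn't
it
it's
its
jar
jars
just
keep
keeping
keeps
kept
kid
kids
kitchen
kitchens
knew
knife
knives
know
knowing
known
knows
ladder
ladders
ladies
lady
last
late
laugh
laughed
laughing
laughs
leaf
lean
leaned
leaning
leans
leave
leaves
leaving
left
leg
legs
let
life
lift
lifted
lifting
lifts
light
lights
like
liked
likes
liking
little
littlely
live
lived
lives
living
long
look
looked
looking
looks
lose
loses
losing
lost
love
loved
loves
loving
low
made
make
makes
making
man
many
may
maybe
me
mean
meaning
means
meant
meanwhile
men
mess
messes
mice
middle
middles
might
mind
minds
mine
minute
minutes
miss
missed
misses
missing
moment
moments
more
most
mother
mothers
mouse
mouth
mouths
move
moved
moves
moving
much
must
my
name
named
names
naming
near
nearby
need
needed
needing
needs
neither
never
next
nice
nine
no
noise
noises
none
nor
not
nothing
notice
noticed
notices
noticing
now
oblivious
obliviously
obviously
of
off
often
oh
okay
old
on
once
one
only
onto
open
openned
openning
opens
or
other
our
ours
out
outside
over
overflow
overflowed
overflowing
overflows
own
part
parts
pass
passed
passes
passing
path
paths
pay
payed
paying
pays
people
perhaps
person
pick
picked
picking
picks
picture
pictures
plate
plates
play
played
playing
plays
pocket
pockets
point
pointed
pointing
points
pour
poured
pouring
pours
probably
pull
pulled
pulling
pulls
push
pushed
pushes
pushing
put
puts
putting
quickly
quiet
quietly
quite
ran
reach
reached
reaches
reaching
read
reading
reads
ready
readyly
really
remember
remembered
remembering
remembers
right
rightly
rinse
rinsed
rinses
rinsing
rise
risen
rises
rising
road
roads
room
rooms
rose
run
running
runs
sad
said
same
sat
saw
say
saying
says
scene
scenes
score
scores
scrub
scrubbed
scrubbing
scrubs
second
see
seeing
seem
seemed
seeming
seems
seen
sees
sentence
sentences
seven
shadow
shadows
shall
share
shared
shares
sharing
she
she's
shelf
shelves
shirt
shirts
shoe
shoes
short
shortly
should
show
showed
showing
shows
side
sides
sink
sinks
sister
sisters
sit
sits
sitting
six
slide
slided
slides
sliding
slip
slipped
slipping
slips
slowly
small
smile
smiled
smiles
smiling
snatch
snatched
snatches
snatching
so
soak
soaked
soaking
soaks
soap
soaps
some
somebody
someone
something
sometimes
soon
speak
speaking
speaks
spill
spilled
spilling
spills
splash
splashed
splashes
splashing
spoke
spoken
sponge
sponges
spoon
spoons
stand
standing
stands
start
started
starting
starts
stay
stayed
staying
stays
steady
steadyly
steal
stealed
stealing
steals
step
steps
still
stood
stool
stools
stop
stopped
stopping
stops
stories
story
such
suddenly
summer
summers
sunny
sunnyly
table
tables
take
taken
takes
taking
talk
talked
talking
talks
tall
task
tasks
taught
teach
teaches
teaching
teeth
tell
telling
tells
ten
test
tests
than
thank
thanked
thanking
thanks
that
that's
the
their
theirs
them
then
there
there's
these
they
they're
thing
things
think
thinking
thinks
third
this
those
thought
thoughts
three
time
times
tip
tipped
tipping
tips
tired
tiredly
to
told
too
took
tooth
top
topple
toppled
topples
toppling
tops
towel
towels
tree
trees
tried
tries
trouble
troubles
try
trying
tumble
tumbled
tumbles
tumbling
turn
turned
turning
turns
twice
two
unaware
unawarely
unconcerned
unconcernedly
under
unstable
unstablely
unsteady
unsteadyly
up
upset
upsetly
upstairs
us
use
used
uses
using
usually
very
wait
waited
waiting
waits
walk
walked
walking
walks
wall
walls
want
wanted
wanting
wants
warm
was
wash
washed
washes
washing
wasn't
watch
watched
watches
watching
water
waters
we
we're
wear
wearing
wears
weather
weathers
well
went
were
weren't
wet
what
when
where
which
while
who
whole
wholely
whom
whose
why
wide
wife
will
window
windows
wipe
wiped
wipes
wiping
with
without
wives
wobble
wobbled
wobbles
wobbling
woman
women
won't
word
words
wore
work
worked
working
works
worn
worried
worries
worry
worrying
would
wouldn't
write
writes
writing
written
wrong
wrongly
wrote
yard
yards
year
years
yes
yet
you
you're
young
youngly
your
yours
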