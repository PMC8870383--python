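there
here
outside
inside
house
home
garden
summer
day
nice
sunny
very
really
quite
just
then
now
well
also
maybe
something
everything
nothing
happening
going
looking
seems
appears
picture
scene
action
busy
quiet
open
closed
small
big
tall
short
old
young
left
right
side
near
beside
behind
front
back
above
below
around
while
because
probably
perhaps
certainly
apparently
almost
always
never
often
sometimes
table
chair
room
door
wall
yard
grass
tree
path
road
weather
breeze
light
shadow
cup
glass
towel
apron
shoe
dress
shirt
hand
arm
foot
head
face
smile
moment
trouble
mess
noise
hurry
care
thought
mind
story
quickly
slowly
carefully
suddenly
finally
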