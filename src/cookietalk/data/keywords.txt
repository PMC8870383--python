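boy
jar
overflowing
girl
plate
spilling
woman
sink
asking
kitchen
stool
unconcerned
window
water
indifferent
cabinet
taking
stealing
cookies
cookie
wobbling
counter
falling
handing
curtain
drying
mother
dishes
washing
sister
faucet
doing
brother
floor
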