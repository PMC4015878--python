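activate
accelerate
exert
extend
increase
rise
peak
drastically
rapidly
positive
promote
enhance
assist
acetylase inhibit
block
deacetylase
prevent
suppress
abolish
reduce
decrease
degrade
compromise
sustain
alleviate
decline
lower
negative
repress
diminish
limit
fail
lack
delay
late
slow
shut down
less effect
turn off
rate change
affect rate
alter
over period
during period
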