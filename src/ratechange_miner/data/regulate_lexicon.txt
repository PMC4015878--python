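regulate
control
express
induce
repress
activate
inhibit
suppress
bind
promote
mediate
modulate
transcription
affect
stimulate
interact
encode
require
target
signal
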