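regulate	regulation	regulates	regulated	regulating	regulatory
express	expression	expressed	expresses	expressing
repress	repression	repressed	represses	repressing	repressor
induce	induction	induced	induces	inducing	inducible
activate	activation	activated	activates	activating	activator
inhibit	inhibition	inhibited	inhibits	inhibiting	inhibitor
suppress	suppression	suppressed	suppresses	suppressing
bind	binding	binds	bound
promote	promoted	promotes	promoting
mediate	mediated	mediates	mediating
modulate	modulated	modulates	modulating
transcription	transcriptional	transcribe	transcribed	transcribes	transcript	transcripts
translation	translational	translate	translated	translates
degrade	degradation	degraded	degrades	degrading
slow	slowed	slows	slowing	slowly
delay	delayed	delays	delaying
prevent	prevented	prevents	preventing	prevention
increase	increased	increases	increasing
decrease	decreased	decreases	decreasing
reduce	reduced	reduces	reducing	reduction
enhance	enhanced	enhances	enhancing
rise	rising	rose	risen
rapid	rapidly
extend	extended	extends	extending	extension
block	blocked	blocks	blocking
abolish	abolished	abolishes	abolishing
decline	declined	declines	declining
lower	lowered	lowers	lowering
diminish	diminished	diminishes	diminishing
limit	limited	limits	limiting
fail	failed	fails	failing	failure
lack	lacked	lacking	lacks
alter	altered	alters	altering	alteration
affect	affected	affects	affecting
accelerate	accelerated	accelerates	accelerating	acceleration
peak	peaked	peaks	peaking
exert	exerted	exerts	exerting
sustain	sustained	sustains	sustaining
compromise	compromised	compromises
alleviate	alleviated	alleviates
ubiquitinate	ubiquitination	ubiquitylation	ubiquitinated	ubiquitylated	ubiquitylates	ubiquitinates
methylate	methylation	dimethylation	methylated	dimethylated	trimethylation
acetylate	acetylation	acetylated	acetylates
mrna	mrnas
reinforce	reinforced	reinforces	reinforcing
disappear	disappearance	disappeared
mutate	mutation	mutant	mutants	mutations
segregate	segregation	segregated
arrest	arrested	arrests
elevate	elevated	elevates	elevating
assist	assisted	assists	assisting
stimulate	stimulated	stimulates	stimulation
interact	interaction	interacts	interacting	interactions
encode	encoded	encodes	encoding
require	required	requires	requiring
target	targeted	targets	targeting
signal	signaling	signalling	signals
turn	turned	turns	turning
shut	shuts
control	controlled	controls	controlling
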