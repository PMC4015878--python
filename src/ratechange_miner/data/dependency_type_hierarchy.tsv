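nsubj	subj
nsubjpass	subj
csubj	subj
csubjpass	subj
xsubj	subj
dobj	obj
iobj	obj
pobj	obj
ccomp	comp
xcomp	comp
acomp	comp
pcomp	comp
amod	mod
advmod	mod
appos	mod
nn	mod
nmod	mod
num	mod
number	mod
poss	mod
possessive	mod
prep	mod
prt	mod
det	mod
predet	mod
preconj	mod
quantmod	mod
partmod	mod
infmod	mod
rcmod	mod
tmod	mod
advcl	mod
purpcl	mod
neg	mod
aux	aux
auxpass	aux
cop	aux
conj	conj
cc	conj
mark	mark
complm	mark
rel	rel
ref	ref
expl	expl
parataxis	parataxis
punct	punct
root	root
dep	dep
agent	agent
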