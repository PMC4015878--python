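Quicken	activate
Quicken	accelerate
Quicken	exert
Quicken	extend
Quicken	increase
Quicken	rise
Quicken	peak
Quicken	drastically
Quicken	rapidly
Quicken	positive
Quicken	promote
Quicken	enhance
Quicken	assist
Quicken	acetylase inhibit
Delay	block
Delay	deacetylase
Delay	prevent
Delay	suppress
Delay	abolish
Delay	reduce
Delay	decrease
Delay	degrade
Delay	compromise
Delay	sustain
Delay	alleviate
Delay	decline
Delay	lower
Delay	negative
Delay	repress
Delay	diminish
Delay	limit
Delay	fail
Delay	lack
Delay	delay
Delay	late
Delay	slow
Delay	shut down
Delay	less effect
Delay	turn off
Change	rate change
Change	affect rate
Change	alter
Change	over period
Change	during period
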