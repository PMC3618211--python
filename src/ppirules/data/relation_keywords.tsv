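activate	Activation
increase	Activation
induce	Activation
initiate	Activation
stimulate	Activation
promote	Activation
catalyze	Activation
up-regulate	Activation
coactivate	Activation
potentiate	Activation
precipitate	Activation
reactivate	Activation
block	Deactivation
decrease	Deactivation
down-regulate	Deactivation
inactivate	Deactivation
inhibit	Deactivation
reduce	Deactivation
repress	Deactivation
suppress	Deactivation
interfere	Deactivation
antagonize	Deactivation
degrade	Deactivation
obstruct	Deactivation
associate	Creating bond
link	Creating bond
dimerize	Creating bond
heterodimerize	Creating bond
crystalize	Creating bond
methylate	Creating bond
phosphorylate	Creating bond
assemble	Creating bond
polymerize	Creating bond
bound	Creating bond
bond	Creating bond
oligomerize	Creating bond
glycosylate	Creating bond
bind	Creating bond
complex	Creating bond
form	Creating bond
conjugate	Creating bond
acetylate	Creating bond
couple	Creating bond
cleave	Breaking bond
demethylate	Breaking bond
dephosphorylate	Breaking bond
sever	Breaking bond
unbind	Breaking bond
depolymerize	Breaking bond
dissociate	Breaking bond
deacetylate	Breaking bond
deglycosilate	Breaking bond
disassemble	Breaking bond
mediate	Signaling
modulate	Signaling
participate	Signaling
regulate	Signaling
control	Signaling
interact	Signaling
react	Signaling
contact	Signaling
response	Signaling
encode	Signaling
recognize	Signaling
stabilize	Signaling
destabilize	Signaling
target	Signaling
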