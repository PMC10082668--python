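#t_s=0.92
#d_f=0.11
#FeatureID	NeighborID	Similarity
MK1	RL1	0.968698
MK2	RL2	0.951944
RL1	MK1	0.968698
RL2	MK2	0.951944
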