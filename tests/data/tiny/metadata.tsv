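SampleID	Group
A01	A
A02	A
A03	A
A04	A
B01	B
B02	B
B03	B
B04	B
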