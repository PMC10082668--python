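# feature_id -> lineage
BG001	k__Bacteria;p__P1;c__C1;o__O0;f__F0;g__G0;s__bg0
BG002	k__Bacteria;p__P2;c__C2;o__O1;f__F1;g__G1;s__bg1
BG003	k__Bacteria;p__P3;c__C3;o__O2;f__F2;g__G2;s__bg2
BG004	k__Bacteria;p__P4;c__C4;o__O3;f__F3;g__G3;s__bg3
BG005	k__Bacteria;p__P5;c__C5;o__O4;f__F4;g__G4;s__bg4
BG006	k__Bacteria;p__P6;c__C6;o__O5;f__F5;g__G5;s__bg5
BG007	k__Bacteria;p__P1;c__C7;o__O6;f__F6;g__G6;s__bg6
BG008	k__Bacteria;p__P2;c__C8;o__O7;f__F7;g__G7;s__bg7
MK1	k__Bacteria;p__Pm;c__Cm;o__Om0;f__Fm0;g__Gm0;s__marker0
RL1	k__Bacteria;p__Pm;c__Cm;o__Om0;f__Fm0;g__Gm0;s__marker0
MK2	k__Bacteria;p__Pm;c__Cm;o__Om1;f__Fm1;g__Gm1;s__marker1
RL2	k__Bacteria;p__Pm;c__Cm;o__Om1;f__Fm1;g__Gm1;s__marker1
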