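FeatureID	A01	A02	A03	A04	B01	B02	B03	B04
BG001	0.2806813653	0.2805824218	0.2030709977	0.4157029905	0.2875741614	0.2372750841	0.3755807851	0.2428192815
BG002	0.2192000534	0.2833456845	0.2343769288	0.2437384042	0.2112513116	0.2792079317	0.1543656839	0.2816882581
BG003	0.0385485228	0.1232027532	0.1642130066	0.03864845424	0.1284325778	0.1930668366	0.1290176246	0.1974369378
BG004	0.001518075585	0.01039651094	0.08711944735	0.009848017682	0.01208804824	0.01231035561	0.01135754199	0.0007735376643
BG005	0.1423248051	0.0762199587	0.08748040669	0.0146335667	0.1273931782	0.100014832	0.03153494376	0.08197457663
BG006	0.1059743859	0.02948800415	0.044314715	0.1411514	0.04856416714	0.0435342595	0.04826481483	0.03711805525
BG007	0.09078936054	0.06586379151	0.03591452825	0.04138429952	0.05285552105	0.06751523795	0.05502646262	0.08186427752
BG008	0.112812362	0.1191621851	0.1354948904	0.0867231685	0.1251650575	0.0628503285	0.1910836107	0.06836204708
MK1	0.005409920697	0.007050703563	0.005088991453	0.008169698672	0	0	0	0
RL1	0	0	0	0	0.005470796791	0.004225134038	0.00326908696	0.007963028539
MK2	0.002741148699	0.004687986606	0.002926087809	0	0.001205180162	0	0.000499445484	0
RL2	0	0	0	0	0	0	0	0
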