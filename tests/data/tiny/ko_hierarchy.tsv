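KO	level2	level1
K00001	pathway_1	category_1
K00002	pathway_2	category_2
K00003	pathway_3	category_3
K00004	pathway_4	category_1
K00005	pathway_5	category_2
K00006	pathway_6	category_3
K00007	pathway_1	category_1
K00008	pathway_2	category_2
K00009	pathway_3	category_3
K00010	pathway_4	category_1
K00011	pathway_5	category_2
K00012	pathway_6	category_3
K00013	pathway_1	category_1
K00014	pathway_2	category_2
K00015	pathway_3	category_3
K00016	pathway_4	category_1
K00017	pathway_5	category_2
K00018	pathway_6	category_3
K00019	pathway_1	category_1
K00020	pathway_2	category_2
K00021	pathway_3	category_3
K00022	pathway_4	category_1
K00023	pathway_5	category_2
K00024	pathway_6	category_3
K00025	pathway_1	category_1
K00026	pathway_2	category_2
K00027	pathway_3	category_3
K00028	pathway_4	category_1
K00029	pathway_5	category_2
K00030	pathway_6	category_3
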