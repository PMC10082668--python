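FeatureID	K00001	K00002	K00003	K00004	K00005	K00006	K00007	K00008	K00009	K00010	K00011	K00012	K00013	K00014	K00015	K00016	K00017	K00018	K00019	K00020	K00021	K00022	K00023	K00024	K00025	K00026	K00027	K00028	K00029	K00030
BG001	0.5298826404	0.1372403938	0.03589939591	0.2262951768	0.5005222554	1.09693068	0.09757291865	0.9412888611	0.08313309552	0.01953075667	5.420301589e-05	0.4900227233	0.8320174694	0.329418439	0.01311713774	0.2219316354	0.7700218013	0.3098851312	0.1907220781	0.1668956527	0.07917689469	0.4839395212	0.8453501895	0.02787995598	0.00810861723	0.2133305758	0.5614765795	0.1451771747	0.4237158208	0.007682508356
BG002	3.193963241	0.5699116645	3.584067533	0.6152623789	0.074115468	1.736868967	0.04095093141	0.3436872699	1.264578725	0.6224439312	0.4185171394	0.4598445364	0.2440269295	0.02088724117	0.3556467	2.100648536	0.1203186613	0.0005200165339	0.2326166053	0.006844252887	0.2407933543	0.3334194649	0.07127600468	0.2715576202	0.0004670819968	1.653492876	0.5057533453	0.4788403254	0.7838141155	1.937569795
BG003	0.00139969936	0.1375833407	0.95885549	0.2655222417	2.335404453	0.002016963734	0.7119939695	1.620480885	0.09981116579	0.4834146433	0.008923951375	0.06888552242	0.05806681802	1.087198583	0.03213712631	1.419430161	0.09630078196	3.756277454	0.05274189211	0.5176781595	0.2564109223	0.3463413841	0.9381171701	0.6806467845	0.01531500392	0.1580684202	0.2387143694	2.927337196	0.3119104961	0.01121426012
BG004	0.1756568127	0.3680233464	0.9392871383	0.8490428638	0.01191241203	0.9029764711	0.2827655988	1.357027546	0.1702152998	0.1813755515	1.354843332	0.06142444896	0.7033590279	0.0110834741	1.048478775	0.0206991331	0.02740075123	0.02359707518	0.000447238595	0.03049964337	0.360747167	0.1549449365	0.2545675222	1.222733468	0.03294167269	0.06219416298	0.1395875245	0.01033717584	0.002700035567	0.009823414834
BG005	1.737555886	0.9278233843	0.4458406216	0.01810429679	0.2646372785	0.2141832528	0.4404257922	0.0195352087	0.1350649306	0.1072533447	0.5361154307	0.23127484	0.28810387	0.4651886591	0.08303365798	0.04096761932	1.297452118	0.6403541908	3.059209935	0.3644971608	0.8950659155	0.064203124	0.009034349958	0.02934071086	0.3343680219	0.2736963575	0.9144345524	0.3733990112	0.01433613222	0.00769287077
BG006	0.1752329095	0.5035704643	1.681217407	0.07318915425	0.09887250115	0.0218399252	0.1917599458	0.6520746405	2.337710586	0.229795179	1.218304912	0.01486489565	0.2064048105	0.08723695385	1.978653523	0.01222979665	1.123837048	0.05799815354	0.815766847	1.852205459	0.00130774163	0.00266854039	0.9251817481	1.210043453	0.9226770987	0.7972150665	1.13091491	0.04071602021	0.2545723624	0.4232394419
BG007	0.02409107302	0.0372650172	0.5962917584	1.515699334	0.02997325121	0.0336844461	0.2102778628	0.4346611149	0.02106279082	0.09080738217	0.5700846852	0.2584942454	0.0179813644	0.09284489555	0.3912482125	0.1695882145	0.04736217563	0.175058597	0.05089214218	0.325492002	0.4561858114	0.09999138981	0.3044065177	0.4162737963	0.2630708654	1.540018955	0.2536594823	0.9174220216	1.127001391	0.01342278057
BG008	1.157743826	0.07874277809	0.02992707807	1.063290389	0.1385786789	0.3753074188	0.1331661401	0.09669706065	0.5844688138	0.04370510462	0.02681448965	1.119997646	0.2009241298	0.006407887812	0.1881642445	0.02270234504	0.0542201866	0.2402936306	0.05937382817	0.4368075434	0.5013571481	0.003376595648	0.29287299	1.174867948	0.7837379585	0.2548377692	0.3548946193	0.11600209	0.1588441006	0.4246848182
MK1	0.1148231418	0.0006161878723	0.2008898091	0.07729629176	0.4299070354	0.4066476626	0.756861785	0.6259239502	0.8373501354	0.01301973906	0.1936780635	0.4681743524	0.6643762053	0.1200573029	0.001676653557	0.2398058371	0.216200315	0.1693948056	0.007194308956	0.9279883777	1.036431621	0.1389070352	0.01194261915	0.6053041708	1.337169477	0.9222319957	0.4092439165	2.025112447e-05	0.5168502459	0.1610862836
RL1	0.1179954306	0.0006034964653	0.1914259285	0.07982723383	0.4523949346	0.4033649484	0.7281039987	0.622049206	0.8325704525	0.01297037769	0.1894129502	0.4736326386	0.6713822929	0.1165221101	0.001700264472	0.2498556331	0.2169451526	0.1682558294	0.007173905643	0.9394779456	1.001170932	0.1393644873	0.01184971912	0.6280925911	1.332519612	0.9535144373	0.4003089153	2.049037994e-05	0.5201624559	0.1583106433
MK2	0.4312890321	0.1767208338	0.7233763266	0.08096350961	0.05527065437	1.82852745	0.6912938335	0.4668646246	0.05826047213	0.02416207984	0.0802288252	0.8807325761	0.1921825117	0.9923146423	0.8612665552	0.4658464669	0.2630633073	0.001284702829	0.001687491907	0.00429423777	0.2666197058	0.002596970784	0.5661129146	0.09124723267	0.01255976806	1.520443158e-06	0.2396122144	0.1860429983	1.152387102	0.1040000845
RL2	0.4185706528	0.1734888875	0.7448278896	0.0814223898	0.05612539871	1.787302951	0.6759872705	0.4710647731	0.05832841352	0.02442871372	0.07992825716	0.8856456336	0.1927912282	1.007871121	0.8752803281	0.4509960899	0.2515015982	0.001310701301	0.001728057335	0.004207470392	0.2568845115	0.002602119693	0.5767508198	0.09458742655	0.01269013152	1.509181589e-06	0.2353701145	0.1860856118	1.145510326	0.1019100288
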