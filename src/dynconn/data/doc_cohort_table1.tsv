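patient_id	diagnosis	sex_age	etiology	lesion	months_since_injury	crs_a	crs_v	crs_m	crs_verbal	crs_comm	crs_arousal	crs_total
01	MCS	M/40	Trauma	Bilateral frontal, temporal and right parietal, occipital lobe lesions	7.1	1	0	3	0	0	2	6
02	MCS	M/67	Hemorrhage	Bilateral frontal, temporal lobe lesions	3.0	0	0	3	0	0	2	5
03	MCS	F/72	Hemorrhage	Right frontal, temporal lobe, basal ganglia and brain stem lesions	6.1	1	1	3	0	0	2	7
04	MCS	M/70	Trauma	Bilateral frontal, temporal lobe lesions	2.2	0	1	4	0	0	2	7
05	MCS	F/44	Anoxia	Diffuse demyelination	3.1	2	3	1	1	0	2	9
06	MCS	M/31	Hemorrhage	Brain stem lesions	10.8	1	2	3	0	0	2	8
07	MCS	M/73	Hemorrhage	Brain stem and cerebellum lesions	4.0	2	3	4	0	0	3	12
08	MCS	M/43	Trauma	Left temporal, parietal lobe lesions	3.2	1	2	3	0	0	2	8
09	MCS	F/67	Trauma	Bilateral frontal lobe and left parietal lobe lesions	2.5	1	0	2	1	0	2	6
10	MCS	F/68	Hemorrhage	Left basal ganglia lesions	2.2	2	2	3	0	0	3	10
11	MCS	M/60	Hemorrhage	SAH	2.2	4	4	5	2	1	3	19
12	MCS	M/61	Hemorrhage	Right basal ganglia lesions	2.5	2	3	2	0	0	2	9
13	MCS	M/45	Trauma	Bilateral frontal lobe and left parietal lobe lesions	2.7	2	3	2	0	0	2	9
14	MCS	F/48	Trauma	Bilateral frontal lobe and left parietal lobe lesions	6.3	2	2	3	0	0	2	9
15	VS	M/44	Anoxia	Diffuse demyelination	7.3	1	0	1	0	0	2	4
16	VS	M/42	Anoxia	Diffuse demyelination	7.1	0	0	1	1	0	2	4
17	VS	M/65	Trauma	Left frontal and parietal lobe lesions	3.0	0	1	0	0	0	2	3
18	VS	M/34	Hemorrhage	Right temporal, parietal and occipital lobe and left frontal lobe lesions	0.7	0	0	1	0	0	2	3
19	VS	F/26	Trauma	Bilateral frontal and temporal lesions	2.1	2	1	2	0	0	2	7
20	VS	M/33	Trauma	Diffuse demyelination	6.1	0	0	1	0	0	2	3
21	VS	M/59	Trauma	Left frontal and temporal lobe, basal ganglia lesions	2.2	0	1	1	0	0	2	4
22	VS	M/62	Trauma	Right frontal and temporal lobe lesions	4.4	0	0	2	0	0	2	4
23	VS	M/52	Trauma	SAH, right temporal lobe lesions	2.5	1	1	2	0	0	2	6
24	VS	F/55	Hemorrhage	left frontal and temporal lesion	1.6	1	1	2	0	0	2	6
25	VS	M/35	Hemorrhage	Brain stem lesion	6.0	0	0	2	0	0	2	4
26	VS	F/49	Hemorrhage	Brain stem lesion	3.2	0	0	2	0	0	2	4
27	VS	M/54	Trauma	SAH	1.7	2	1	2	0	0	2	7
28	VS	F/67	Trauma	Right temporal lobe lesions	5.9	0	1	1	0	0	2	4
29	VS	F/53	Hemorrhage	SAH	1.4	2	1	2	0	0	3	8
30	VS	M/69	Hemorrhage	Brain stem lesion	2.0	0	1	2	1	0	2	6
31	VS	F/63	Trauma	Right temporal lobe lesions	4.0	0	1	2	0	0	2	5
32	VS	M/75	Trauma	Left frontal and temporal lobe lesions	2.4	2	1	2	2	0	2	9
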