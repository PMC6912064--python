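patient_id	age	gender	smoking_index	stage	diameter_sum_cm	histology	best_response
1	50	male	400	IV	5.2	Squamous cell carcinoma	SD
2	59	male	1500	IV	4.2	Squamous cell carcinoma	SD
3	61	male	800	IV	10.9	Squamous cell carcinoma	PR
4	68	male	600	III	5	Squamous cell carcinoma	SD
5	72	male	800	IV	4.7	Squamous cell carcinoma	PR
6	54	male	600	IV	5.1	Squamous cell carcinoma	PR
7	66	male	0	IV	28.7	Squamous cell carcinoma	PD
8	63	female	0	IV	34.1	Squamous cell carcinoma	PR
9	69	male	450	IV	8	Squamous cell carcinoma	PR
10	57	male	800	IV	8.7	Adenocarcinoma	SD
11	64	female	0	IV	3.4	Squamous cell carcinoma	SD
12	60	male	800	IV	6.4	Adenocarcinoma	SD
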