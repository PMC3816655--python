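atom_name	residue_name	charge_e	rmin_half_A	eps_kcal	solv_param	radius_A
C1	TOA	0.069891	1.880664	0.193391	0.025843	1.880664
C2	TOA	0.034619	1.537992	0.153755	-0.008120	1.537992
C3	TOA	-0.018039	1.574398	0.101378	-0.007710	1.574398
C4	TOA	-0.005618	1.836235	0.176666	-0.008997	1.836235
C5	TOA	0.382836	1.893380	0.190771	0.009313	1.893380
C6	TOA	0.198038	1.688877	0.143833	-0.002945	1.688877
C7	TOA	0.080624	1.669794	0.119406	0.017291	1.669794
C8	TOA	0.086413	1.529046	0.175263	0.007288	1.529046
C1	TOB	-0.025870	1.741596	0.142038	0.010423	1.741596
C2	TOB	0.143481	1.641103	0.112443	0.021590	1.641103
C3	TOB	-0.015593	1.618866	0.151616	-0.004658	1.618866
C4	TOB	-0.508987	1.592050	0.057406	-0.006272	1.592050
C5	TOB	0.063303	1.672762	0.117041	0.007855	1.672762
C6	TOB	0.410265	1.840697	0.090666	0.020538	1.840697
C7	TOB	0.260114	1.858851	0.151570	0.014618	1.858851
C8	TOB	0.121103	1.777932	0.170851	0.023401	1.777932
C1	TOC	-0.216432	1.915540	0.146701	0.021623	1.915540
C2	TOC	0.212076	1.776814	0.131069	0.012665	1.776814
C3	TOC	0.121422	1.793775	0.072599	-0.004081	1.793775
C4	TOC	-0.211417	1.784315	0.060316	0.012722	1.784315
C5	TOC	-0.171933	1.644283	0.115333	0.021541	1.644283
C6	TOC	-0.030347	1.739509	0.087348	0.002097	1.739509
C7	TOC	0.197107	1.785072	0.148206	0.008641	1.785072
C8	TOC	0.101521	1.845842	0.106237	-0.006558	1.845842
L1	LIG	-0.447486	1.977052	0.097801	0.008075	1.977052
L2	LIG	-0.270068	1.791387	0.114050	0.015888	1.791387
L3	LIG	-0.262376	1.936715	0.084172	-0.002741	1.936715
L4	LIG	-0.244209	1.676270	0.173515	0.025168	1.676270
L5	LIG	0.553632	1.519904	0.183412	0.008433	1.519904
L6	LIG	0.469482	1.793788	0.105485	0.011895	1.793788
L7	LIG	-0.176441	1.716306	0.177855	0.025562	1.716306
L8	LIG	-0.248189	1.564678	0.112094	0.027837	1.564678
L9	LIG	-0.198110	1.705880	0.062144	0.023758	1.705880
L10	LIG	0.505179	1.764940	0.122329	-0.004243	1.764940
L11	LIG	0.045840	1.579032	0.184215	0.017042	1.579032
L12	LIG	-0.014024	1.566263	0.149113	0.006760	1.566263
L13	LIG	-0.021824	1.558113	0.188996	0.009076	1.558113
L14	LIG	-0.723866	1.547765	0.198141	-0.005255	1.547765
L15	LIG	-0.493475	1.984991	0.192977	-0.005002	1.984991
L16	LIG	-0.146670	1.863135	0.069662	0.003186	1.863135
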