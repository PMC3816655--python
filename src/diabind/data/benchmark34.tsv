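pdb_id	protein_name	dg_exptl	dg_simple	dg_diav	dg_dias
1abe	L-ARABINOSE-BINDING PROTEIN	-9.57	-5.46	-6.27	-6.68
1abf	L-ARABINOSE-BINDING PROTEIN	-7.39	-6.30	-6.67	-6.90
1apu	ACID PROTEINASE (PENICILLOPEPSIN)	-10.50	-13.50	-11.98	-11.76
1dbb	FAB' FRAGMENT	-12.27	-8.75	-11.79	-11.69
1dbj	FAB' FRAGMENT	-10.47	-8.35	-12.27	-12.10
1dog	GLUCOAMYLASE	-5.48	-5.40	-6.09	-6.12
1dwb	THROMBIN	-3.98	-3.69	-4.83	-5.05
1epo	ENDOTHIA ASPARTIC PROTEINASE	-10.85	-17.25	-14.82	-15.56
1etr	THROMBIN	-10.09	-9.91	-10.35	-10.08
1ets	THROMBIN	-11.62	-11.05	-11.82	-11.52
1ett	THROMBIN	-8.44	-9.46	-9.99	-9.75
1hpv	HIV-1 PROTEASE	-12.57	-14.02	-12.88	-12.78
1hsl	HISTIDINE-BINDING PROTEIN	-9.96	-6.53	-6.74	-7.18
1htf	HIV-1 PROTEASE	-11.04	-12.45	-11.12	-11.00
1hvr	HIV-1 PROTEASE	-12.97	-16.98	-14.67	-14.95
1nsd	NEURAMINIDASE	-7.23	-7.44	-8.33	-8.13
1pgp	6-PHOSPHOGLUCONATE DEHYDROGENASE	-7.77	-11.01	-11.09	-10.24
1phg	CYTOCHROME P450	-11.81	-6.88	-8.03	-8.22
1ppc	TRYPSIN	-8.80	-9.83	-8.66	-8.85
1pph	TRYPSIN	-8.49	-8.50	-7.87	-8.00
1rbp	RETINOL-BINDING PROTEIN	-9.17	-9.29	-8.58	-8.91
1tng	TRYPSIN	-4.00	-4.15	-4.64	-4.90
1tnh	TRYPSIN	-4.59	-3.54	-4.24	-4.61
1ulb	PURINE NUCLEOSIDE PHOSPHORYLASE	-7.23	-3.82	-5.71	-5.74
2cgr	IGG2B (KAPPA) FAB FRAGMENT	-9.92	-7.07	-10.94	-10.88
2gbp	D-GALACTOSE/D-GLUCOSE-BINDING PROTEIN	-10.36	-8.95	-9.27	-9.77
2ifb	INTESTINAL FATTY ACID BINDING	-7.41	-9.57	-8.53	-8.38
2phh	P-HYDROXYBENZOATE HYDROXYLASE	-6.38	-4.09	-6.83	-6.79
2r04	RHINOVIRUS 14 (HRV14)	-8.48	-10.39	-10.31	-10.26
2tsc	THYMIDYLATE SYNTHASE	-11.62	-11.05	-8.68	-8.28
2ypi	TRIOSE PHOSPHATE ISOMERASE	-6.58	-5.40	-5.72	-6.45
3ptb	TRYPSIN	-6.46	-4.93	-5.02	-4.55
4dfr	DIHYDROFOLATE REDUCTASE	-13.23	-11.52	-13.93	-13.52
5abp	L-ARABINOSE-BINDING PROTEIN	-9.05	-6.64	-7.19	-7.59
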