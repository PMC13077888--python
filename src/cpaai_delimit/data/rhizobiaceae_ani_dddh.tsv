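strain_a	strain_b	ani	dddh	dddh_ci_lo	dddh_ci_hi	note
Agrobacterium deltaense YIC 4121	Agrobacterium leguminum MOPV5	95.97	66.7	63.7	69.5	dDDH formula 2
Neorhizobium petrolearium DSM 26482	Neorhizobium phenanthreniclasticum Rsf11	95.86	66.7	63.7	69.5	dDDH formula 2
Pseudorhizobium banfieldiae NT-26	Pseudorhizobium flavum YW14	95.30	62.1	59.2	64.9	dDDH formula 2
Pseudorhizobium banfieldiae NT-26	Pseudorhizobium halotolerans AB21	95.39	61.9	59.0	64.7	dDDH formula 2
Pseudorhizobium flavum YW14	Pseudorhizobium halotolerans AB21	96.01	67.4	64.4	70.2	dDDH formula 2
Rhizobium aegyptiacum 1010	Rhizobium aethiopicum HBR26	98.43	86.6	84.0	88.9	dDDH formula 2
Rhizobium favelukesii LPU83	Rhizobium tibeticum CCBAU85039	95.59	67.9	64.9	70.7	dDDH formula 2
Rhizobium johnstonii 3841	Rhizobium acaciae 1AS11	95.91	66.0	63.0	68.8	dDDH formula 2
Rhizobium sophorae CCBAU 03386	Rhizobium changzhiense WYCCWR 11279	95.52	63.0	60.1	65.9	dDDH formula 2
Shinella sumterensis MEC087	Shinella oryzae Z-25	96.55	72.0	68.9	74.8	dDDH formula 2
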