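# Pair potentials between ions and charged coarse-grained particles.
# Units: energies kcal/mol, distances Angstrom. "-" marks an absent term.
# AA+ = positive amino acids (Arg, Lys); AA- = negative amino acids (Asp, Glu).
pair	eps	sigma	rm_eps	sigma_eps	H1	rm_h1	sigma_h1	H2	rm_h2	sigma_h2
P-P	0.18379	6.86	6.86	0.5	-	-	-	-	-	-
Na+-P	0.02510	4.14	3.44	1.25	3.15488	4.1	0.57	0.47801	6.5	0.4
Na+-AA+	0.239	4.065	3.44	1.25	3.15488	4.1	0.57	-	-	-
Na+-AA-	0.239	4.065	3.44	1.25	3.15488	4.1	0.57	0.47801	6.5	0.4
Mg2+-P	0.1195	4.87	3.75	1.0	1.29063	6.1	0.5	0.97992	8.3	1.2
Mg2+-AA+	0.239	3.556	3.75	1.0	1.29063	6.1	0.5	-	-	-
Mg2+-AA-	0.239	3.556	3.75	1.0	1.29063	6.1	0.5	0.97992	8.3	1.2
Cl--P	0.08121	5.5425	4.2	0.5	0.83652	6.7	1.5	-	-	-
Cl--AA+	0.239	4.8725	4.2	0.5	0.83652	6.7	1.5	0.47801	5.6	0.4
Cl--AA-	0.239	4.8725	4.2	0.5	0.83652	6.7	1.5	-	-	-
Na+-Na+	0.01121	2.43	2.7	0.57	0.17925	5.8	0.57	-	-	-
Na+-Mg2+	0.04971	2.37	2.37	0.5	-	-	-	-	-	-
Na+-Cl-	0.08387	3.1352	3.9	2.06	5.49713	3.3	0.57	0.47801	5.6	0.4
Mg2+-Mg2+	0.89460	1.412	1.412	0.5	-	-	-	-	-	-
Mg2+-Cl-	0.49737	4.74	4.48	0.57	1.09943	5.48	0.44	0.05975	8.16	0.35
Cl--Cl-	0.03585	4.045	4.2	0.56	0.23901	6.2	0.5	-	-	-
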