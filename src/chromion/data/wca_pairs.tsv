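# Purely repulsive WCA interactions between ions and neutral coarse-grained particles.
# Units: eps kcal/mol, sigma Angstrom.
# S = deoxyribose sugar site; A/T/G/C = base sites; AA = non-charged amino acids.
pair	eps	sigma
Na+-S	0.239	4.315
Na+-A	0.239	3.915
Na+-T	0.239	4.765
Na+-G	0.239	3.665
Na+-C	0.239	4.415
Na+-AA	0.239	4.065
Mg2+-S	0.239	3.806
Mg2+-A	0.239	3.406
Mg2+-T	0.239	4.256
Mg2+-G	0.239	3.156
Mg2+-C	0.239	3.906
Mg2+-AA	0.239	3.556
Cl--S	0.239	5.1225
Cl--A	0.239	4.7225
Cl--T	0.239	5.5725
Cl--G	0.239	4.4725
Cl--C	0.239	5.2225
Cl--AA	0.239	4.8725
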