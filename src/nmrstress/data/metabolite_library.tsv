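metabolite	pathway	shifts_ppm	relative_amplitudes
Creatinine	Arginine (Arg) and creatine metabolism	3.05	1.0
Hippurate	Phenylalanine (Phe)	7.83,7.63,7.54	2.0,1.0,2.0
OH-Phenylacetylglycine	Tyrosine (Tyr)	7.20	1.0
Trimethylamine N-oxide	Microbial metabolism	3.27	1.0
3-Methyladenine	Nucleotide	3.97	1.0
Phosphocreatine	Arginine (Arg) and Proline (Pro)	3.93	1.0
Phenylglyoxylate	Microbial metabolism	7.62	1.0
OH-Phenylacetate	Microbial metabolism	7.27	1.0
Allantoic acid	Microbial and purine metabolism	5.30	1.0
Cholecalciferol	Vitamin D	0.56,0.53	1.0,1.0
Glycogen	Glucagon signaling	5.40	1.0
Galactitol	Galactose	3.69	1.0
6OH-Dopamine	Neurodegeneration	2.86	1.0
Pyridoxal	Vitamin B6	5.29,5.28,5.27	1.0,1.0,1.0
β-Alanine	Pantotenate and CoA biosynthesis and pyrimidine metabolism	3.17	1.0
Histamine	Histamine	3.28	1.0
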