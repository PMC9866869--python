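code_id	name
1	Standard
2	Vertebrate Mitochondrial
3	Yeast Mitochondrial
4	Mold Mitochondrial
5	Invertebrate Mitochondrial
6	Ciliate Nuclear
9	Echinoderm Mitochondrial
10	Euplotid Nuclear
12	Alternative Yeast Nuclear
13	Ascidian Mitochondrial
14	Alternative Flatworm Mitochondrial
16	Chlorophycean Mitochondrial
21	Trematode Mitochondrial
22	Scenedesmus obliquus Mitochondrial
23	Thraustochytrium Mitochondrial
24	Pterobranchia Mitochondrial
25	Candidate Division SR1
26	Pachysolen tannophilus Nuclear
27	Karyorelict Nuclear
28	Condylostoma Nuclear
29	Mesodinium Nuclear
30	Peritrich Nuclear
31	Blastocrithidia Nuclear
33	Cephalodiscidae Mitochondrial
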