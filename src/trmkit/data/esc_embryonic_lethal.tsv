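entrez	symbol	phenotype
93760	Arid1a	Complete
15251	Hif1a	Partial
18519	Kat2b	Complete
17187	Max	Complete
71950	Nanog	Complete
18999	Pou5f1	Complete
99377	Sall4	Complete
20466	Sin3a	Complete
20674	Sox2	Complete
20848	Stat3	Complete
22059	Trp53	Complete
93765	Ube2n	Complete
226442	Zfp281	Complete
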