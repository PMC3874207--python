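entrez	symbol	phenotype
12400	Cbfb	Hematopoiesis
12914	Crebbp	Hematopoiesis
23871	Ets1	Lymphopoiesis
14011	Etv6	Hematopoiesis/Lymphopoiesis
14247	Fli1	Hematopoiesis
14281	Fos	Lymphopoiesis
14460	Gata1	Hematopoiesis
14461	Gata2	Hematopoiesis/Morphology
14582	Gfi1b	Morphology
15412	Hoxb4	Hematopoiesis
15414	Hoxb6	Hematopoiesis
16452	Jak2	Hematopoiesis
16909	Lmo2	Morphology
17268	Meis1	Hematopoiesis
18514	Pbx1	Hematopoiesis
12394	Runx1	Hematopoiesis
12393	Runx2	Hematopoiesis
20375	Sfpi1	Hematopoiesis/Morphology
20586	Smarca4	Morphology
20587	Smarcb1	Morphology
21349	Tal1	Hematopoiesis
21423	Tcf3	Lymphopoiesis/Morphology
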