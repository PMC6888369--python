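m6A	CD8T	GM	HEK293T	hESC	Neuro	A549	AML	H1299	HepG2	HeLa	PA-HeLa
1763	-	-	+	-	-	-	-	-	-	-	-
2414	-	-	+	-	-	-	-	-	-	-	-
2515	+	-	+	+	+	+	+	+	+	+	-
2577	+	+	+	+	+	+	+	+	+	+	-
2611	+	+	+	+	+	+	+	+	+	+	+
2720	+	-	+	-	-	+	-	-	-	+	+
3752	-	-	+	-	-	-	-	-	-	-	-
4457	-	-	+	-	-	-	-	-	-	-	+
5044	+	-	+	-	+	+	-	-	-	-	-
6924	-	-	+	-	-	-	-	-	-	-	-
8181	+	-	+	-	-	-	-	-	-	-	-
8290	-	-	+	-	-	-	-	-	-	-	-
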