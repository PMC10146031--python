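group_id	forward	start	reverse	end	sample_size
Same1	CCAGCASCYGCGGTAATTCC	564	ACTTTCGTTCTTGAT	980	120
Same2	CCAGCASCYGCGGTAAT	564	ACTTTCGTTCTTGATYRA	980	23
Short1	CYGCGGTAATTCCAGCTC	571	TCYDAGAATTYCACCTCT	914	73
Short2	TTAAAAAGCTCGTAGTTG	616	AAGAAGACATCCTTGGTG	963	27
Near1	GCGGTAATTCCAGCTCCAA	573	ACTTTCGTTCTTGATYRR	980	33
Near2	CCAGCASCCGCGGTAATWCC	564	AKCCCCYAACTTTCGTTCTTGAT	988	17
Near3	CCAGCASCCGCGGTAATWCC	564	TCTGRTYGTCTTTGATCCCYTA	1002	12
Long1	CGGTAAYTCCAGCTCYAV	574	CCGTCAATTHCTTYAART	1149	62
Long2	GTGCCAGCAGCCGCG	561	TTTAAGTTTCAGCCTTGCG	1138	44
Long3	GGCAAGTCTGGTGCCAG	551	TCCGTCAATTYCTTTAAGT	1149	36
Long4	CGGTAATTCCAGCTCCAATAGC	574	CACCAACTAAGAACGGCCATGC	1293	150
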