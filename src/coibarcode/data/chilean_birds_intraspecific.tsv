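species	n_individuals	mean_intraspecific_percent
Anas georgica	2	0.0
Aphrastura masafuerae	2	0.0
Attagis gayi	3	0.0
Burhinus supercialiaris	2	0.0
Charadrius alexandrinus	3	0.0
Charadrius alticola	2	0.2
Charadrius falklandicus	2	0.0
Charadrius modestus	2	0.2
Chloephaga rubidiceps	2	0.0
Chroicocephalus maculipennis	2	0.5
Curaeus curaeus	2	8.7
Elaenia albiceps chilensis	4	0.0
Enicognathus leptorhynchus	4	0.2
Eudyptes chrysocome	8	0.1
Haematopus leucopodus	2	0.0
Haematopus palliatus	2	0.0
Larus belcheri	2	0.2
Leucophaeus modestus	4	0.0
Limosa haemastica	2	0.0
Milvago chimango	5	0.0
Mimus thenca	3	0.0
Molothrus bonariensis	2	0.2
Oceanites oceanicus	2	0.0
Oreopholus ruficollis	2	0.0
Phegornis mitchelli	2	0.0
Phrygilus alaudinus	15	0.5
Phrygilus atriceps	3	0.0
Phrygilus fruticeti	7	0.3
Phrygilus gayi	7	1.5
Phrygilus plebejus	7	0.3
Phrygilus unicolor	2	0.2
Recurvirostra andina	2	0.0
Sephanoides sephanoides	2	2.2
Spheniscus magellanicus	2	0.5
Spinus barbatus	4	0.1
Strix rufipes	2	0.0
Theristicus melanopis	4	0.1
Thinocorus orbignyianus	6	0.1
Troglodytes musculus chilensis	3	1.1
Turdus falcklandii	3	0.3
Tyto alba	17	0.1
Vanellus chilensis	6	0.0
Zenaida auriculata auriculata	4	0.4
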