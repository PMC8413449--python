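position	ref	alt	label
1494	C	T	deafness
1555	A	G	deafness
3243	A	G	MELAS
3256	C	T	MELAS
3271	T	C	MELAS
3460	G	A	LHON
3697	G	A	Leigh/MELAS
3733	G	A	LHON
4171	C	A	LHON
4300	A	G	cardiomyopathy
7445	A	G	deafness
8344	A	G	MERRF
8356	T	C	MERRF
8363	G	A	MERRF
8993	T	G	NARP/Leigh
8993	T	C	NARP/Leigh
9176	T	C	Leigh
9185	T	C	Leigh
10158	T	C	Leigh
10191	T	C	Leigh
10197	G	A	Leigh/dystonia
11696	G	A	LHON
11777	C	A	Leigh
11778	G	A	LHON
12706	T	C	Leigh
13094	T	C	Leigh
13513	G	A	Leigh/MELAS
14459	G	A	LHON/dystonia
14484	T	C	LHON
14487	T	C	Leigh
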