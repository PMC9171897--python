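element	neutron_offset	mass	abundance
C	0	12.0	0.9893
C	1	13.00335483521	0.0107
H	0	1.00782503224	0.999885
H	1	2.01410177812	0.000115
N	0	14.00307400446	0.99636
N	1	15.00010889894	0.00364
O	0	15.9949146196	0.99757
O	1	16.99913175664	0.00038
O	2	17.99915961287	0.00205
S	0	31.97207117443	0.9499
S	1	32.97145890985	0.0075
S	2	33.96786701	0.0425
S	4	35.96708071	0.0001
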