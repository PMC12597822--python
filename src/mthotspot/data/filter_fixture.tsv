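# 12-row boundary fixture for the somatic retention rules.
# Designed survivors (see filter_fixture_truth.tsv): F01, F03, F08, F11.
sample_id	pos	ref	alt	tumor_vaf	normal_vaf	alt_fwd	alt_rev	depth	tissue	type
F01	1227	G	A	0.30	0.002	10	10	1000	breast	SNV
F02	1227	G	A	0.05	0.000	10	10	1000	breast	SNV
F03	2571	T	C	0.051	0.0099	2	2	900	lung	SNV
F04	2571	T	C	0.30	0.01	10	10	900	lung	SNV
F05	2571	T	C	0.30	0.011	10	10	900	lung	SNV
F06	709	G	A	0.40	0.001	2	1	1100	renal	SNV
F07	709	G	A	0.40	0.001	1	5	1100	renal	SNV
F08	709	G	A	0.40	0.001	2	2	1100	renal	SNV
F09	513	C	T	0.30	0.000	10	10	1000	ovary	SNV
F10	525	C	T	0.30	0.000	10	10	1000	ovary	SNV
F11	526	C	T	0.30	0.000	10	10	1000	ovary	SNV
F12	3105	A	G	0.30	0.000	10	10	1000	ovary	SNV
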