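code_id	min_Fpi	me_Fpi	max_Fpi	pct_min	pct_me	pct_max
1	0.245	1.696	9.016	0.0	0.0	0.0
2	0.43	1.968	10.45	75.4	16.0	15.9
3	0.266	1.712	7.983	8.7	0.9	-11.5
4	0.24	1.627	7.855	-2.0	-4.1	-12.9
5	0.232	1.565	7.264	-5.4	-7.7	-19.4
6	0.271	1.734	8.926	10.5	2.2	-1.0
9	0.222	1.337	6.208	-9.3	-21.2	-31.1
10	0.249	1.537	8.341	1.6	-9.4	-7.5
12	0.317	1.91	9.556	29.3	12.6	6.0
13	0.33	1.759	7.671	34.7	3.7	-14.9
14	0.227	1.341	6.176	-7.4	-20.9	-31.5
16	0.297	1.674	8.344	21.2	-1.3	-7.5
21	0.203	1.371	6.758	-17.0	-19.2	-25.0
22	0.376	2.322	11.34	53.5	36.9	25.8
23	0.274	1.985	11.41	12.0	17.0	26.5
24	0.233	1.588	7.728	-5.0	-6.4	-14.3
25	0.243	1.726	9.002	-0.8	1.7	-0.2
26	0.406	1.894	9.737	65.7	11.7	8.0
27	0.262	1.73	9.052	7.0	2.0	0.4
28	0.262	1.73	9.052	7.0	2.0	0.4
29	0.262	1.537	8.242	7.0	-9.4	-8.6
30	0.238	1.708	8.831	-2.9	0.7	-2.1
31	0.256	1.708	7.742	4.6	0.7	-14.1
33	0.248	1.608	7.42	1.3	-5.2	-17.7
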