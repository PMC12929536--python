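# default propensity table, drawn once (seed=20260921); replace via PropensityTable.from_tsv
# window=7
aa	dG_native	dH_ap_native	dH_pol_native	TdS_conf_native	dG_denatured	dH_ap_denatured	dH_pol_denatured	TdS_conf_denatured
A	2.459727	-9.846730	5.276616	1.918950	-0.448262	-10.198649	3.766647	7.311402
C	0.001877	-1.140104	7.297774	5.196103	1.521887	-9.321829	1.024853	4.438788
D	1.522440	-12.705749	13.791569	1.930375	0.417023	-7.318906	1.980024	4.320485
E	3.609038	-8.771404	7.740062	2.991059	-0.054711	-0.786498	3.177380	1.729404
F	0.217394	-10.851081	11.893126	3.083250	-0.260898	2.129298	2.780028	6.192678
G	3.090303	-8.514081	9.835006	3.016595	1.335528	-5.224546	2.226624	3.915887
H	1.403423	-5.342460	9.710640	1.243454	2.124883	-4.808797	2.690368	5.876622
I	4.379273	-8.129127	7.812267	3.039273	-1.529790	0.135437	4.665309	4.993973
K	4.962250	-9.173584	11.984061	1.236838	0.136521	-3.431621	4.435219	2.036144
L	1.229627	-6.767406	6.254657	2.957911	1.621344	0.169204	1.480581	5.372129
M	3.425592	-13.140480	11.625264	3.649498	-0.214802	-1.366734	1.406524	3.478179
N	1.597175	-9.914065	12.831476	2.562921	1.159282	-7.203983	-0.571405	4.734666
P	1.930925	-7.666989	15.180794	4.475091	2.617033	-2.402376	3.266030	5.193213
Q	0.792810	-8.394839	8.346674	3.119634	-0.162743	-4.709904	1.173078	5.975021
R	2.221278	-17.543723	11.366512	2.212038	1.087896	-4.818090	-0.764928	3.978948
S	3.143964	-16.825061	7.781631	3.160800	0.614922	-4.224875	2.109971	7.493569
T	-2.307377	-22.840077	5.435027	3.045787	-0.561850	-3.687623	3.990348	5.089298
V	3.040031	-9.871699	10.264886	1.959602	1.675286	-3.783189	1.404653	3.443305
W	0.033721	-8.280738	3.412986	1.071213	1.525564	-11.423636	3.425893	3.052040
Y	3.840188	-14.048939	6.755762	2.495909	1.617837	1.375355	2.646203	6.882248
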