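probe	weight	direction
cgS00000	1.5164	hyper
cgS00001	1.272	hypo
cgS00002	0.4677	hyper
cgS00003	2.3862	hypo
cgS00004	1.0733	hypo
cgS00005	0.9503	hypo
cgS00006	0.6847	hyper
cgS00007	0.1426	hypo
cgS00008	0.1001	hypo
cgS00009	1.2566	hypo
cgS00010	0.31	hyper
cgS00011	0.8046	hypo
cgS00012	0.4076	hypo
cgS00013	1.3054	hypo
cgS00014	0.1753	hypo
cgS00015	0.3737	hyper
cgS00016	2.5066	hyper
cgS00017	0.3081	hypo
cgS00018	0.5796	hypo
cgS00019	0.9604	hypo
cgS00020	1.9555	hypo
cgS00021	1.394	hypo
cgS00022	0.56	hypo
cgS00023	0.7319	hypo
cgS00024	1.214	hyper
cgS00025	0.8015	hypo
cgS00026	1.8505	hyper
cgS00027	0.4872	hyper
cgS00028	0.435	hyper
cgS00029	1.5169	hyper
cgS00030	0.2674	hypo
cgS00031	1.719	hypo
cgS00032	2.1494	hypo
cgS00033	1.6498	hyper
cgS00034	0.4217	hyper
cgS00035	0.877	hypo
cgS00036	0.4012	hypo
cgS00037	0.683	hyper
cgS00038	0.6867	hyper
cgS00039	0.2803	hypo
cgS00040	1.0532	hypo
cgS00041	0.2229	hypo
cgS00042	1.2678	hyper
cgS00043	0.2492	hypo
cgS00044	0.3104	hypo
cgS00045	2.7422	hyper
cgS00046	0.7078	hypo
cgS00047	1.0128	hypo
cgS00048	0.3389	hypo
cgS00049	0.2188	hyper
cgS00050	2.2051	hyper
cgS00051	0.8706	hyper
cgS00052	0.4549	hypo
cgS00053	0.3522	hypo
cgS00054	1.9878	hypo
cgS00055	1.8132	hypo
cgS00056	0.7254	hypo
cgS00057	0.7408	hypo
cgS00058	1.3329	hypo
cgS00059	0.2282	hypo
cgS00060	0.8969	hypo
cgS00061	1.9134	hyper
cgS00062	1.5427	hypo
cgS00063	0.9454	hypo
cgS00064	2.1499	hypo
cgS00065	1.0601	hypo
cgS00066	0.7381	hypo
cgS00067	0.1591	hypo
cgS00068	0.7814	hypo
cgS00069	0.5142	hyper
cgS00070	0.2117	hypo
cgS00071	0.1302	hypo
cgS00072	0.6911	hypo
cgS00073	0.0876	hypo
cgS00074	0.0918	hypo
cgS00075	1.1411	hypo
cgS00076	0.8694	hyper
cgS00077	1.4574	hyper
cgS00078	0.4487	hypo
cgS00079	1.4525	hypo
cgS00080	0.5923	hyper
cgS00081	1.1623	hypo
cgS00082	1.1544	hypo
cgS00083	1.2841	hypo
cgS00084	0.7334	hypo
cgS00085	0.8294	hypo
cgS00086	0.1747	hypo
cgS00087	1.8433	hyper
cgS00088	1.3726	hyper
cgS00089	1.7361	hyper
cgS00090	1.34	hypo
cgS00091	0.6481	hyper
cgS00092	0.2243	hypo
cgS00093	0.5836	hypo
cgS00094	1.9124	hypo
cgS00095	1.1543	hypo
cgS00096	1.2353	hypo
cgS00097	0.8171	hypo
cgS00098	1.7983	hypo
cgS00099	0.0658	hyper
cgS00100	1.3984	hypo
cgS00101	1.4895	hypo
cgS00102	2.3229	hypo
cgS00103	0.1192	hypo
cgS00104	0.5036	hypo
cgS00105	0.8295	hypo
cgS00106	2.1165	hypo
cgS00107	0.5722	hypo
cgS00108	0.6426	hypo
cgS00109	0.6088	hypo
cgS00110	0.5459	hypo
cgS00111	0.2851	hypo
cgS00112	0.6771	hypo
cgS00113	1.5911	hyper
cgS00114	1.0866	hypo
cgS00115	0.4642	hypo
cgS00116	1.2681	hyper
cgS00117	1.7157	hypo
cgS00118	0.6471	hypo
cgS00119	1.49	hypo
cgS00120	1.7286	hyper
cgS00121	0.3142	hypo
cgS00122	1.3772	hypo
cgS00123	0.6171	hyper
cgS00124	2.3736	hypo
cgS00125	0.0945	hypo
cgS00126	0.5474	hyper
cgS00127	2.5879	hyper
cgS00128	2.0723	hypo
cgS00129	2.5574	hypo
cgS00130	0.5326	hypo
cgS00131	0.3275	hypo
cgS00132	0.4939	hypo
cgS00133	1.3337	hypo
cgS00134	0.3096	hypo
cgS00135	0.1833	hypo
cgS00136	2.0161	hypo
cgS00137	1.1645	hypo
cgS00138	0.3693	hyper
cgS00139	0.4979	hypo
cgS00140	1.1806	hyper
cgS00141	1.1956	hypo
cgS00142	0.3006	hypo
cgS00143	0.1901	hypo
cgS00144	1.4615	hypo
cgS00145	2.9223	hypo
cgS00146	0.8312	hypo
cgS00147	0.3667	hypo
cgS00148	0.9509	hypo
cgS00149	0.7791	hypo
cgS00150	0.4352	hypo
cgS00151	0.2839	hyper
cgS00152	0.3458	hypo
cgS00153	1.8611	hypo
cgS00154	0.3431	hypo
cgS00155	1.1571	hyper
cgS00156	0.2488	hyper
cgS00157	0.5201	hypo
cgS00158	0.7051	hypo
cgS00159	0.2264	hyper
cgS00160	0.2272	hypo
cgS00161	0.167	hypo
cgS00162	0.97	hyper
cgS00163	1.4084	hypo
cgS00164	0.9049	hyper
cgS00165	0.6873	hypo
cgS00166	1.0373	hypo
cgS00167	0.3554	hyper
cgS00168	2.6913	hypo
cgS00169	0.4283	hypo
cgS00170	0.5814	hyper
cgS00171	0.5022	hyper
cgS00172	0.0556	hyper
cgS00173	0.0698	hyper
cgS00174	0.9281	hyper
cgS00175	1.3649	hyper
cgS00176	1.7047	hypo
cgS00177	0.9791	hypo
cgS00178	0.1375	hypo
cgS00179	0.5367	hypo
cgS00180	2.0169	hypo
cgS00181	0.4761	hyper
cgS00182	1.6487	hypo
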