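feature	trt_FR1_R1	trt_FR1_R2	trt_FR1_R3	trt_FR1_R4	ctl_FR1_R1	ctl_FR1_R2	ctl_FR1_R3	ctl_FR1_R4
P001	23.148265	23.331927	23.24372	22.955567	23.075669	22.870602	22.57136	23.934246
P002	30.417733	30.429902	29.373883	30.345232	29.380464	29.26314	29.593642	29.463544
P003	21.751955	22.501056	22.327566	22.542107	22.552762	22.310112	22.317403	22.477206
P004	28.860495	29.272849	28.749143	29.19509	28.350693	29.214137	28.924079	29.072575
P005	28.248083	28.036978	28.749828	28.718566	27.340511	27.020421	27.071929	27.24432
P006	28.812063	29.140864	29.209925	29.565478	29.170857	29.205721	29.065392	29.174857
P007	24.425782	24.321586	24.412132	24.679536	24.437075	24.438632	24.4399	24.592887
P008	20.981513	20.566041	20.429782	20.790491	20.499873	20.723953	20.789471	20.745961
P009	20.749683	20.965086	20.743552	20.562925	21.080348	21.05924	20.645451	20.614936
P010	21.717223	21.474012	21.702465	21.864251	21.862311	21.575425	21.634836	21.761774
P011	21.426993	20.9915	21.671223	21.421976	21.236618	21.689645	21.427658	21.51051
P012	26.537654	26.378182	26.693261	26.142091	26.497014	26.565455	26.377798	26.258069
P013	22.030112	21.485785	21.59185	21.814332	21.696414	21.794596	22.153523	21.744114
P014	28.885807	29.147784	28.940888	29.000751	29.173275	29.189208	29.347538	29.067209
P015	28.529299	28.137503	28.229429	28.069547	28.36051	28.473864	28.34411	28.148502
P016	30.2672	30.771842	30.689763	30.860087	29.180761	28.974476	29.563743	29.158138
P017	25.197088	25.082696	25.363046	25.550089	25.366928	25.642232	25.100215	25.522778
P018	22.845724	22.491972	22.521896	22.919103	23.303875	23.287852	22.894955	22.950384
P019	24.19224	24.314309	24.416705	24.546899	24.243407	24.424892	24.046642	24.168702
P020	22.281508	21.865724	22.643392	22.456747	22.184936	22.070032	22.02136	22.003123
P021	29.103034	29.110201	28.294825	28.408302	28.596793	29.013641	28.415586	28.555279
P022	28.366778	28.573674	28.455893	28.536622	28.643638	28.34086	28.545754	28.603236
P023	25.715944	25.724199	25.967016	25.618483	26.367952	25.808002	26.315424	25.805494
P024	21.504084	21.406953	21.288447	21.541978	21.817585	21.330822	21.578055	21.547742
P025	23.070013	22.90967	23.06676	22.963171	23.011519	23.149875	22.926991	23.041335
P026	25.836148	26.013127	25.82775	26.004307	26.313173	25.920258	26.053232	25.61614
P027	27.833093	27.141371	27.536245	27.732297	27.572972	27.307716	27.36565	27.538489
P028	22.592156	22.303505	22.142882	22.265143	21.928212	22.382479	22.595431	22.337169
P029	22.565228	22.589184	22.397675	22.40941	22.473692	22.517526	22.751851	22.382667
P030	26.954225	27.221528	27.291853	26.634717	26.964124	26.863565	27.383954	26.925233
P031	25.592361	25.288374	24.954193	24.83407	25.201856	25.114516	25.445321	25.704979
P032	21.786533	21.851183	21.845487	22.007406	22.056844	21.859258	21.628677	21.98289
P033	22.680496	22.442905	22.417633	22.217191	22.694107	22.668034	22.112302	22.027453
P034	20.785376	20.686822	20.955626	20.385309	20.538883	20.718083	20.772117	20.843462
P035	23.565905	23.699102	23.771359	23.573719	23.619207	23.422843	23.690474	23.494899
P036	22.237569	22.198578	22.346335	22.165005	21.928998	21.848255	21.985792	22.07228
P037	23.345001	23.332208	23.428379	23.310942	22.911899	23.225894	22.929864	23.405071
P038	27.990739	28.261338	27.969077	28.032022	27.82186	27.946108	27.850564	28.075008
P039	28.28631	27.992409	27.791676	27.933118	28.145575	28.188763	27.733737	28.397909
P040	22.146216	22.318238	22.843764	22.757682	22.329155	22.059072	22.373888	22.468065
P041	24.446217	24.629511	24.349683	24.342465	24.086136	24.360511	24.802544	24.460342
P042	23.310196	23.006709	23.241712	22.930407	24.36891	24.452672	24.361529	24.147966
P043	23.446773	23.969486	23.479892	23.749317	23.684897	23.904785	23.704079	23.474778
P044	27.639491	26.951256	27.335228	27.404519	27.03468	27.119845	26.916411	27.314902
P045	26.159094	25.991844	25.678601	26.031512	27.535817	27.202214	27.508161	27.666007
P046	24.011763	24.228599	24.09396	24.213718	24.550366	24.045691	24.122048	24.08455
P047	23.196399	23.326886	23.411803	23.261603	23.379189	23.104326	23.090549	23.289888
P048	20.287555	20.370229	20.426688	20.353685	20.228078	20.496534	20.085978	20.541346
P049	26.113788	25.688276	25.634306	26.393192	26.179101	25.417295	25.834547	26.124003
P050	29.575633	29.33688	29.627969	29.236827	29.524019	29.200541	28.992476	29.917671
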