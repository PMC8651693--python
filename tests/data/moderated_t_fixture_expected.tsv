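feature	logFC	t	df_total	p	q
P001	 5.69004999999976e-02	 2.70081057132676e-01	1.9053465754226e+01	7.90001533149729e-01	9.78016474240441e-01
P002	 7.16489999999993e-01	 3.69393508638563e+00	1.9053465754226e+01	1.53497658822387e-03	1.53497658822387e-02
P003	-1.33699750000002e-01	-8.14275647681387e-01	1.9053465754226e+01	4.25547575740319e-01	9.78016474240441e-01
P004	 1.29023249999999e-01	 7.24324299688924e-01	1.9053465754226e+01	4.77667342351698e-01	9.78016474240441e-01
P005	 1.26906850000000e+00	 7.73885759264893e+00	1.9053465754226e+01	2.68308987544401e-07	3.35386234430501e-06
P006	 2.78757499999968e-02	 1.83129991961658e-01	1.9053465754226e+01	8.56630668151151e-01	9.78016474240441e-01
P007	-1.73645000000014e-02	-1.30565650429949e-01	1.9053465754226e+01	8.97487589266237e-01	9.78016474240441e-01
P008	 2.14224999999444e-03	 1.46593270229423e-02	1.9053465754226e+01	9.88456381498773e-01	9.88456381498773e-01
P009	-9.46822500000017e-02	-6.30096443558164e-01	1.9053465754226e+01	5.36115680809464e-01	9.78016474240441e-01
P010	-1.90987500000006e-02	-1.39637512010968e-01	1.9053465754226e+01	8.90411884599803e-01	9.78016474240441e-01
P011	-8.81847500000029e-02	-5.64150948860468e-01	1.9053465754226e+01	5.79232356651523e-01	9.78016474240441e-01
P012	 1.32130000000005e-02	 9.08205151890035e-02	1.9053465754226e+01	9.28583208043986e-01	9.78016474240441e-01
P013	-1.16641999999999e-01	-7.62728917761787e-01	1.9053465754226e+01	4.54965071333524e-01	9.78016474240441e-01
P014	-2.00499999999999e-01	-1.51930971659898e+00	1.9053465754226e+01	1.45104764939200e-01	6.04603187246665e-01
P015	-9.03020000000054e-02	-6.37986570167844e-01	1.9053465754226e+01	5.31075955990325e-01	9.78016474240441e-01
P016	 1.42794350000000e+00	 8.92160899650258e+00	1.9053465754226e+01	3.12493954811193e-08	7.52693267792871e-07
P017	-1.09808500000004e-01	-7.25030780765183e-01	1.9053465754226e+01	4.77243750594100e-01	9.78016474240441e-01
P018	-4.14592750000002e-01	-2.74325680889235e+00	1.9053465754226e+01	1.29003481595031e-02	1.07502901329193e-01
P019	 1.46627499999996e-01	 1.06034339562338e+00	1.9053465754226e+01	3.02245419028081e-01	9.61315507124627e-01
P020	 2.41979999999995e-01	 1.54378801443711e+00	1.9053465754226e+01	1.39086446016473e-01	6.04603187246665e-01
P021	 8.37657499999951e-02	 4.43273196698503e-01	1.9053465754226e+01	6.62560337679497e-01	9.78016474240441e-01
P022	-5.01302500000014e-02	-3.79504432427669e-01	1.9053465754226e+01	7.08509993578169e-01	9.78016474240441e-01
P023	-3.17807499999998e-01	-2.02465301621504e+00	1.9053465754226e+01	5.71489401286304e-02	3.57180875803940e-01
P024	-1.33185500000001e-01	-9.53902424451227e-01	1.9053465754226e+01	3.52079302416930e-01	9.78016474240441e-01
P025	-3.00265000000043e-02	-2.33599553585076e-01	1.9053465754226e+01	8.17787314996737e-01	9.78016474240441e-01
P026	-5.53677500000035e-02	-3.66667642386015e-01	1.9053465754226e+01	7.17907269846800e-01	9.78016474240441e-01
P027	 1.14544750000000e-01	 7.38941161433415e-01	1.9053465754226e+01	4.68948731165285e-01	9.78016474240441e-01
P028	 1.50987499999970e-02	 9.67993810084267e-02	1.9053465754226e+01	9.23896675429528e-01	9.78016474240441e-01
P029	-4.10597500000000e-02	-3.05117271899454e-01	1.9053465754226e+01	7.63584884740570e-01	9.78016474240441e-01
P030	-8.63825000000365e-03	-5.27806419601076e-02	1.9053465754226e+01	9.58456144755632e-01	9.78016474240441e-01
P031	-1.99418500000000e-01	-1.14868519105631e+00	1.9053465754226e+01	2.64902711043972e-01	9.46081110871329e-01
P032	-9.26500000000588e-03	-6.75187017209441e-02	1.9053465754226e+01	9.46872273881173e-01	9.78016474240441e-01
P033	 6.40822499999981e-02	 3.82280906485759e-01	1.9053465754226e+01	7.06483681114074e-01	9.78016474240441e-01
P034	-1.48529999999990e-02	-1.02010322843820e-01	1.9053465754226e+01	9.19814400161493e-01	9.78016474240441e-01
P035	 9.56654999999946e-02	 7.27539938935168e-01	1.9053465754226e+01	4.75741106503994e-01	9.78016474240441e-01
P036	 2.78040499999998e-01	 2.16129273739252e+00	1.9053465754226e+01	4.36096542160913e-02	3.11497530114938e-01
P037	 2.35950499999998e-01	 1.66508820366401e+00	1.9053465754226e+01	1.12253137570268e-01	6.04603187246665e-01
P038	 1.39908999999995e-01	 1.04829056635222e+00	1.9053465754226e+01	3.07620962279881e-01	9.61315507124627e-01
P039	-1.15617750000003e-01	-7.33420286658215e-01	1.9053465754226e+01	4.72230580916387e-01	9.78016474240441e-01
P040	 2.08929999999996e-01	 1.27741649466997e+00	1.9053465754226e+01	2.16801970028973e-01	8.33853730880664e-01
P041	 1.45857499999990e-02	 9.48205152794429e-02	1.9053465754226e+01	9.25447501637791e-01	9.78016474240441e-01
P042	-1.21051325000000e+00	-8.71183805621975e+00	1.9053465754226e+01	4.51615960675722e-08	7.52693267792871e-07
P043	-3.07677499999995e-02	-2.04851221978302e-01	1.9053465754226e+01	8.39860864651967e-01	9.78016474240441e-01
P044	 2.36163999999993e-01	 1.52439506986428e+00	1.9053465754226e+01	1.43837024525626e-01	6.04603187246665e-01
P045	-1.51278700000000e+00	-1.02762694042484e+01	1.9053465754226e+01	3.29095495267208e-09	1.64547747633604e-07
P046	-6.36537500000029e-02	-4.44031819776099e-01	1.9053465754226e+01	6.62021426299888e-01	9.78016474240441e-01
P047	 8.31847499999981e-02	 6.26854522403717e-01	1.9053465754226e+01	5.38193936347330e-01	9.78016474240441e-01
P048	 2.15552499999958e-02	 1.54970244082825e-01	1.9053465754226e+01	8.78474662746218e-01	9.78016474240441e-01
P049	 6.86540000000004e-02	 3.65925849826699e-01	1.9053465754226e+01	7.18451734550869e-01	9.78016474240441e-01
P050	 3.56504999999967e-02	 2.02609701891678e-01	1.9053465754226e+01	8.41587939641523e-01	9.78016474240441e-01
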