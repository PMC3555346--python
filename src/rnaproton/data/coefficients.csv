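base,atom,const,pre_a,pre_c,pre_g,pre_gu,pre_ug,suc_a,suc_c,suc_g,suc_gu,suc_ug,5ter,3ter,3loop,5loop,GU,corr,rms,nobs,xcorr,xrms,ntrim
A,H2,7.0299,0.6672,0.2521,0.6899,0.7637,0.2555,-0.5934,0.0658,0.2814,-0.3321,0.0804,0.1558,0,0.0274,0.0622,0,0.9868,0.0562,162,0.9845,0.0608,1
A,H8,8.1525,-0.4169,-0.1145,-0.3709,-0.3808,0.2107,-0.1006,0.0379,-0.0723,0.0458,-0.0261,0.3206,0,-0.0175,0.08,0,0.9535,0.0575,157,0.9406,0.065,0
G,H8,7.7036,-0.5622,-0.1595,-0.497,-0.5083,0.2215,-0.0383,0.0562,-0.0265,0.0369,-0.0671,0.3563,-0.0607,-0.0253,0.0332,-0.0529,0.9655,0.0658,288,0.9612,0.0697,2
C,H5,5.6724,-0.4611,-0.1625,-0.4304,-0.2815,0.0377,-0.0222,-0.0368,-0.0249,-0.032,-0.0958,0.1245,-0.016,-0.0205,0.01,0,0.9674,0.0478,256,0.9635,0.0505,5
U,H5,5.5639,-0.5133,-0.1778,-0.5018,-0.3641,-0.0469,0.0333,0.0165,0,0.0348,0.047,0,0,0,0.0216,0.2747,0.9692,0.0537,178,0.9623,0.0594,0
C,H6,7.8627,-0.3901,-0.0867,-0.2215,-0.2059,0.085,-0.0253,0.0363,-0.0288,-0.0833,-0.1132,0.2326,-0.0359,-0.0428,0.0311,0,0.9332,0.0558,260,0.9249,0.0591,0
U,H6,7.9946,-0.3643,-0.1083,-0.2523,-0.3392,0.0832,-0.0402,0.0332,-0.0555,-0.0809,-0.0457,0,-0.0287,-0.0341,0.0268,-0.0412,0.9444,0.0446,172,0.9331,0.0489,4
A,H1',5.9905,-0.1042,-0.05,0,-0.0639,0,-0.0823,0,-0.0324,0.0528,-0.0353,0.0966,0,-0.0173,0.0061,0,0.8476,0.0332,157,0.7905,0.0384,0
G,H1',5.7539,-0.1822,-0.0584,-0.019,-0.068,-0.0373,0,0.0216,0.0198,0.0777,0,0.1435,-0.0376,0,0,0,0.9278,0.0415,284,0.9209,0.0434,3
C,H1',5.56,-0.1805,-0.0825,-0.0446,-0.0492,0.039,-0.0226,-0.0139,0.0134,0.0711,-0.0224,0.1351,0.0114,-0.0168,0.0121,0,0.8355,0.0427,253,0.7872,0.0482,5
U,H1',5.6203,-0.1679,-0.0865,-0.1049,-0.1992,0.0234,-0.0405,0.0097,0.0196,0.0571,0.0328,0,0.0183,0.0145,0.0403,-0.0316,0.7411,0.053,172,0.6451,0.0609,1
A,H2',4.4575,-0.0269,0.0268,0.0309,-0.0499,0.1174,0.1041,0.0496,0.1613,0.1416,0.1044,0.0702,0,-0.0115,0.0291,0,0.7512,0.0618,143,0.6531,0.0714,0
G,H2',4.4582,-0.0666,0.0389,0,0,0.0794,0.1367,0.0248,0.1286,0.0705,0.1022,0.074,-0.1122,-0.0326,-0.0257,0.1211,0.8675,0.0516,246,0.8359,0.057,2
C,H2',4.3454,-0.1298,0.0188,0.0499,-0.0867,0.0363,0.1475,0,0.1557,0.1724,0.1198,0.085,-0.1316,0,0,0,0.9014,0.0589,217,0.8774,0.0654,4
U,H2',4.4078,-0.0599,0.0404,0.0658,-0.0445,0.0618,0.0807,0.059,0.174,0.1431,0.1691,0,-0.229,-0.0488,-0.03,-0.3095,0.92,0.0609,146,0.8999,0.0679,2
A,H3',4.6788,-0.1275,-0.0229,-0.0794,-0.083,0.0436,-0.0377,0.006,0.0105,0.0593,0.0283,0.0235,0,-0.0248,0.0202,0,0.5997,0.064,129,0.4933,0.0708,0
G,H3',4.5076,-0.1292,-0.029,-0.0537,-0.1527,0.0644,0.0445,0.0459,0.0333,0.0674,-0.0887,0.1061,-0.0416,-0.0146,0.0244,-0.1527,0.7307,0.0807,226,0.6391,0.0914,3
C,H3',4.4794,-0.1336,-0.0189,-0.0431,0.0221,0.0364,0.0498,-0.0147,0.0454,-0.043,-0.1182,0.1326,-0.0178,0.0096,-0.0224,0,0.7442,0.062,191,0.6942,0.0669,4
U,H3',4.495,-0.119,-0.0065,-0.0447,0.0458,0.0506,0.1024,0.0229,0.0657,0.0839,-0.0268,0,-0.0432,-0.0187,0.0159,0.0266,0.7047,0.0482,121,0.5928,0.0552,2
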