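name,n,type,q,z1,z2,y1,x1,mu,sigma,epsilon,provenance
gas_exp/3,3,a,0.2202,—,0.9284,1.2727,—,1.964,3.3320,0.7113,reference-tables/rigid/gas-exp-3
gas_exp/4,4,b,1.9094,0.3351,0.4601,0.4322,—,2.293,3.2999,0.7196,reference-tables/rigid/gas-exp-4
gas_exp/5,5,c,0.8633,0.1862,0.4723,0.6179,0.1773,2.373,3.2945,0.7740,reference-tables/rigid/gas-exp-5
gas_qm/3,3,a,0.2217,—,0.9039,1.2486,—,1.925,3.2999,0.7573,reference-tables/rigid/gas-qm-3
gas_qm/4,4,b,1.4346,0.3073,0.4698,0.4908,—,2.239,3.2910,0.7071,reference-tables/rigid/gas-qm-4
gas_qm/5,5,c,0.9194,0.2184,0.4769,0.5989,0.1314,2.283,3.2749,0.7782,reference-tables/rigid/gas-qm-5
liquid_mp2_4mm/3,3,a,0.2261,—,0.9795,1.3413,—,2.127,3.3854,0.7448,reference-tables/rigid/liquid-3
liquid_mp2_4mm/4,4,b,2.7937,0.3679,0.4615,0.3815,—,2.512,3.3516,0.7364,reference-tables/rigid/liquid-4
liquid_mp2_4mm/5,5,c,0.5833,0.0234,0.5076,0.7632,0.3386,2.713,3.3801,0.7699,reference-tables/rigid/liquid-5
tip3p,3,a,0.4170,—,0.5859,0.7570,—,2.35,3.1506,0.6364,reference-tables/rigid/tip3p
opc3,3,a,0.4476,—,0.5652,0.7992,—,2.43,3.1743,0.6837,reference-tables/rigid/opc3
opc,4,b,0.6791,0.1594,0.5395,0.6856,—,2.48,3.1666,0.8904,reference-tables/rigid/opc
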