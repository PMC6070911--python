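gene	day1	day2	day3	day5
asm10	0.09675340098026626	0.9759050329202371	3.1164953348817064	102.86502452813103
asm30	40.46995703941183	290.88433514378926	664.7670607641095	22467.167005726118
peg.1001	283.7559362164888	20.92798959474815	10.498195353654081	1.9285592570219299
peg.1006	0.14289803744421714	1.2240992430363544	5.7106925842183776	276.0231153711958
peg.1007	768.2973554563087	396.78163921381247	509.9589865734158	568.3627865957423
peg.1011	0.5664132194329504	4.295389791907016	18.51345955909397	907.5546186268252
peg.1014	5.458295662943357	44.32564052705783	205.06773125046982	7438.0488074859895
peg.1036	0.350355858405413	3.280186011698399	16.17930089590944	800.669985813357
peg.1040	81.62742839165871	11.64213503306434	2.6208686291269636	0.5611060849690181
peg.1055	1435.2659765061028	1585.2278913167354	1432.0026538143097	1168.7749820163215
peg.1061	159.90612094656828	34.41960324389525	11.191439372339536	1.5611205481755157
peg.1066	631.2695785561356	649.5588304038523	350.08569995018956	386.7367334006448
peg.1069	11.514470339967817	4.133958760011541	0.5637728052274902	0.1805163019092039
peg.1072	1281.057665733583	1124.6357170841234	867.0049833894107	349.61325566924256
peg.1073	949.3509087873261	992.8383073352427	578.2116689320316	1135.4191074591674
peg.1081	39.63420297782304	511.8887937268795	1471.5398218571763	105761.88459295503
peg.1084	1.6010639359347174	13.829432147820013	41.866255382489534	1583.5103167832967
peg.1090	37.227870609708965	368.89687538801223	748.0902241787171	62287.56078612325
peg.1091	810.0728775464323	421.43800454875867	364.59831068097435	462.76455962197673
peg.1092	1029.7649913675348	781.9814951938747	590.5513479415117	547.7439999828442
peg.1093	1173.0274743732994	788.2755319147449	568.3624819257399	962.7782131284783
peg.1100	501.35746556061423	112.21595119181642	12.645755210150766	6.972546242156109
peg.1106	850.5788905677405	764.4292706136536	787.1407365228175	861.6644344358209
peg.1112	0.12088012205879682	0.785071188286786	3.0497713554809516	134.32812114944187
peg.1117	50.948319152146276	323.66459847114976	773.3667537943752	45576.680427932835
peg.1118	3.1062872599811757	0.7715657315737002	0.16054356750760934	0.03494916223831311
peg.1120	52.04745195800156	8.021394752750735	2.856200177765387	0.4782059075403769
peg.1124	57.39865228960852	425.74160800735814	556.0996948838923	65383.37676818507
peg.1127	628.0212962493273	587.2893345333432	558.3071749656134	517.364682492308
peg.1132	376.92257057463615	613.1212168441898	471.56186508842546	783.7267818223713
peg.1137	805.9394848320295	578.7039133862583	606.9332366555914	665.7985877448745
peg.1139	430.0417811757105	57.09606352589555	11.013095545362148	1.9136966484684867
peg.1140	899.7932296649266	797.230929650929	824.876187390174	1442.1121035870387
peg.1143	945.2689208220015	560.0737800400352	1358.7560413232288	1030.924391223531
peg.1146	0.1791918867811241	1.8604866714890549	5.923227929759195	254.7884736048492
peg.1153	610.390040330202	1228.5962759288386	478.38514033476787	751.2696310928628
peg.1154	74.87089532416051	18.456935964282714	3.8560700441451163	0.8979800680896813
peg.1158	639.5518811757065	1063.310204561097	737.9067523677437	543.9855217467825
peg.1159	359.21734662211975	699.9504366515635	471.40229177179106	415.2152819899643
peg.1160	670.4140097760194	785.0124562327939	769.3556921495016	998.318610909534
peg.1161	0.16009250629458968	0.9511520077720642	7.185205288736263	294.1060837787979
peg.1164	73.14410857017316	4.110961336035475	1.3281886155752647	0.21453677483849795
peg.1166	1250.2960701714812	818.2568610730893	1488.4623749106806	555.0585592962291
peg.1169	887.6146270887682	1059.5944062862322	845.2779389318416	676.079759170738
peg.1172	1317.0709391843934	487.28917263043115	258.0093488390116	367.3280914834822
peg.1173	4.518820044118627	63.16995799500691	212.76117681596085	6018.712726091473
peg.1180	639.3949716039389	665.5936953821332	500.0255696447089	1054.437398834647
peg.1181	481.35687033389627	467.6182056130312	371.49532401516484	446.6499380174091
peg.1192	19.722222561731392	6.149583591566109	1.0018538683689404	0.35902430898049476
peg.1199	2.6619854459580186	0.24995296309165327	0.05598875292826876	0.03375688390690017
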