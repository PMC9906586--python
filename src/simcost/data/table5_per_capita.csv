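jurisdiction,sim_pc_1999_2000,sim_pc_2018_2019,sim_pct_change,suicide_pc_1999_2000,suicide_pc_2018_2019,suicide_pct_change
Alabama,1689,3186,89,1382,1763,28
Alaska,3220,5112,59,2385,3245,36
Arizona,2439,4271,75,1621,2008,24
Arkansas,1752,3203,83,1390,1967,41
California,1487,2378,60,937,1151,23
Colorado,2267,4050,79,1571,2515,60
Connecticut,1735,4076,135,906,1193,32
Delaware,1797,5351,198,1224,1256,3
District of Columbia,1488,3962,166,542,781,44
Florida,1788,3591,101,1283,1545,20
Georgia,1492,2742,84,1175,1606,37
Hawaii,1734,2702,56,1270,1506,19
Idaho,1780,3537,99,1445,2344,62
Illinois,1498,3120,108,897,1220,36
Indiana,1477,4006,171,1218,1654,36
Iowa,1256,2579,105,1114,1750,57
Kansas,1568,3165,102,1315,2084,58
Kentucky,1831,4635,153,1351,1838,36
Louisiana,1655,3986,141,1235,1630,32
Maine,1769,4525,156,1427,2009,41
Maryland,2153,4877,127,947,1113,17
Massachusetts,1471,4050,175,730,1039,42
Michigan,1506,3831,154,1089,1595,46
Minnesota,1226,2673,118,1025,1536,50
Mississippi,1425,2566,80,1162,1516,30
Missouri,1765,4414,150,1383,2063,49
Montana,2189,3773,72,1877,2773,48
Nebraska,1416,2215,56,1233,1591,29
Nevada,3128,3817,22,2166,2148,-1
New Hampshire,1492,4973,233,1215,2028,67
New Jersey,1349,3882,188,714,892,25
New Mexico,3233,5249,62,2027,2698,33
New York,1069,2589,142,672,917,37
North Carolina,1689,3409,102,1295,1421,10
North Dakota,1365,3088,126,1229,2154,75
Ohio,1385,4890,253,1036,1642,59
Oklahoma,2061,3682,79,1644,2204,34
Oregon,1954,3216,65,1477,2134,44
Pennsylvania,1917,4681,144,1163,1555,34
Rhode Island,1508,3808,153,928,1088,17
South Carolina,1585,3679,132,1171,1726,47
South Dakota,1681,3105,85,1536,2301,50
Tennessee,1904,4423,132,1421,1818,28
Texas,1515,2400,58,1105,1495,35
Utah,2422,4014,66,1558,2453,57
Vermont,1638,4050,147,1215,1900,56
Virginia,1617,3047,89,1191,1468,23
Washington,2192,3053,39,1420,1715,21
West Virginia,1800,6534,263,1408,2113,50
Wisconsin,1547,3290,113,1249,1576,26
Wyoming,2273,4030,77,1978,2895,46
UNITED STATES,1638,3413,108,1137,1534,35
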