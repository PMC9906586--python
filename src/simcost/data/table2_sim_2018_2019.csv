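jurisdiction,count,rate_per_100k,medical,work_loss,qol_loss,total
Alabama,1410,28.8,8.8,4087.4,11499.3,15595.6
Alaska,313,42.7,1.5,1015.9,2737.4,3754.8
Arizona,2825,39.1,16.0,8108.9,22736.0,30860.9
Arkansas,867,28.7,4.2,2548.8,7105.9,9658.9
California,8920,22.6,45.5,24179.4,69776.9,94001.8
Colorado,2057,35.9,11.0,6139.5,17041.9,23192.3
Connecticut,1321,37.0,6.9,3828.3,10711.2,14546.3
Delaware,444,45.7,2.8,1401.8,3788.4,5193.1
District of Columbia,281,39.9,2.1,678.2,2109.2,2789.4
Florida,7265,34.0,45.0,19810.0,56957.2,76812.2
Georgia,2640,25.0,13.5,7567.0,21395.5,28975.9
Hawaii,371,26.2,2.9,974.9,2854.6,3832.4
Idaho,577,32.6,2.9,1624.2,4635.8,6262.8
Illinois,3577,28.1,20.5,10406.2,29221.4,39648.2
Indiana,2357,35.1,14.7,7134.8,19735.6,26885.2
Iowa,738,23.4,4.8,2151.3,5983.2,8139.4
Kansas,816,28.0,4.6,2441.1,6770.7,9216.4
Kentucky,1845,41.3,10.2,5445.4,15254.5,20710.1
Louisiana,1658,35.6,9.4,4900.1,13644.5,18554.0
Maine,559,41.7,1.9,1596.2,4471.5,6069.7
Maryland,2667,44.1,14.1,7724.9,21740.7,29479.7
Massachusetts,2445,35.4,12.4,7479.6,20443.2,27935.2
Michigan,3467,34.7,18.7,9990.2,28265.3,38274.2
Minnesota,1333,23.7,7.8,3978.4,11050.1,15036.4
Mississippi,705,23.7,3.1,1991.6,5654.7,7649.3
Missouri,2402,39.2,11.1,7166.3,19886.2,27063.6
Montana,371,34.8,1.5,1039.8,2978.5,4019.8
Nebraska,398,20.6,1.8,1105.9,3171.0,4278.7
Nevada,1128,36.9,6.4,2948.8,8713.8,11669.0
New Hampshire,592,43.6,2.3,1811.0,4940.8,6754.2
New Jersey,3037,34.1,16.3,9223.4,25288.9,34528.7
New Mexico,994,47.4,4.9,2886.3,8111.3,11002.4
New York,4565,23.4,25.3,13276.0,37179.1,50480.4
North Carolina,3150,30.2,18.2,9447.2,26114.5,35580.0
North Dakota,202,26.5,1.1,630.3,1719.0,2350.4
Ohio,5028,43.0,30.4,15179.7,41955.0,57165.1
Oklahoma,1331,33.7,6.9,3776.4,10759.0,14542.3
Oregon,1285,30.6,5.5,3469.4,10043.8,13518.7
Pennsylvania,5341,41.7,26.6,15873.1,44041.8,59941.5
Rhode Island,366,34.6,2.6,1064.0,2963.5,4030.1
South Carolina,1698,33.2,9.3,4940.4,13873.6,18823.3
South Dakota,234,26.5,0.9,732.7,2009.1,2742.7
Tennessee,2711,39.9,17.1,7846.8,22213.7,30077.6
Texas,6236,21.6,37.1,18246.1,50965.1,69248.3
Utah,1098,34.5,5.2,3414.5,9359.9,12779.5
Vermont,230,36.7,1.0,663.2,1867.5,2531.7
Virginia,2327,27.3,12.6,6861.6,19109.6,25983.9
Washington,2163,28.6,12.4,5953.5,17164.0,23130.0
West Virginia,1036,57.6,5.4,3117.1,8632.3,11754.9
Wisconsin,1727,29.7,10.0,5015.9,14114.0,19139.8
Wyoming,218,37.7,1.1,605.6,1724.0,2330.6
UNITED STATES,101325,30.9,558.4,293499.3,824484.0,1118541.7
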