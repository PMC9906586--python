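jurisdiction,count,rate_per_100k,medical,work_loss,qol_loss,total
Alabama,814,16.6,4.9,2249.2,6378.7,8632.3
Alaska,197,26.8,0.9,652.0,1730.7,2383.5
Arizona,1429,19.8,6.8,3725.6,10774.5,14506.9
Arkansas,551,18.3,2.2,1557.5,4371.7,5931.4
California,4464,11.3,20.2,11659.4,33836.9,45516.5
Colorado,1297,22.6,6.4,3805.9,10589.6,14402.0
Connecticut,427,12.0,2.0,1059.2,3195.2,4256.5
Delaware,112,11.5,0.5,318.5,899.6,1218.6
District of Columbia,49,7.0,0.3,143.9,405.8,550.0
Florida,3516,16.4,18.9,8079.3,24939.5,33037.7
Georgia,1577,14.9,7.3,4437.7,12527.9,16972.9
Hawaii,200,14.1,1.2,563.4,1571.6,2136.2
Idaho,391,22.1,1.8,1076.5,3072.2,4150.5
Illinois,1464,11.5,7.5,4004.6,11484.2,15496.3
Indiana,1026,15.3,5.2,2909.9,8186.9,11102.0
Iowa,509,16.1,3.0,1459.4,4059.3,5521.8
Kansas,540,18.5,2.7,1624.3,4441.4,6068.5
Kentucky,778,17.4,3.6,2132.1,6076.6,8212.3
Louisiana,712,15.3,3.5,1979.2,5605.7,7588.4
Maine,273,20.4,1.0,678.9,2014.9,2694.8
Maryland,654,10.8,3.0,1720.0,5002.9,6725.8
Massachusetts,694,10.1,3.1,1816.5,5349.6,7169.1
Michigan,1510,15.1,7.7,4132.7,11792.9,15933.4
Minnesota,785,13.9,4.1,2282.0,6353.3,8639.4
Mississippi,429,14.4,1.7,1178.6,3338.5,4518.8
Missouri,1186,19.3,4.9,3298.5,9344.8,12648.2
Montana,277,26.0,0.9,761.8,2192.2,2954.8
Nebraska,290,15.0,1.2,799.9,2272.3,3073.4
Nevada,650,21.2,3.0,1666.7,4896.5,6566.2
New Hampshire,267,19.7,0.9,705.1,2047.9,2753.9
New Jersey,770,8.7,4.0,2009.6,5917.6,7931.2
New Mexico,525,25.0,2.4,1473.6,4178.6,5654.7
New York,1714,8.8,8.4,4589.7,13280.2,17878.3
North Carolina,1426,13.7,7.0,3804.3,11017.1,14828.4
North Dakota,142,18.6,0.7,439.0,1199.4,1639.1
Ohio,1822,15.6,10.9,4978.6,14205.5,19194.9
Oklahoma,803,20.3,3.4,2285.8,6415.2,8704.4
Oregon,875,20.8,3.1,2282.4,6685.7,8971.2
Pennsylvania,1955,15.3,8.7,5071.0,14834.3,19914.0
Rhode Island,115,10.8,0.7,291.1,860.0,1151.8
South Carolina,832,16.3,4.2,2305.8,6521.1,8831.1
South Dakota,175,19.8,0.6,543.2,1489.0,2032.8
Tennessee,1190,17.5,6.5,3171.4,9185.7,12363.6
Texas,3911,13.6,21.9,11392.6,31702.0,43116.6
Utah,660,20.7,2.8,2124.2,5682.5,7809.5
Vermont,118,18.8,0.4,301.2,886.2,1187.9
Virginia,1192,14.0,6.3,3224.7,9286.6,12517.5
Washington,1258,16.6,5.8,3317.5,9665.2,12988.6
West Virginia,363,20.2,1.7,987.1,2811.8,3800.6
Wisconsin,867,14.9,4.4,2375.3,6788.5,9168.2
Wyoming,159,27.4,0.7,437.4,1236.1,1674.2
UNITED STATES,47928,14.6,235.1,129883.8,372602.0,502720.9
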