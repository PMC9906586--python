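jurisdiction,count,rate_per_100k,medical,work_loss,qol_loss,total
Alabama,684,15.4,3.6,1996.3,5494.7,7494.6
Alaska,160,25.5,0.5,554.9,1459.5,2015.0
Arizona,1115,22.0,8.6,3351.6,9024.0,12384.2
Arkansas,425,16.0,2.6,1249.7,3412.2,4664.6
California,4590,13.6,24.9,13375.2,36695.6,50095.7
Colorado,839,19.7,4.2,2631.6,7030.8,9666.6
Connecticut,515,15.2,2.8,1614.9,4273.6,5891.3
Delaware,120,15.4,0.7,385.6,1014.3,1400.6
District of Columbia,75,13.2,0.6,229.7,619.5,849.8
Florida,2715,17.1,15.1,7456.4,20900.7,28372.2
Georgia,1074,13.2,6.2,3256.9,8846.8,12109.9
Hawaii,184,15.2,1.0,575.5,1523.0,2099.5
Idaho,211,16.4,1.2,604.6,1680.9,2286.7
Illinois,1608,13.0,8.8,5105.7,13443.4,18557.8
Indiana,785,12.9,5.4,2450.4,6498.2,8954.0
Iowa,332,11.4,1.8,989.0,2678.7,3669.5
Kansas,369,13.7,2.5,1146.3,3058.5,4207.3
Kentucky,653,16.2,4.2,2009.7,5364.1,7378.0
Louisiana,645,14.5,4.0,2011.6,5372.6,7388.2
Maine,199,15.6,0.9,613.6,1633.1,2247.7
Maryland,966,18.3,4.7,3145.6,8209.1,11359.4
Massachusetts,777,12.3,4.8,2568.1,6743.3,9316.2
Michigan,1320,13.3,7.4,4041.6,10882.9,14931.9
Minnesota,522,10.7,2.7,1653.2,4345.6,6001.5
Mississippi,362,12.8,2.3,1084.9,2955.8,4043.0
Missouri,874,15.7,5.1,2667.6,7172.0,9844.7
Montana,184,20.4,0.8,521.9,1447.2,1969.9
Nebraska,212,12.4,1.3,657.9,1758.6,2417.8
Nevada,562,28.6,2.2,1642.2,4506.0,6150.5
New Hampshire,162,13.2,0.7,501.6,1331.3,1833.6
New Jersey,985,11.7,5.5,3103.6,8205.9,11315.0
New Mexico,499,27.5,2.8,1623.6,4236.2,5862.6
New York,1788,9.4,10.6,5508.3,14720.6,20239.5
North Carolina,1191,14.9,7.2,3647.2,9859.4,13513.9
North Dakota,78,12.2,0.5,238.2,639.5,878.1
Ohio,1429,12.6,8.4,4225.0,11483.1,15716.6
Oklahoma,617,17.9,4.1,1936.2,5159.0,7099.4
Oregon,621,18.2,3.1,1766.4,4890.4,6659.9
Pennsylvania,2066,16.8,11.2,6426.3,17092.1,23529.6
Rhode Island,135,12.9,0.6,427.9,1146.0,1574.5
South Carolina,569,14.3,3.1,1693.9,4632.6,6329.6
South Dakota,109,14.4,0.6,350.1,914.1,1264.8
Tennessee,959,16.9,6.8,2901.9,7873.6,10782.3
Texas,2721,13.1,17.3,8519.4,22835.6,31372.3
Utah,442,19.9,2.4,1499.9,3871.1,5373.3
Vermont,91,15.0,0.3,269.5,724.1,993.9
Virginia,1022,14.5,5.8,3059.1,8314.2,11379.2
Washington,1150,19.6,7.3,3457.8,9397.5,12862.7
West Virginia,298,16.4,1.8,869.9,2386.3,3258.0
Wisconsin,727,13.6,3.8,2240.9,6027.1,8271.8
Wyoming,104,21.0,0.5,293.3,826.0,1119.9
UNITED STATES,40834,14.6,235.8,124152.5,334610.6,458998.9
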