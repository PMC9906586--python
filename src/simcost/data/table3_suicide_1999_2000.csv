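jurisdiction,count,rate_per_100k,medical,work_loss,qol_loss,total
Alabama,569,12.8,2.5,1634.2,4496.7,6133.3
Alaska,117,18.6,0.4,417.4,1075.0,1492.8
Arizona,775,15.3,5.5,2180.6,6046.5,8232.6
Arkansas,343,12.9,1.9,989.4,2710.6,3701.9
California,3023,9.0,15.3,8292.9,23243.2,31551.4
Colorado,594,13.9,2.6,1815.8,4880.1,6698.5
Connecticut,289,8.5,1.5,812.0,2262.7,3076.2
Delaware,84,10.8,0.5,261.8,691.5,953.8
District of Columbia,27,4.6,0.2,85.3,224.3,309.8
Florida,2058,13.0,10.8,5240.2,15114.5,20365.4
Georgia,860,10.6,4.6,2558.0,6971.9,9534.5
Hawaii,137,11.3,0.8,423.8,1113.2,1537.9
Idaho,174,13.5,0.9,491.9,1363.4,1856.1
Illinois,1012,8.2,5.4,3004.2,8105.9,11115.5
Indiana,656,10.8,4.1,2017.1,5362.6,7383.7
Iowa,297,10.2,1.5,878.4,2375.9,3255.8
Kansas,312,11.6,2.1,960.2,2566.7,3529.0
Kentucky,496,12.3,3.1,1475.0,3966.7,5444.7
Louisiana,493,11.0,2.9,1495.5,4017.0,5515.4
Maine,165,12.9,0.7,489.3,1323.2,1813.2
Maryland,455,8.6,2.2,1340.1,3655.0,4997.2
Massachusetts,409,6.5,2.0,1240.1,3382.5,4624.6
Michigan,974,9.8,4.7,2919.5,7880.1,10804.3
Minnesota,439,9.0,1.9,1382.9,3635.8,5020.7
Mississippi,299,10.5,1.9,885.2,2410.1,3297.1
Missouri,700,12.5,3.8,2075.7,5638.0,7717.5
Montana,160,17.8,0.7,447.4,1241.3,1689.4
Nebraska,185,10.8,1.0,574.1,1531.4,2106.6
Nevada,402,20.4,1.5,1129.9,3128.7,4260.1
New Hampshire,134,10.9,0.5,404.2,1088.3,1493.0
New Jersey,562,6.7,2.9,1585.7,4396.7,5985.4
New Mexico,323,17.8,1.6,1001.1,2672.8,3675.5
New York,1164,6.1,6.2,3411.0,9298.7,12715.9
North Carolina,928,11.6,5.3,2780.6,7569.8,10355.7
North Dakota,71,11.0,0.4,213.9,576.5,790.8
Ohio,1095,9.7,6.1,3138.2,8606.9,11751.2
Oklahoma,495,14.4,3.2,1545.1,4113.4,5661.7
Oregon,486,14.2,2.2,1317.8,3713.8,5033.7
Pennsylvania,1320,10.8,6.5,3823.8,10447.9,14278.2
Rhode Island,86,8.2,0.4,264.0,704.6,969.0
South Carolina,431,10.8,2.1,1240.8,3433.6,4676.4
South Dakota,99,13.2,0.5,321.3,834.5,1156.3
Tennessee,728,12.9,4.8,2163.6,5881.2,8049.6
Texas,2029,9.8,11.9,6179.8,16682.7,22874.5
Utah,290,13.1,1.6,954.6,2500.9,3457.2
Vermont,70,11.5,0.2,197.6,539.2,737.1
Virginia,780,11.1,4.1,2216.2,6165.5,8385.8
Washington,772,13.1,4.6,2222.4,6105.8,8332.8
West Virginia,237,13.1,1.3,676.1,1870.4,2547.8
Wisconsin,592,11.1,2.7,1806.8,4869.1,6678.6
Wyoming,91,18.4,0.4,256.0,718.5,974.9
UNITED STATES,29275,10.4,156.6,85238.4,233205.4,318600.3
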