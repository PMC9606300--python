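station_id,region,regime,turbidity_change_m,mean_turbidity_ftu,max_depth_m,date,local_time,lat_dd,lon_dd
IS1,ISF,D,71.6,0.16,74,2019-07-27,10:30,78.409900,17.100917
IS2,ISF,D,77.7,0.15,80,2019-07-27,11:15,78.408883,17.120650
IS3,ISF,D,69.7,0.16,93,2019-07-27,13:08,78.437100,17.155750
ISF3,ISF,S,9.6,0.02,93,2019-07-27,15:45,78.447717,16.082383
IC1,ISF,S,4.5,0.02,150,2019-07-27,17:20,78.437100,16.000683
IC2,ISF,S,6.5,0.02,152,2019-07-27,18:20,78.440000,15.980900
IA2,ISF,I,28.5,0.06,80,2019-07-28,07:50,78.257483,15.570800
T1,TOR,I,14.5,0.05,42,2019-07-29,16:10,77.157700,14.722367
T2,TOR,I,14.5,0.04,52,2019-07-29,17:15,77.152267,14.696933
T3,TOR,I,13.5,0.04,52,2019-07-29,18:10,77.151067,14.746850
H1,HOR,S,0,0.02,168,2019-08-01,07:57,76.934283,15.365783
HO1,HOR,S,0,0.02,150,2019-08-01,15:40,76.924683,15.372083
H4,HOR,I,28.5,0.09,106,2019-08-03,09:10,77.001200,15.996333
HC1,HOR,I,14.4,0.06,122,2019-08-03,16:20,76.994383,15.969367
HC2,HOR,I,30.5,0.06,105,2019-08-03,17:50,76.990500,16.020083
H3,HOR,D,67.5,0.11,120,2019-08-04,08:45,77.000283,16.469200
H3prim,HOR,D,60.4,0.09,118,2019-08-04,10:45,76.995517,16.457433
KB3,KGF,I,10.6,0.06,341,2019-08-07,14:00,78.954883,11.942267
KB0,KGF,S,3.5,0.02,322,2019-08-09,09:55,79.043017,11.136517
KB5prim,KGF,D,49.5,0.43,50,2019-08-09,21:50,78.896250,12.334017
KI,KGF,D,76.3,0.13,79,2019-08-10,08:35,78.896250,12.334017
KI2,KGF,D,59.5,0.11,60,2019-08-10,15:00,78.998233,12.012550
KB1,KGF,S,6.5,0.03,335,2019-08-11,15:30,79.011317,11.433583
KB2,KGF,S,8.5,0.02,307,2019-08-11,19:00,78.976867,11.718317
KB5bis,KGF,D,60,0.26,64,2019-08-11,22:15,78.877250,12.496483
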