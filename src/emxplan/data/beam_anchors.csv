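energy_MV,kind,key,value
10,depth_at_percent,100,2.4
10,depth_at_percent,90,5.6
10,depth_at_percent,80,8.2
10,depth_at_percent,70,11.1
10,depth_at_percent,60,14.5
10,depth_at_percent,50,18.3
10,percent_at_depth,0,23.4
10,percent_at_depth,10,73.9
10,percent_at_depth,20,46.3
10,percent_at_depth,30,29.0
10,measured_depth_at_percent,100,2.4
10,measured_depth_at_percent,90,5.5
10,measured_depth_at_percent,80,8.2
10,measured_depth_at_percent,70,11.1
10,measured_depth_at_percent,60,14.4
10,measured_depth_at_percent,50,18.3
10,measured_percent_at_depth,0,44.7
10,measured_percent_at_depth,10,73.4
10,measured_percent_at_depth,20,46.3
10,measured_percent_at_depth,30,29.0
6,depth_at_percent,100,1.5
6,depth_at_percent,90,4.2
6,depth_at_percent,80,6.6
6,depth_at_percent,70,9.2
6,depth_at_percent,60,12.0
6,depth_at_percent,50,15.0
6,percent_at_depth,0,36.1
6,percent_at_depth,10,66.5
6,percent_at_depth,20,38.5
6,percent_at_depth,30,22.0
6,measured_depth_at_percent,100,1.6
6,measured_depth_at_percent,90,4.2
6,measured_depth_at_percent,80,6.6
6,measured_depth_at_percent,70,9.2
6,measured_depth_at_percent,60,12.0
6,measured_depth_at_percent,50,15.2
6,measured_percent_at_depth,0,63.7
6,measured_percent_at_depth,10,66.7
6,measured_percent_at_depth,20,38.2
6,measured_percent_at_depth,30,21.7
5,depth_at_percent,100,1.3
5,depth_at_percent,90,3.8
5,depth_at_percent,80,6.0
5,depth_at_percent,70,8.6
5,depth_at_percent,60,11.3
5,depth_at_percent,50,14.3
5,percent_at_depth,0,41.5
5,percent_at_depth,10,64.7
5,percent_at_depth,20,35.9
5,percent_at_depth,30,19.8
4,depth_at_percent,100,1.1
4,depth_at_percent,90,3.3
4,depth_at_percent,80,5.7
4,depth_at_percent,70,8.0
4,depth_at_percent,60,10.4
4,depth_at_percent,50,13.2
4,percent_at_depth,0,51.2
4,percent_at_depth,10,61.0
4,percent_at_depth,20,32.2
4,percent_at_depth,30,16.8
3,depth_at_percent,100,0.7
3,depth_at_percent,90,3.1
3,depth_at_percent,80,5.2
3,depth_at_percent,70,7.4
3,depth_at_percent,60,9.6
3,depth_at_percent,50,12.2
3,percent_at_depth,0,60.5
3,percent_at_depth,10,58.7
3,percent_at_depth,20,29.1
3,percent_at_depth,30,14.3
2,depth_at_percent,100,0.5
2,depth_at_percent,90,2.9
2,depth_at_percent,80,4.7
2,depth_at_percent,70,6.9
2,depth_at_percent,60,9.0
2,depth_at_percent,50,11.2
2,percent_at_depth,0,73.9
2,percent_at_depth,10,55.8
2,percent_at_depth,20,24.9
2,percent_at_depth,30,11.1
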