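distance_m,cumulative_time_s
200,0:28.09
300,0:41.86
400,0:55.90
500,1:10.00
600,1:24.17
700,1:37.69
800,1:52.04
900,2:06.12
1000,2:20.28
1100,2:34.23
1200,2:48.28
1300,3:02.13
1400,3:15.69
1500,3:29.47
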