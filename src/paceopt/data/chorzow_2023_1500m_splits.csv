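distance_m,cumulative_time_s
200,0:27.7
300,0:41.8
400,0:55.8
500,1:09.8
600,1:23.8
700,1:37.8
800,1:51.6
900,2:05.5
1000,2:19.3
1100,2:33.1
1200,2:46.9
1300,3:00.4
1400,3:13.8
1500,3:27.14
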