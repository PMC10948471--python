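distance_m,cumulative_time_s
200,0:28.09
300,0:42.20
400,0:56.34
500,1:10.66
600,1:25.08
700,1:39.75
800,1:54.11
900,2:08.52
1000,2:23.04
1100,2:37.51
1200,2:51.68
1300,3:05.62
1400,3:19.08
1500,3:32.76
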