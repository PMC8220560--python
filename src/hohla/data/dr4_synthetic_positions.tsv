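beta_position
-29
-17
-1
9
11
13
26
28
30
32
37
40
47
57
60
67
70
71
74
77
85
86
90
96
98
104
112
120
133
140
152
160
180
200
233
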