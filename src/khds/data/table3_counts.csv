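points,urgency,count
0,non_urgent,5430
0,urgent,0
0,very_urgent,0
0,emergent,0
1,non_urgent,728
1,urgent,2
1,very_urgent,5
1,emergent,0
2,non_urgent,689
2,urgent,127
2,very_urgent,206
2,emergent,15
3,non_urgent,79
3,urgent,27
3,very_urgent,184
3,emergent,8
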