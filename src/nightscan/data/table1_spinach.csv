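Code,Time,Fert,Inf,1,2,3,4,5,6,7,8,9,10,11,12,13,14,15,Plants
1,Base,Low,No,95.0,0,5.0,0,0,0,0,0,0,0,0,0,0,0,0,10
2,Base,Med,No,0,50.0,50.0,0,0,0,0,0,0,0,0,0,0,0,0,10
3,Base,High,No,0,0,100.0,0,0,0,0,0,0,0,0,0,0,0,0,40
4,Early,Low,No,0,0,5.0,95.0,0,0,0,0,0,0,0,0,0,0,0,10
5,Early,Med,No,0,0,15.0,5.0,75.0,5.0,0,0,0,0,0,0,0,0,0,10
6,Early,High,No,0,0,10.0,0,0,79.4,0,10.6,0,0,0,0,0,0,0,9.5
7,Early,Low,Yes,0,0,0,0,0,0,95.0,5.0,0,0,0,0,0,0,0,10
8,Early,Med,Yes,0,0,0,0,0,0,0,90.0,10.0,0,0,0,0,0,0,10
9,Early,High,Yes,0,0,0,0,0,0,0,5.6,94.4,0,0,0,0,0,0,9
10,Late,Low,No,0,0,0,0,0,0,0,0,0,100.0,0,0,0,0,0,10
11,Late,Med,No,0,0,0,0,0,0,0,0,0,0,100.0,0,0,0,0,10
12,Late,High,No,0,0,0,0,0,0,0,0,0,0,5.0,95.0,0,0,0,9
13,Late,Low,Yes,0,0,0,0,0,0,0,0,0,0,0,0,100.0,0,0,9
14,Late,Med,Yes,0,0,0,0,0,0,0,0,0,0,0,5.0,0,88.8,6.3,9
15,Late,High,Yes,0,0,0,0,0,0,0,0,0,0,0,0,6.3,5.6,88.2,8.5
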