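Code,Time,Fert,Inf,1,2,3,4,5,6,7,8,9,10,11,12,13,14,15,Plants
1,Base,Low,No,90.0,2.5,2.5,2.5,0,2.5,0,0,0,0,0,0,0,0,0,20
2,Base,Med,No,7.5,82.5,7.5,0,0,2.5,0,0,0,0,0,0,0,0,0,20
3,Base,High,No,10.0,7.5,82.5,0,0,0,0,0,0,0,0,0,0,0,0,20
4,Early,Low,No,16.7,0,0,77.8,0,0,5.6,0,0,0,0,0,0,0,0,9
5,Early,Med,No,5.0,0,5.0,0,78.9,5.6,0,5.6,0,0,0,0,0,0,0,9.5
6,Early,High,No,0,0,5.6,0,0,88.9,5.6,0,0,0,0,0,0,0,0,9
7,Early,Low,Yes,0,0,0,0,0,0,83.3,11.1,5.6,0,0,0,0,0,0,9
8,Early,Med,Yes,0,0,0,0,0,0,18.1,75.7,6.3,0,0,0,0,0,0,8.5
9,Early,High,Yes,0,0,0,0,0,0,5.6,0,94.4,0,0,0,0,0,0,8
10,Late,Low,No,0,0,0,0,0,0,0,0,0,100.0,0,0,0,0,0,10
11,Late,Med,No,0,0,0,0,0,0,0,0,0,0,100.0,0,0,0,0,10
12,Late,High,No,0,0,0,0,0,0,0,0,0,0,0,100.0,0,0,0,10
13,Late,Low,Yes,0,0,0,0,0,0,0,0,0,0,0,0,89.4,5.0,5.6,9.5
14,Late,Med,Yes,0,0,0,0,0,0,0,0,0,0,0,0,5.0,95.0,0,9.5
15,Late,High,Yes,0,0,0,0,0,0,0,0,0,0,0,0,5.0,20.0,75.0,10
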