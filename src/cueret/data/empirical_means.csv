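experiment,measure,region,slice,distractor,mean,se
1,FFD,pre-critical,antecedent-match,match,279,3
1,FFD,pre-critical,antecedent-match,mismatch,277,3
1,FFD,pre-critical,antecedent-mismatch,match,285,3
1,FFD,pre-critical,antecedent-mismatch,mismatch,279,3
1,FFD,reflexive,antecedent-match,match,258,3
1,FFD,reflexive,antecedent-match,mismatch,259,3
1,FFD,reflexive,antecedent-mismatch,match,264,4
1,FFD,reflexive,antecedent-mismatch,mismatch,251,3
1,FFD,post-critical,antecedent-match,match,270,4
1,FFD,post-critical,antecedent-match,mismatch,274,4
1,FFD,post-critical,antecedent-mismatch,match,274,3
1,FFD,post-critical,antecedent-mismatch,mismatch,268,4
1,FPRT,pre-critical,antecedent-match,match,366,6
1,FPRT,pre-critical,antecedent-match,mismatch,370,6
1,FPRT,pre-critical,antecedent-mismatch,match,386,6
1,FPRT,pre-critical,antecedent-mismatch,mismatch,375,6
1,FPRT,reflexive,antecedent-match,match,269,4
1,FPRT,reflexive,antecedent-match,mismatch,270,4
1,FPRT,reflexive,antecedent-mismatch,match,282,5
1,FPRT,reflexive,antecedent-mismatch,mismatch,263,4
1,FPRT,post-critical,antecedent-match,match,376,8
1,FPRT,post-critical,antecedent-match,mismatch,370,8
1,FPRT,post-critical,antecedent-mismatch,match,384,7
1,FPRT,post-critical,antecedent-mismatch,mismatch,364,7
1,RBRT,pre-critical,antecedent-match,match,397,6
1,RBRT,pre-critical,antecedent-match,mismatch,407,7
1,RBRT,pre-critical,antecedent-mismatch,match,425,7
1,RBRT,pre-critical,antecedent-mismatch,mismatch,413,7
1,RBRT,reflexive,antecedent-match,match,286,4
1,RBRT,reflexive,antecedent-match,mismatch,284,4
1,RBRT,reflexive,antecedent-mismatch,match,302,5
1,RBRT,reflexive,antecedent-mismatch,mismatch,284,4
1,RBRT,post-critical,antecedent-match,match,436,9
1,RBRT,post-critical,antecedent-match,mismatch,430,9
1,RBRT,post-critical,antecedent-mismatch,match,448,9
1,RBRT,post-critical,antecedent-mismatch,mismatch,432,9
1,RPD,pre-critical,antecedent-match,match,484,13
1,RPD,pre-critical,antecedent-match,mismatch,508,14
1,RPD,pre-critical,antecedent-mismatch,match,537,15
1,RPD,pre-critical,antecedent-mismatch,mismatch,533,15
1,RPD,reflexive,antecedent-match,match,430,16
1,RPD,reflexive,antecedent-match,mismatch,410,15
1,RPD,reflexive,antecedent-mismatch,match,484,18
1,RPD,reflexive,antecedent-mismatch,mismatch,494,25
1,RPD,post-critical,antecedent-match,match,688,25
1,RPD,post-critical,antecedent-match,mismatch,662,23
1,RPD,post-critical,antecedent-mismatch,match,759,27
1,RPD,post-critical,antecedent-mismatch,mismatch,755,30
1,FPRP,pre-critical,antecedent-match,match,13,1
1,FPRP,pre-critical,antecedent-match,mismatch,14,1
1,FPRP,pre-critical,antecedent-mismatch,match,14,1
1,FPRP,pre-critical,antecedent-mismatch,mismatch,16,1
1,FPRP,reflexive,antecedent-match,match,17,1
1,FPRP,reflexive,antecedent-match,mismatch,15,1
1,FPRP,reflexive,antecedent-mismatch,match,19,1
1,FPRP,reflexive,antecedent-mismatch,mismatch,17,1
1,FPRP,post-critical,antecedent-match,match,24,1
1,FPRP,post-critical,antecedent-match,mismatch,24,1
1,FPRP,post-critical,antecedent-mismatch,match,26,1
1,FPRP,post-critical,antecedent-mismatch,mismatch,26,1
1,TFT,pre-critical,antecedent-match,match,725,14
1,TFT,pre-critical,antecedent-match,mismatch,696,14
1,TFT,pre-critical,antecedent-mismatch,match,761,15
1,TFT,pre-critical,antecedent-mismatch,mismatch,716,14
1,TFT,reflexive,antecedent-match,match,439,10
1,TFT,reflexive,antecedent-match,mismatch,428,9
1,TFT,reflexive,antecedent-mismatch,match,455,10
1,TFT,reflexive,antecedent-mismatch,mismatch,433,9
1,TFT,post-critical,antecedent-match,match,628,14
1,TFT,post-critical,antecedent-match,mismatch,614,15
1,TFT,post-critical,antecedent-mismatch,match,628,15
1,TFT,post-critical,antecedent-mismatch,mismatch,605,13
1,RRT,pre-critical,antecedent-match,match,577,17
1,RRT,pre-critical,antecedent-match,mismatch,537,16
1,RRT,pre-critical,antecedent-mismatch,match,604,17
1,RRT,pre-critical,antecedent-mismatch,mismatch,565,16
1,RRT,reflexive,antecedent-match,match,418,15
1,RRT,reflexive,antecedent-match,mismatch,396,14
1,RRT,reflexive,antecedent-mismatch,match,411,14
1,RRT,reflexive,antecedent-mismatch,mismatch,397,13
1,RRT,post-critical,antecedent-match,match,507,18
1,RRT,post-critical,antecedent-match,mismatch,503,20
1,RRT,post-critical,antecedent-mismatch,match,509,21
1,RRT,post-critical,antecedent-mismatch,mismatch,493,17
2,FFD,pre-critical,local,match,267,5
2,FFD,pre-critical,local,mismatch,268,5
2,FFD,pre-critical,non-local,match,267,5
2,FFD,pre-critical,non-local,mismatch,270,5
2,FFD,reflexive,local,match,251,6
2,FFD,reflexive,local,mismatch,239,5
2,FFD,reflexive,non-local,match,240,5
2,FFD,reflexive,non-local,mismatch,244,6
2,FFD,post-critical,local,match,257,6
2,FFD,post-critical,local,mismatch,255,5
2,FFD,post-critical,non-local,match,253,5
2,FFD,post-critical,non-local,mismatch,258,6
2,FPRT,pre-critical,local,match,342,9
2,FPRT,pre-critical,local,mismatch,341,9
2,FPRT,pre-critical,non-local,match,351,9
2,FPRT,pre-critical,non-local,mismatch,343,9
2,FPRT,reflexive,local,match,260,7
2,FPRT,reflexive,local,mismatch,245,6
2,FPRT,reflexive,non-local,match,250,6
2,FPRT,reflexive,non-local,mismatch,254,7
2,FPRT,post-critical,local,match,325,10
2,FPRT,post-critical,local,mismatch,320,10
2,FPRT,post-critical,non-local,match,322,9
2,FPRT,post-critical,non-local,mismatch,320,9
2,RBRT,pre-critical,local,match,398,11
2,RBRT,pre-critical,local,mismatch,409,11
2,RBRT,pre-critical,non-local,match,433,12
2,RBRT,pre-critical,non-local,mismatch,447,13
2,RBRT,reflexive,local,match,278,7
2,RBRT,reflexive,local,mismatch,259,6
2,RBRT,reflexive,non-local,match,263,7
2,RBRT,reflexive,non-local,mismatch,277,8
2,RBRT,post-critical,local,match,378,11
2,RBRT,post-critical,local,mismatch,375,12
2,RBRT,post-critical,non-local,match,383,12
2,RBRT,post-critical,non-local,mismatch,375,11
2,RPD,pre-critical,local,match,575,25
2,RPD,pre-critical,local,mismatch,573,26
2,RPD,pre-critical,non-local,match,596,24
2,RPD,pre-critical,non-local,mismatch,638,28
2,RPD,reflexive,local,match,486,28
2,RPD,reflexive,local,mismatch,419,27
2,RPD,reflexive,non-local,match,448,29
2,RPD,reflexive,non-local,mismatch,484,32
2,RPD,post-critical,local,match,636,35
2,RPD,post-critical,local,mismatch,628,36
2,RPD,post-critical,non-local,match,667,41
2,RPD,post-critical,non-local,mismatch,710,47
2,FPRP,pre-critical,local,match,23,2
2,FPRP,pre-critical,local,mismatch,20,2
2,FPRP,pre-critical,non-local,match,25,2
2,FPRP,pre-critical,non-local,mismatch,28,2
2,FPRP,reflexive,local,match,18,1
2,FPRP,reflexive,local,mismatch,14,1
2,FPRP,reflexive,non-local,match,16,1
2,FPRP,reflexive,non-local,mismatch,16,1
2,FPRP,post-critical,local,match,24,2
2,FPRP,post-critical,local,mismatch,24,2
2,FPRP,post-critical,non-local,match,25,2
2,FPRP,post-critical,non-local,mismatch,25,2
2,TFT,pre-critical,local,match,683,25
2,TFT,pre-critical,local,mismatch,666,22
2,TFT,pre-critical,non-local,match,737,26
2,TFT,pre-critical,non-local,mismatch,763,28
2,TFT,reflexive,local,match,396,14
2,TFT,reflexive,local,mismatch,354,13
2,TFT,reflexive,non-local,match,377,14
2,TFT,reflexive,non-local,mismatch,379,14
2,TFT,post-critical,local,match,501,19
2,TFT,post-critical,local,mismatch,491,18
2,TFT,post-critical,non-local,match,508,19
2,TFT,post-critical,non-local,mismatch,479,17
2,RRT,pre-critical,local,match,626,33
2,RRT,pre-critical,local,mismatch,592,28
2,RRT,pre-critical,non-local,match,645,33
2,RRT,pre-critical,non-local,mismatch,704,34
2,RRT,reflexive,local,match,352,22
2,RRT,reflexive,local,mismatch,365,26
2,RRT,reflexive,non-local,match,360,24
2,RRT,reflexive,non-local,mismatch,345,22
2,RRT,post-critical,local,match,432,29
2,RRT,post-critical,local,mismatch,414,30
2,RRT,post-critical,non-local,match,468,32
2,RRT,post-critical,non-local,mismatch,413,26
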