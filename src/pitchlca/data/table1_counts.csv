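condition,trial,opposing,following,nonresponse,error
down_only,1,19,15,0,2
down_only,2,24,11,0,1
down_only,3,22,14,0,0
down_only,4,24,11,1,0
down_only,5,19,17,0,0
down_only,6,25,11,0,0
down_only,7,22,13,1,0
down_only,8,24,12,0,0
down_only,9,19,17,0,0
down_only,10,22,13,1,0
down_only,11,16,19,0,1
down_only,12,15,21,0,0
down_only,13,21,15,0,0
down_only,14,20,14,1,1
down_only,15,22,14,0,0
down_only,16,16,20,0,0
down_only,17,14,21,1,0
down_only,18,18,17,0,1
down_only,19,19,17,0,0
down_only,20,22,13,1,0
down_only,21,15,19,0,2
down_only,22,13,21,1,1
down_only,23,17,17,2,0
down_only,24,16,19,0,1
down_only,25,19,15,1,1
down_only,26,16,17,1,2
down_only,27,17,19,0,0
down_only,28,15,20,0,1
down_only,29,17,19,0,0
down_only,30,15,21,0,0
up_only,1,22,14,0,0
up_only,2,19,15,1,1
up_only,3,25,11,0,0
up_only,4,24,12,0,0
up_only,5,26,10,0,0
up_only,6,26,9,0,1
up_only,7,28,6,1,1
up_only,8,23,12,1,0
up_only,9,19,15,1,1
up_only,10,23,12,0,1
up_only,11,24,10,2,0
up_only,12,20,13,1,2
up_only,13,26,10,0,0
up_only,14,21,15,0,0
up_only,15,21,14,1,0
up_only,16,21,13,1,1
up_only,17,18,16,1,1
up_only,18,24,12,0,0
up_only,19,24,11,1,0
up_only,20,25,8,3,0
up_only,21,25,11,0,0
up_only,22,23,12,1,0
up_only,23,19,16,1,0
up_only,24,24,11,1,0
up_only,25,15,18,0,3
up_only,26,23,13,0,0
up_only,27,22,14,0,0
up_only,28,25,11,0,0
up_only,29,22,13,1,0
up_only,30,24,10,2,0
random,1,22,12,1,1
random,2,22,14,0,0
random,3,18,16,2,0
random,4,19,15,2,0
random,5,28,8,0,0
random,6,23,13,0,0
random,7,27,9,0,0
random,8,23,13,0,0
random,9,25,8,2,1
random,10,21,15,0,0
random,11,19,17,0,0
random,12,24,12,0,0
random,13,20,15,0,1
random,14,24,10,1,1
random,15,20,15,0,1
random,16,21,15,0,0
random,17,25,10,1,0
random,18,23,13,0,0
random,19,26,9,1,0
random,20,21,13,1,1
random,21,21,15,0,0
random,22,21,15,0,0
random,23,22,13,0,1
random,24,23,11,1,1
random,25,17,16,1,2
random,26,19,15,1,1
random,27,18,17,1,0
random,28,21,14,1,0
random,29,25,11,0,0
random,30,18,17,1,0
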