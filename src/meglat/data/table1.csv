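case_no,sex,age_at_meg,age_at_onset,duration_y,side,eeg,mri,fdg_pet,ecd,linear_svm,ice,surgery,histology,engel
1,M,71,35,36,R,R,HS,R,No spike,CTR,N,SAH,HS,1a
2,M,31,23,8,R,R,HS,R,R,R,N,SAH,HS,1d
3,F,33,7,26,R,R,HS,R,R,R,N,SAH,HS,1a
4,F,39,30,30,R,R,HS,R,R,R,N,SAH,HS,1a
5,F,38,20,18,R,R,HS,R,No spike,CTR,N,SAH,HS,1a
6,M,36,20,16,R,bilateral,HS,R,Bilateral,R,N,SAH,HS,2c
7,F,20,10,10,R,R,HS,R,R,R,N,SAH,HS,1b
8,F,36,24,12,R,R,Negative,R,R,R,N,SAH,HS,1a
9,M,40,12,28,R,R,Negative,Negative,No spike,R,Y,SAH,HS,1a
10,M,31,21,10,R,R,HS,R,no spike,CTR,N,SAH,HS,1a
11,F,17,15,2,R,R,HS,R,No spike,R,N,SAH,HS,1a
12,M,22,15,6,R,R,HS,R,R,CTR,N,SAH,noHS,1a
13,M,22,18,4,R,R,AE,R,R,R,Y,ATL,noHS,1d
14,F,44,30,14,R,R,Negative,R,No spike,CTR,N,ATL,noHS,1b
15,F,44,19,25,R,R,Negative,Negative,R,R,Y,ATL,noHS,3a
16,F,8,3,5,R,R,HS,R,R,R,N,ATL,FCD,1a
17,F,54,49,5,R,R,AE,Negative,R,R,N,SAH,noHS,1b
18,F,22,16,6,R,R,Negative,R,R,R,,,,
19,F,30,4,15,R,R,Negative,R,R,CTR,,,,
20,F,42,25,17,L,L,HS,L,L,L,N,SAH,HS,1a
21,F,36,20,16,L,L,HS,L,Bilateral,L,N,SAH,HS,1a
22,F,35,17,18,L,L,HS,L,L,L,N,SAH,HS,1a
23,M,30,2,28,L,L,HS,L,L,L,N,SAH,HS,1a
24,M,25,20,5,L,Bilateral,HS,L,L,L,N,SAH,HS,1a
25,M,38,19,19,L,L,HS,L,L,L,N,SAH,HS,1a
26,F,52,12,40,L,Bilateral,HS,L,Bilateral,CTR,Y,SAH,HS,1a
27,M,56,6,50,L,L,HS,L,L,CTR,N,SAH,HS,1a
28,F,14,8,6,L,L,FCD,L,L,L,N,SAH,FCD,1a
29,F,22,20,2,L,L,Negative,L,L,L,N,SAH,HS,1a
30,M,45,14,31,L,L,DNT,L,L,L,N,SAH,noHS,1a
31,M,38,2,36,L,L,HS,L,No spike,L,,,,
32,F,49,6,43,L,L,Negative,L,No spike,CTR,Y,SAH,HS,1b
33,F,41,8,33,L,L,HS,L,L,L,N,SAH,HS,2b
34,M,37,24,13,L,L,HS,L,Bilateral,L,N,SAH,HS,1b
35,F,36,3,33,L,L,HS,L,L,CTR,N,SAH,HS,2c
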