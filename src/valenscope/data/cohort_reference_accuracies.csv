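subject,knn_delta,knn_alpha,knn_fast_gamma,svm_delta,svm_alpha,svm_fast_gamma
1,95.0,97.5,77.5,97.5,97.5,77.5
2,92.5,95.0,77.5,87.5,95.0,82.5
3,95.0,97.5,72.5,97.5,97.5,75.0
4,100,92.5,60.0,97.5,95.0,72.5
5,95.0,90.0,90.0,97.5,95.0,92.5
6,100,95.0,97.5,100,97.5,95.0
7,95.0,95.0,87.5,97.5,100,92.5
8,95.0,97.5,77.5,97.5,100,85.0
9,95.0,97.5,82.5,97.5,97.5,87.5
10,95.0,97.5,90.0,100,95.0,90.0
11,90.0,92.5,90.0,90.0,95.0,87.5
12,95.0,100,85.0,100,100,85.0
13,97.5,95.0,70.0,100,97.5,67.5
14,95.0,97.5,97.5,100,97.5,100
15,95.0,97.5,82.5,97.5,97.5,82.5
16,100,95.0,75.0,100,95.0,77.5
17,95.0,97.5,85.0,97.5,100,85.0
18,97.5,100,90.0,97.5,100,92.5
19,95.0,95.0,95.0,97.5,92.5,95.0
20,95.0,97.5,85.0,97.5,97.5,90.0
21,95.0,97.5,90.0,100,97.5,97.5
22,97.5,100,90.0,100,100,85.0
23,92.5,100,95.0,95.0,100,95.0
24,97.5,97.5,77.5,95.0,97.5,77.5
25,95.0,95.0,87.5,97.5,97.5,85.0
26,95.0,95.0,100,97.5,97.5,100
27,97.5,90.0,95.0,100,92.5,95.0
28,87.5,97.5,97.5,90.0,97.5,97.5
29,95.0,95.0,97.5,97.5,95.0,97.5
30,95.0,97.5,87.5,97.5,100,90.0
31,85.0,97.5,82.5,92.5,100,85.0
32,95.0,97.5,70.0,100,100,70.0
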