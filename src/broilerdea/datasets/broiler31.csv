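dmu,housing,age,feed,mortality,cost,total_weight
1,544436,43.13,2637,4.58%,4.36,1654
2,632907,42.52,2913,3.82%,4.27,1899
3,359794,43.92,1721,4.42%,4.42,1065
4,1249391,43.04,5940,3.49%,4.15,3956
5,359318,40.90,1558,4.72%,4.33,1013
6,295866,42.01,1352,4.73%,4.40,850
7,132038,41.35,560,8.06%,4.50,347
8,254029,43.02,1169,5.85%,4.33,736
9,359864,42.95,1635,7.37%,4.23,1062
10,1116457,42.89,5143,7.27%,4.28,3334
11,646762,41.26,2810,9.15%,4.39,1800
12,788492,42.48,3487,8.92%,4.28,2276
13,303212,42.22,1370,6.50%,4.24,903
14,762851,41.06,3197,5.28%,4.33,2066
15,673960,41.87,3108,4.25%,4.28,2017
16,717801,42.02,3267,3.56%,4.33,2099
17,894040,42.67,4213,4.56%,4.35,2656
18,606406,43.67,2922,5.12%,4.34,1843
19,467990,44.70,2263,3.70%,4.47,1370
20,326485,43.31,1521,4.51%,4.42,944
21,779931,43.02,3407,3.84%,4.30,2220
22,201268,42.10,935,4.73%,4.30,603
23,227720,39.85,956,3.56%,4.06,654
24,207620,40.68,899,4.44%,4.33,579
25,336127,41.63,1567,3.33%,4.28,1020
26,526711,41.05,2275,5.00%,4.37,1446
27,758505,42.70,3567,4.19%,4.30,2296
28,707747,40.86,3071,4.30%,4.37,1951
29,485820,43.07,2270,3.85%,4.28,1469
30,104795,42.42,496,4.42%,4.42,308
31,74668,43.53,325,6.65%,4.57,195
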