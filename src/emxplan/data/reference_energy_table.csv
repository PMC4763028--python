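ts_cm,ep_cm,energy_MV
2,2,3
2,3,3
2,4,3
2,5,3
2,6,3
2,7,3
2,8,4
2,9,4
2,10,4
2,11,4
2,12,4
2,13,4
2,14,4
2,15,4
2,16,5
2,17,5
2,18,10
2,19,10
2,20,10
2,21,10
3,3,3
3,4,3
3,5,4
3,6,4
3,7,4
3,8,4
3,9,4
3,10,4
3,11,4
3,12,4
3,13,4
3,14,5
3,15,5
3,16,5
3,17,5
3,18,10
3,19,10
3,20,10
3,21,10
4,4,4
4,5,4
4,6,4
4,7,4
4,8,5
4,9,5
4,10,5
4,11,5
4,12,5
4,13,5
4,14,5
4,15,5
4,16,5
4,17,5
4,18,10
4,19,10
4,20,10
4,21,10
5,4,4
5,5,5
5,6,5
5,7,5
5,8,5
5,9,5
5,10,5
5,11,5
5,12,5
5,13,5
5,14,5
5,15,5
5,16,5
5,17,5
5,18,10
5,19,10
5,20,10
5,21,10
6,4,5
6,5,5
6,6,5
6,7,5
6,8,5
6,9,5
6,10,5
6,11,5
6,12,5
6,13,5
6,14,5
6,15,5
6,16,5
6,17,5
6,18,10
6,19,10
6,20,10
6,21,10
7,5,5
7,6,5
7,7,5
7,8,5
7,9,5
7,10,5
7,11,5
7,12,5
7,13,5
7,14,5
7,15,5
7,16,5
7,17,5
7,18,10
7,19,10
7,20,10
7,21,10
8,5,5
8,6,5
8,7,5
8,8,5
8,9,5
8,10,5
8,11,5
8,12,5
8,13,6
8,14,6
8,15,6
8,16,6
8,17,6
8,18,10
8,19,10
8,20,10
8,21,10
9,6,6
9,7,6
9,8,6
9,9,6
9,10,6
9,11,6
9,12,6
9,13,6
9,14,6
9,15,6
9,16,6
9,17,6
9,18,10
9,19,10
9,20,10
9,21,10
10,6,6
10,7,6
10,8,6
10,9,6
10,10,6
10,11,6
10,12,6
10,13,6
10,14,6
10,15,6
10,16,6
10,17,6
10,18,10
10,19,10
10,20,10
10,21,10
11,7,10
11,8,10
11,9,10
11,10,10
11,11,10
11,12,10
11,13,10
11,14,10
11,15,10
11,16,10
11,17,10
11,18,10
11,19,10
11,20,10
11,21,10
12,7,10
12,8,10
12,9,10
12,10,10
12,11,10
12,12,10
12,13,10
12,14,10
12,15,10
12,16,10
12,17,10
12,18,10
12,19,10
12,20,10
12,21,10
13,8,10
13,9,10
13,10,10
13,11,10
13,12,10
13,13,10
13,14,10
13,15,10
13,16,10
13,17,10
13,18,10
13,19,10
13,20,10
13,21,10
14,8,10
14,9,10
14,10,10
14,11,10
14,12,10
14,13,10
14,14,10
14,15,10
14,16,10
14,17,10
14,18,10
14,19,10
14,20,10
14,21,10
15,9,10
15,10,10
15,11,10
15,12,10
15,13,10
15,14,10
15,15,10
15,16,10
15,17,10
15,18,10
15,19,10
15,20,10
15,21,10
16,9,10
16,10,10
16,11,10
16,12,10
16,13,10
16,14,10
16,15,10
16,16,10
16,17,10
16,18,10
16,19,10
16,20,10
16,21,10
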