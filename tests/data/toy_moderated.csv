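user_id,day,slot,available,considered,prob,push,outcome_24h,week_in_study,which_day,days_since_chart,pushed_indicator,push_success_ratio,has_charted_10
0,1,2,1,1,0.5,0,0,0,1,0.0,0,0.0,0
0,3,4,1,1,0.5,0,0,0,1,2.0,0,0.0,0
0,5,6,1,1,0.5,1,0,0,1,4.0,0,0.0,0
0,7,4,1,1,0.5,1,0,0,0,6.0,1,0.0,0
0,9,6,1,1,0.5,0,0,1,1,8.0,1,0.0,0
0,15,6,1,1,0.5,0,0,2,1,14.0,1,0.0,0
0,21,5,1,1,0.5,1,0,2,0,20.0,1,0.0,0
0,27,4,1,1,0.5,0,0,3,0,26.0,1,0.0,0
0,34,6,1,1,0.5,0,0,4,0,1.0,1,0.0,0
1,1,4,1,1,0.5,1,0,0,1,0.0,0,0.0,0
1,3,3,1,1,0.5,0,0,0,1,2.0,1,0.0,0
1,5,5,1,1,0.5,1,0,0,1,4.0,1,0.0,0
1,7,3,1,1,0.5,1,0,0,0,6.0,1,0.0,0
1,9,2,1,1,0.5,0,0,1,1,8.0,1,0.0,0
1,15,6,1,1,0.5,1,1,2,1,1.0,1,0.0,0
1,18,5,1,1,0.5,0,0,2,1,2.0,1,0.25,0
1,20,3,1,1,0.5,1,1,2,0,4.0,1,0.25,0
1,23,4,1,1,0.5,1,1,3,1,2.0,1,0.4,0
1,26,3,1,1,0.5,0,0,3,1,1.0,1,0.5,0
1,28,2,1,1,0.5,0,0,3,0,3.0,1,0.5,0
1,30,2,1,1,0.5,1,0,4,1,5.0,1,0.5,0
1,32,1,1,1,0.5,0,0,4,1,7.0,1,0.42857142857142855,0
1,34,5,1,1,0.5,0,0,4,0,9.0,1,0.42857142857142855,0
2,1,2,1,1,0.5,1,1,0,1,0.0,0,0.0,0
2,4,1,1,1,0.5,0,1,0,1,2.0,1,1.0,0
2,6,5,1,1,0.5,0,1,0,0,2.0,1,1.0,0
2,9,3,1,1,0.5,0,0,1,1,2.0,1,1.0,0
2,11,5,1,1,0.5,0,0,1,1,4.0,1,1.0,0
2,13,3,1,1,0.5,1,1,1,0,6.0,1,1.0,0
2,16,6,1,1,0.5,1,1,2,1,1.0,1,1.0,0
2,19,5,1,1,0.5,0,0,2,1,2.0,1,1.0,0
2,21,4,1,1,0.5,1,1,2,0,4.0,1,1.0,0
2,24,4,1,1,0.5,0,1,3,1,1.0,1,1.0,0
2,27,6,1,1,0.5,0,1,3,0,1.0,1,1.0,1
2,30,1,1,1,0.5,0,0,4,1,1.0,1,1.0,1
2,32,1,1,1,0.5,1,1,4,1,3.0,1,1.0,1
2,35,4,1,1,0.5,0,0,4,0,2.0,1,1.0,1
3,1,2,1,1,0.5,1,0,0,1,0.0,0,0.0,0
3,3,2,1,1,0.5,0,0,0,1,2.0,1,0.0,0
3,5,4,1,1,0.5,0,0,0,1,4.0,1,0.0,0
3,7,5,1,1,0.5,0,0,0,0,6.0,1,0.0,0
3,9,2,1,1,0.5,1,0,1,1,8.0,1,0.0,0
3,15,1,1,1,0.5,0,0,2,1,14.0,1,0.0,0
3,21,5,1,1,0.5,1,0,2,0,1.0,1,0.0,0
3,23,5,1,1,0.5,1,0,3,1,3.0,1,0.0,0
3,25,6,1,1,0.5,0,0,3,1,5.0,1,0.0,0
3,27,3,1,1,0.5,1,1,3,0,7.0,1,0.0,0
3,29,2,1,1,0.5,1,0,4,1,2.0,1,0.2,0
3,31,5,1,1,0.5,0,0,4,1,4.0,1,0.16666666666666666,0
3,33,2,1,1,0.5,1,0,4,1,6.0,1,0.16666666666666666,0
3,35,2,1,1,0.5,0,0,4,0,8.0,1,0.14285714285714285,0
4,1,1,1,1,0.5,0,0,0,1,0.0,0,0.0,0
4,3,2,1,1,0.5,1,0,0,1,2.0,0,0.0,0
4,5,1,1,1,0.5,1,0,0,1,4.0,1,0.0,0
4,7,5,1,1,0.5,0,0,0,0,6.0,1,0.0,0
4,9,5,1,1,0.5,0,0,1,1,8.0,1,0.0,0
4,15,4,1,1,0.5,0,0,2,1,14.0,1,0.0,0
4,21,4,1,1,0.5,0,0,2,0,20.0,1,0.0,0
4,27,2,1,1,0.5,0,0,3,0,26.0,1,0.0,0
5,1,6,1,1,0.5,0,1,0,1,0.0,0,0.0,0
5,4,4,1,1,0.5,0,1,0,1,2.0,0,0.0,0
5,7,5,1,1,0.5,0,0,0,0,2.0,0,0.0,0
5,9,6,1,1,0.5,1,1,1,1,4.0,0,0.0,0
5,12,1,1,1,0.5,0,0,1,1,2.0,1,1.0,0
5,14,6,1,1,0.5,0,0,1,0,4.0,1,1.0,0
5,16,4,1,1,0.5,0,0,2,1,6.0,1,1.0,0
5,18,5,1,1,0.5,0,0,2,1,8.0,1,1.0,0
5,21,4,1,1,0.5,0,0,2,0,1.0,1,1.0,0
5,23,6,1,1,0.5,1,1,3,1,3.0,1,1.0,0
5,26,6,1,1,0.5,0,0,3,1,2.0,1,1.0,0
5,28,6,1,1,0.5,1,0,3,0,4.0,1,1.0,0
5,30,2,1,1,0.5,1,0,4,1,6.0,1,0.6666666666666666,0
5,32,6,1,1,0.5,0,0,4,1,8.0,1,0.5,0
6,1,3,1,1,0.5,1,0,0,1,0.0,0,0.0,0
6,3,4,1,1,0.5,1,0,0,1,2.0,1,0.0,0
6,5,6,1,1,0.5,0,0,0,1,4.0,1,0.0,0
6,7,5,1,1,0.5,0,0,0,0,6.0,1,0.0,0
6,9,2,1,1,0.5,1,0,1,1,8.0,1,0.0,0
6,14,2,1,1,0.5,0,0,1,0,1.0,1,0.0,0
6,16,3,1,1,0.5,0,0,2,1,3.0,1,0.0,0
6,18,6,1,1,0.5,0,0,2,1,5.0,1,0.0,0
6,20,2,1,1,0.5,0,0,2,0,7.0,1,0.0,0
6,22,1,1,1,0.5,0,1,3,1,9.0,1,0.0,0
6,24,6,1,1,0.5,0,0,3,1,2.0,1,0.0,0
6,26,1,1,1,0.5,0,0,3,1,4.0,1,0.0,0
6,28,2,1,1,0.5,1,0,3,0,6.0,1,0.0,0
6,30,4,1,1,0.5,1,0,4,1,8.0,1,0.0,0
6,34,3,1,1,0.5,1,0,4,0,1.0,1,0.0,0
7,1,2,1,1,0.5,1,0,0,1,0.0,0,0.0,0
7,3,3,1,1,0.5,0,1,0,1,2.0,1,0.0,0
7,6,3,1,1,0.5,0,0,0,0,2.0,1,0.0,0
7,8,2,1,1,0.5,0,0,1,1,4.0,1,0.0,0
7,10,6,1,1,0.5,1,0,1,1,6.0,1,0.0,0
7,12,6,1,1,0.5,0,0,1,1,8.0,1,0.0,0
7,18,5,1,1,0.5,1,0,2,1,14.0,1,0.0,0
7,21,4,1,1,0.5,0,0,2,0,1.0,1,0.0,0
7,23,4,1,1,0.5,1,0,3,1,3.0,1,0.0,0
7,25,4,1,1,0.5,0,1,3,1,5.0,1,0.0,0
7,28,2,1,1,0.5,1,0,3,0,2.0,1,0.0,0
7,30,5,1,1,0.5,1,1,4,1,4.0,1,0.0,0
7,33,6,1,1,0.5,0,1,4,1,2.0,1,0.16666666666666666,0
8,1,5,1,1,0.5,1,0,0,1,0.0,0,0.0,0
8,3,4,1,1,0.5,1,1,0,1,2.0,1,0.0,0
8,6,5,1,1,0.5,0,1,0,0,1.0,1,0.5,0
8,9,3,1,1,0.5,1,1,1,1,2.0,1,0.5,0
8,12,5,1,1,0.5,1,0,1,1,2.0,1,0.6666666666666666,0
8,14,2,1,1,0.5,0,1,1,0,4.0,1,0.5,0
8,16,6,1,1,0.5,0,0,2,1,2.0,1,0.5,0
8,18,5,1,1,0.5,0,0,2,1,4.0,1,0.5,0
8,20,3,1,1,0.5,1,1,2,0,6.0,1,0.5,0
8,23,4,1,1,0.5,1,0,3,1,1.0,1,0.6,0
8,25,2,1,1,0.5,0,1,3,1,3.0,1,0.5,0
8,28,5,1,1,0.5,1,0,3,0,2.0,1,0.5,0
8,30,3,1,1,0.5,0,0,4,1,4.0,1,0.42857142857142855,0
8,32,4,1,1,0.5,1,0,4,1,6.0,1,0.42857142857142855,0
8,34,6,1,1,0.5,1,0,4,0,8.0,1,0.375,0
9,1,3,1,1,0.5,0,0,0,1,0.0,0,0.0,0
9,3,6,1,1,0.5,1,1,0,1,2.0,0,0.0,0
9,6,4,1,1,0.5,1,0,0,0,1.0,1,1.0,0
9,8,2,1,1,0.5,1,1,1,1,3.0,1,0.5,0
9,11,4,1,1,0.5,0,0,1,1,2.0,1,0.6666666666666666,0
9,13,3,1,1,0.5,0,0,1,0,4.0,1,0.6666666666666666,0
9,15,2,1,1,0.5,1,1,2,1,6.0,1,0.6666666666666666,0
9,18,1,1,1,0.5,0,0,2,1,2.0,1,0.75,0
9,20,2,1,1,0.5,1,1,2,0,4.0,1,0.75,0
9,23,2,1,1,0.5,1,0,3,1,2.0,1,0.8,0
9,25,6,1,1,0.5,1,0,3,1,4.0,1,0.6666666666666666,0
9,27,4,1,1,0.5,1,0,3,0,6.0,1,0.5714285714285714,0
9,29,3,1,1,0.5,0,1,4,1,8.0,1,0.5,0
9,31,6,1,1,0.5,1,0,4,1,2.0,1,0.5,0
9,33,5,1,1,0.5,0,0,4,1,4.0,1,0.4444444444444444,0
9,35,4,1,1,0.5,0,0,4,0,6.0,1,0.4444444444444444,0
10,1,5,1,1,0.5,1,0,0,1,0.0,0,0.0,0
10,3,4,1,1,0.5,1,0,0,1,2.0,1,0.0,0
10,5,2,1,1,0.5,0,0,0,1,4.0,1,0.0,0
10,7,3,1,1,0.5,0,0,0,0,6.0,1,0.0,0
10,9,2,1,1,0.5,1,0,1,1,8.0,1,0.0,0
10,15,4,1,1,0.5,1,0,2,1,14.0,1,0.0,0
10,21,3,1,1,0.5,1,0,2,0,20.0,1,0.0,0
10,27,4,1,1,0.5,0,1,3,0,1.0,1,0.0,0
10,30,6,1,1,0.5,0,0,4,1,2.0,1,0.0,0
10,32,3,1,1,0.5,1,1,4,1,4.0,1,0.0,0
10,35,5,1,1,0.5,0,0,4,0,2.0,1,0.16666666666666666,0
11,1,4,1,1,0.5,1,1,0,1,0.0,0,0.0,0
11,4,5,1,1,0.5,1,0,0,1,2.0,1,1.0,0
11,6,4,1,1,0.5,0,0,0,0,4.0,1,0.5,0
11,8,4,1,1,0.5,1,0,1,1,6.0,1,0.5,0
11,10,1,1,1,0.5,1,1,1,1,8.0,1,0.3333333333333333,0
11,12,6,1,1,0.5,1,1,1,1,2.0,1,0.5,0
11,15,5,1,1,0.5,1,0,2,1,1.0,1,0.6,0
11,17,4,1,1,0.5,0,1,2,1,3.0,1,0.5,0
11,19,3,1,1,0.5,1,0,2,1,2.0,1,0.5,0
11,21,3,1,1,0.5,1,0,2,0,4.0,1,0.42857142857142855,0
11,23,4,1,1,0.5,1,0,3,1,6.0,1,0.375,0
11,25,2,1,1,0.5,1,0,3,1,8.0,1,0.3333333333333333,0
11,30,6,1,1,0.5,0,0,4,1,1.0,1,0.3,0
11,32,5,1,1,0.5,0,0,4,1,3.0,1,0.3,0
11,34,4,1,1,0.5,1,0,4,0,5.0,1,0.3,0
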