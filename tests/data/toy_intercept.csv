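user_id,day,slot,available,considered,prob,push,outcome_24h,week_in_study,which_day,days_since_chart,pushed_indicator,push_success_ratio,has_charted_10
0,1,2,1,1,0.5,1,0,0,1,0.0,0,0.0,0
0,3,1,1,1,0.5,0,0,0,1,2.0,1,0.0,0
0,5,6,1,1,0.5,1,0,0,1,4.0,1,0.0,0
0,7,5,1,1,0.5,1,0,0,0,6.0,1,0.0,0
0,9,6,1,1,0.5,0,0,1,1,8.0,1,0.0,0
0,13,3,1,1,0.5,0,1,1,0,1.0,1,0.0,0
0,15,3,1,1,0.5,1,1,2,1,2.0,1,0.0,0
0,18,2,1,1,0.5,0,0,2,1,1.0,1,0.25,0
0,20,2,1,1,0.5,1,1,2,0,3.0,1,0.25,0
0,22,4,1,1,0.5,0,0,3,1,2.0,1,0.4,0
0,24,1,1,1,0.5,1,1,3,1,4.0,1,0.4,0
0,26,2,1,1,0.5,1,0,3,1,2.0,1,0.5,0
0,28,2,1,1,0.5,0,0,3,0,4.0,1,0.42857142857142855,0
1,1,6,1,1,0.5,0,0,0,1,0.0,0,0.0,0
1,3,4,1,1,0.5,1,0,0,1,2.0,0,0.0,0
1,5,3,1,1,0.5,0,0,0,1,4.0,1,0.0,0
1,7,5,1,1,0.5,0,0,0,0,6.0,1,0.0,0
1,9,2,1,1,0.5,0,0,1,1,8.0,1,0.0,0
1,12,3,1,1,0.5,0,1,1,1,1.0,1,0.0,0
1,15,4,1,1,0.5,1,0,2,1,1.0,1,0.0,0
1,17,2,1,1,0.5,1,0,2,1,3.0,1,0.0,0
1,19,2,1,1,0.5,0,0,2,1,5.0,1,0.0,0
1,21,4,1,1,0.5,1,0,2,0,7.0,1,0.0,0
1,23,1,1,1,0.5,0,0,3,1,9.0,1,0.0,0
2,1,6,1,1,0.5,0,1,0,1,0.0,0,0.0,0
2,4,2,1,1,0.5,1,0,0,1,1.0,0,0.0,0
2,6,6,1,1,0.5,1,0,0,0,3.0,1,0.0,0
2,8,2,1,1,0.5,1,1,1,1,5.0,1,0.0,0
2,10,6,1,1,0.5,0,0,1,1,2.0,1,0.3333333333333333,0
2,12,5,1,1,0.5,1,1,1,1,4.0,1,0.3333333333333333,0
2,15,3,1,1,0.5,1,0,2,1,1.0,1,0.5,0
2,17,3,1,1,0.5,0,0,2,1,3.0,1,0.4,0
2,19,3,1,1,0.5,1,0,2,1,5.0,1,0.4,0
2,21,6,1,1,0.5,0,0,2,0,7.0,1,0.3333333333333333,0
2,23,1,1,1,0.5,0,0,3,1,9.0,1,0.3333333333333333,0
2,26,6,1,1,0.5,0,1,3,1,1.0,1,0.3333333333333333,0
3,1,5,1,1,0.5,1,0,0,1,0.0,0,0.0,0
3,3,4,1,1,0.5,1,0,0,1,2.0,1,0.0,0
3,5,1,1,1,0.5,1,0,0,1,4.0,1,0.0,0
3,7,6,1,1,0.5,1,0,0,0,6.0,1,0.0,0
3,9,6,1,1,0.5,0,0,1,1,8.0,1,0.0,0
3,13,6,1,1,0.5,1,0,1,0,1.0,1,0.0,0
3,15,4,1,1,0.5,0,0,2,1,3.0,1,0.0,0
3,17,5,1,1,0.5,1,0,2,1,5.0,1,0.0,0
3,19,6,1,1,0.5,1,1,2,1,7.0,1,0.0,0
3,22,2,1,1,0.5,0,0,3,1,2.0,1,0.14285714285714285,0
3,24,3,1,1,0.5,1,0,3,1,4.0,1,0.14285714285714285,0
3,26,2,1,1,0.5,1,1,3,1,6.0,1,0.125,0
4,1,3,1,1,0.5,0,1,0,1,0.0,0,0.0,0
4,4,2,1,1,0.5,1,0,0,1,2.0,0,0.0,0
4,6,6,1,1,0.5,0,1,0,0,4.0,1,0.0,0
4,9,3,1,1,0.5,1,0,1,1,2.0,1,0.0,0
4,11,6,1,1,0.5,0,0,1,1,4.0,1,0.0,0
4,13,6,1,1,0.5,1,0,1,0,6.0,1,0.0,0
4,15,5,1,1,0.5,1,0,2,1,8.0,1,0.0,0
4,19,6,1,1,0.5,0,0,2,1,1.0,1,0.0,0
4,21,5,1,1,0.5,1,1,2,0,3.0,1,0.0,0
4,24,4,1,1,0.5,1,0,3,1,2.0,1,0.2,0
4,26,3,1,1,0.5,1,0,3,1,4.0,1,0.16666666666666666,0
4,28,5,1,1,0.5,0,0,3,0,6.0,1,0.14285714285714285,0
5,1,5,1,1,0.5,0,1,0,1,0.0,0,0.0,0
5,4,3,1,1,0.5,1,1,0,1,1.0,0,0.0,0
5,7,2,1,1,0.5,1,0,0,0,2.0,1,1.0,0
5,9,1,1,1,0.5,1,0,1,1,4.0,1,0.5,0
5,11,1,1,1,0.5,0,1,1,1,6.0,1,0.3333333333333333,0
5,13,5,1,1,0.5,1,0,1,0,2.0,1,0.3333333333333333,0
5,15,1,1,1,0.5,0,0,2,1,4.0,1,0.25,0
5,17,6,1,1,0.5,1,1,2,1,6.0,1,0.25,0
5,19,5,1,1,0.5,1,0,2,1,2.0,1,0.4,0
5,21,6,1,1,0.5,0,0,2,0,4.0,1,0.3333333333333333,0
5,23,3,1,1,0.5,0,0,3,1,6.0,1,0.3333333333333333,0
5,25,4,1,1,0.5,0,0,3,1,8.0,1,0.3333333333333333,0
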