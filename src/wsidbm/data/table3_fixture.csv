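replicate,slide_id,long_dbm_pct,short_dbm_pct,ratio,outcome,prediction,long_pct_is_floor
1,T13,9.4,4.2,0.4,Long,Long,False
1,T15,7.0,3.4,0.5,Long,Long,False
1,T17,2.3,1.8,0.8,Long,Long,False
1,T16,9.3,9.5,1.0,Long,Long,False
1,T07,5.4,7.0,1.3,Short,Long,False
1,T12,4.1,11.4,2.7,Long,Long,False
1,T08,3.6,16.0,4.4,Short,Long,False
1,T14,4.2,28.7,6.8,Long,Long,False
1,T02,1.1,12.6,11.4,Short,Long,False
1,T20,1.2,19.6,16.5,Long,Long,False
1,T18,0.9,16.9,18.0,Long,Long,False
1,T04,0.6,23.0,35.9,Short,Short,False
1,T19,0.3,11.4,36.4,Long,Short,False
1,T22,0.3,10.4,37.4,Long,Short,False
1,T03,1.2,57.5,49.6,Short,Short,False
1,T21,0.2,25.9,104.6,Long,Short,False
1,T01,0.4,72.9,166.6,Short,Short,False
1,T09,0.1,18.3,198.3,Short,Short,False
1,T06,0.1,36.4,347.1,Short,Short,False
1,T11,0.1,63.4,537.6,Short,Short,False
1,T05,0.0,56.6,1446.4,Short,Short,True
1,T10,0.0,56.5,8506.6,Short,Short,True
2,T07,11.2,4.1,0.4,Short,Long,False
2,T15,15.8,7.4,0.5,Long,Long,False
2,T16,16.2,9.7,0.6,Long,Long,False
2,T13,8.1,7.9,1.0,Long,Long,False
2,T17,6.5,8.6,1.3,Long,Long,False
2,T14,6.2,17.0,2.8,Long,Long,False
2,T12,8.0,28.8,3.6,Long,Long,False
2,T20,4.5,18.5,4.1,Long,Long,False
2,T08,5.6,24.4,4.4,Short,Long,False
2,T02,2.4,16.3,6.9,Short,Long,False
2,T19,1.2,22.0,18.7,Long,Long,False
2,T18,1.5,38.2,25.1,Long,Long,False
2,T21,1.9,49.6,25.7,Long,Long,False
2,T03,2.2,66.5,30.2,Short,Short,False
2,T09,0.2,30.2,124.7,Short,Short,False
2,T11,0.5,78.2,146.5,Short,Short,False
2,T06,0.4,63.8,181.0,Short,Short,False
2,T04,0.3,48.9,186.3,Short,Short,False
2,T22,0.2,56.5,278.8,Long,Short,False
2,T01,0.2,87.4,374.5,Short,Short,False
2,T05,0.1,68.8,523.1,Short,Short,False
2,T10,0.0,70.0,8150.6,Short,Short,True
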