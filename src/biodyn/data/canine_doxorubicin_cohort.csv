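subject_id,tumour_type,pre_count,post_count
1,LSA,7.6,3.8
2,LSA,10.1,4.2
3,LSA,30.0,0.8
4,HSA,10.7,2.0
5,LSA,8.2,1.6
6,HSA,5.0,2.5
7,LSA,12.6,2.4
8,LSA,4.2,1.4
9,OSA,5.6,3.3
10,LSA,10.2,0.7
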