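stratum,cluster,deaths_placebo,n_placebo,deaths_bb,n_bb
SR,SR all,1121,6276,907,6546
SR,SR1,14,222,8,211
SR,SR2,40,487,34,514
SR,SR3,108,731,59,683
SR,SR4,151,1231,140,1306
SR,SR5,267,1706,202,1791
SR,SR6,541,1899,464,2041
AF,AF all,300,1425,278,1412
AF,AF1,50,307,59,301
AF,AF2,50,338,29,321
AF,AF3,68,348,69,348
AF,AF4,81,201,68,202
AF,AF5,51,231,53,240
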