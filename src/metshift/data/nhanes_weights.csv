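period,gender,mean_weight_kg,source
1960-62,men,76.9,reported
1960-62,women,64.9,reported
1971-74,men,,unreported
1971-74,women,,unreported
1976-80,men,,unreported
1976-80,women,,unreported
1988-94,men,,unreported
1988-94,women,,unreported
1999-2002,men,,unreported
1999-2002,women,,unreported
2003-06,men,91.8,reported
2003-06,women,,unreported
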