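sector,met_median,met_min,met_max,category
farm,3.0,2.5,4.5,moderate
mining_logging,3.8,3.0,8.0,moderate
construction,4.0,1.5,7.5,moderate
manufacturing,3.0,1.5,4.0,moderate
trade_transport_utilities,2.0,1.5,3.0,light
information,1.5,1.5,1.5,sedentary
financial,1.5,1.5,1.5,sedentary
professional_business,1.5,1.5,2.0,sedentary
education_health,2.5,1.5,4.0,light
leisure_hospitality,2.5,1.5,3.5,light
other_services,2.5,1.5,3.0,light
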