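alias,sector
farm,farm
farm jobs,farm
farming,farm
agriculture,farm
agricultural,farm
mining_logging,mining_logging
mining and logging,mining_logging
mining/logging,mining_logging
mining-logging,mining_logging
mining,mining_logging
construction,construction
manufacturing,manufacturing
trade_transport_utilities,trade_transport_utilities
trade transportation and utilities,trade_transport_utilities
"trade, transportation, and utilities",trade_transport_utilities
"trade (wholesale & retail), transportation, and utilities",trade_transport_utilities
trade/transportation/utilities,trade_transport_utilities
ttu,trade_transport_utilities
information,information
financial,financial
financial activities,financial
financial services,financial
finance,financial
professional_business,professional_business
professional and business services,professional_business
professional/business services,professional_business
professional services,professional_business
education_health,education_health
education and health services,education_health
education/health services,education_health
health/education,education_health
leisure_hospitality,leisure_hospitality
leisure and hospitality,leisure_hospitality
leisure/hospitality,leisure_hospitality
other_services,other_services
other services,other_services
other,other_services
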