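study_id,region,population,n,years,central_stat,high_stat,highest_stat,moe_overall_central,moe_overall_high,moe_overall_highest
Roca et al.,ES-Valencia,children,125,2010,p50,p95,max,1201,320,33
Fernandez et al. (children),ES-Valencia,children,568,2016,p50,p95,max,3504,357,39
Suarez et al.,ES-Andalusia,adolescents,117,2017-2019,p50,p95,max,247500,58929,4091
Llop et al.,ES-Valencia,pregnant women,573,2003-2006,p50,p95,max,12122,1800,51
Fernandez et al. (lactating),ES-Valencia,lactating women,116,2015,p50,p95,max,2970,752,354
Gari et al. (adults),ES-Catalonia,adults,80,n.r.,p50,,max,2475,,675
Gari et al. (farm workers),ES-Catalonia,farm workers,45,n.r.,p50,,max,1414,,297
HBM4EU Portugal,Portugal,adults,296,2019-2020,p50,p95,upper_ci_p95,3193,808,710
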