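study_id,country,population,years,n,p50,p95,upper_ci_p95,max,adjusted
BE 3xG,Belgium,children,2014-2020,,1.22,3.24,5.05,,false
CY Organiko,Cyprus,children,2014-2020,,6.52,13.82,15.74,,false
FR Esteban,France,children,2014-2020,,n.r.,n.r.,n.r.,,false
IL RAVMABAT,Israel,children,2014-2020,,2.80,18.38,28.84,,false
SI SLOCRP,Slovenia,children,2014-2020,,0.61,3.08,4.92,,false
NL SPECIMEN,The Netherlands,children,2014-2020,,1.13,3.49,5.55,,false
FR ESTEBAN,France,adults,2014-2021,,n.r.,n.r.,0.06,,false
DE ESB,Germany,adults,2014-2021,,0.82,2.87,3.87,,false
IS Diet_HBM,Iceland,adults,2014-2021,,0.61,2.07,3.30,,false
IL RAVMABAT adults,Israel,adults,2014-2021,,2.75,11.22,55.22,,false
PT INSEF,Portugal,adults,2014-2021,296,1.86,7.35,8.37,,false
Study CH,Switzerland,adults,2014-2021,,0.97,3.64,4.72,,false
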