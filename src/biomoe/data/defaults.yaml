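# Default configuration: chlorpyrifos / chlorpyrifos-methyl -> urinary TCPy.
#
# Sources of the numbers are the published EU hazard characterisation for the
# two parents: molar urinary excretion fraction Fue 0.7 (range 0.5-0.93),
# TCPy/chlorpyrifos molar ratio 0.566, daily urinary excretion 0.02 L/kg bw
# (adults) and 0.03 L/kg bw (children), 0.024 L/kg bw/day in the
# food-monitoring forward model.  The chlorpyrifos-methyl molar ratio is not
# tabulated anywhere authoritative; 0.6153 follows from standard molecular
# weights (TCPy 198.43 / chlorpyrifos-methyl 322.53) and may be overridden.

toxicokinetics:
  fue: 0.7
  fue_low: 0.5
  fue_high: 0.93
  molar_ratio: 0.566
  urine_output_adult: 0.02
  urine_output_child: 0.03
  urine_output_food_model: 0.024

pesticides:
  chlorpyrifos:
    molar_ratio: 0.566
    # chronic ADI (mg/kg bw/day) in force for each monitoring report year:
    # 0.01 up to the 2016 MRL revision, 0.001 afterwards
    adi_by_year:
      2012: 0.01
      2013: 0.01
      2014: 0.01
      2015: 0.01
      2016: 0.001
      2017: 0.001
      2018: 0.001
      2019: 0.001
  chlorpyrifos-methyl:
    molar_ratio: 0.6153
    adi_by_year:
      2012: 0.01
      2013: 0.01
      2014: 0.01
      2015: 0.01
      2016: 0.01
      2017: 0.01
      2018: 0.01
      2019: 0.01

# Animal points of departure, mg/kg bw/day.  The overall endpoint is a
# developmental-neurotoxicity LOAEL (effects at the lowest tested dose);
# the rest are NOAELs.
pods:
  chlorpyrifos:
    - {endpoint: overall, value: 0.3, basis: LOAEL}
    - {endpoint: long_term, value: 0.1, basis: NOAEL}
    - {endpoint: short_term_ache, value: 0.1, basis: NOAEL}
    - {endpoint: offspring, value: 1.0, basis: NOAEL}
    - {endpoint: reproductive, value: 5.0, basis: NOAEL}
    - {endpoint: carcinogenicity, value: 10.0, basis: NOAEL}
  chlorpyrifos-methyl:
    # same overall/long-term PoD as chlorpyrifos; no short-term AChE value
    - {endpoint: overall, value: 0.3, basis: LOAEL}
    - {endpoint: long_term, value: 0.1, basis: NOAEL}
    - {endpoint: offspring, value: 3.0, basis: NOAEL}
    - {endpoint: reproductive, value: 10.0, basis: NOAEL}
    - {endpoint: carcinogenicity, value: 40.0, basis: NOAEL}

# Margin-of-exposure classification cutoffs per endpoint category.
# Boundary values belong to the safer class (strict <).  ORANGE exists only
# where an extrapolation-range factor applies (LOAEL-based overall PoD,
# subacute-to-subchronic AChE); GREEN requires an additional margin of 10
# over the most severe applicable concern threshold.
thresholds:
  loael_overall:    {red_below: 300,   orange_below: 1000, yellow_below: 10000}
  st_ache:          {red_below: 100,   orange_below: 300,  yellow_below: 3000}
  noael_generic:    {red_below: 100,                       yellow_below: 1000}
  carcinogenicity:  {red_below: 10000,                     yellow_below: 100000}

uncertainty:
  fue_low: 0.5
  fue_mode: 0.7
  fue_high: 0.93
  n_draws: 10000
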